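"""Synthetic methylation cohorts with known ground truth.

The generator emulates the statistical structure of a placental-inflammation
methylation study so that every downstream stage (differential methylation,
batch correction, cross-tissue overlap, cell-type signatures, clustering) can
be exercised against a truth table:

* CpG archetypes are bimodal: most sites sit near 0 or 1 methylation, a
  configurable fraction is intermediate.
* Tissue-specific and immune-cell-type-specific CpG sets are planted so that
  the owning type differs from every other type by at least ``effect_delta``
  on the beta scale.
* Case (aCA) chorionic villi are modelled as a mixture of the villous
  profile with the neutrophil reference profile — the "infiltrating maternal
  neutrophils" hypothesis — with per-sample mixture fraction f drawn
  uniformly from a configured range.  Direct (non-mixture) case effects are
  available but default to zero.
* Gestational age, fetal sex, ancestry, chip and chip-row effects act
  additively on the logit (M-like) scale; residual noise is logit-scale
  Gaussian, so emitted beta values stay strictly inside (0, 1).

Everything is driven by a single integer seed: identical configuration and
seed give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data import BetaMatrix, SampleSheet, IMMUNE_CELL_TYPES, TISSUES

EPS = 1e-6  # logit clipping bound, keeps logit finite

REFERENCE_TYPES = TISSUES + IMMUNE_CELL_TYPES + ("whole_blood",)

#: gestational-age spread (weeks) used to scale planted GA slopes
GA_SD = 2.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, EPS, 1.0 - EPS)
    return np.log(p / (1.0 - p))


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort.

    ``n_per_group`` maps (tissue, aca_status) to a sample count; the default
    mirrors the discovery design: 22 aCA + 22 non-aCA chorionic villi,
    9 + 7 chorion, 8 + 7 amnion.  ``effect_delta`` is the planted beta-scale
    effect magnitude shared by all planted sets; covariate (GA, sex, direct
    case) effects are applied on the logit scale as 4·effect_delta per
    covariate SD / indicator, which translates to ≈ effect_delta on the beta
    scale at mid-range sites.
    """

    n_cpg: int = 20_000
    n_per_group: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("chorionic_villi", "aCA"): 22,
            ("chorionic_villi", "non-aCA"): 22,
            ("chorion", "aCA"): 9,
            ("chorion", "non-aCA"): 7,
            ("amnion", "aCA"): 8,
            ("amnion", "non-aCA"): 7,
        }
    )
    n_reference_per_type: int = 6
    archetype_mix: tuple[float, float, float] = (0.4, 0.2, 0.4)
    n_tissue_specific: int = 100
    n_celltype_specific: int = 50
    n_aca_effect: int = 0
    n_ga_effect: int = 50
    n_sex_effect: int = 50
    effect_delta: float = 0.2
    mixture_fraction_range: tuple[float, float] = (0.1, 0.4)
    batch_effect_sd: float = 0.1
    individual_effect_sd: float = 0.0
    noise_sd: float = 0.3
    samples_per_chip: int = 8
    ga_mean_aca: float = 30.7
    ga_mean_non_aca: float = 32.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(self.n_per_group)
        if any(v < 0 for v in counts.values()) or self.n_cpg < 0:
            raise ConfigError("counts must be non-negative")
        for name in (
            "n_tissue_specific",
            "n_celltype_specific",
            "n_aca_effect",
            "n_ga_effect",
            "n_sex_effect",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.total_planted() > self.n_cpg:
            raise ConfigError(
                f"planted sets ({self.total_planted()}) exceed n_cpg ({self.n_cpg})"
            )
        f_min, f_max = self.mixture_fraction_range
        if not (0.0 <= f_min <= f_max <= 1.0):
            raise ConfigError("mixture_fraction_range must satisfy 0 <= f_min <= f_max <= 1")
        mix = np.asarray(self.archetype_mix, dtype=float)
        if mix.size != 3 or mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigError("archetype_mix must be 3 non-negative proportions summing to 1")

    def total_planted(self) -> int:
        return (
            len(TISSUES) * self.n_tissue_specific
            + len(IMMUNE_CELL_TYPES) * self.n_celltype_specific
            + self.n_aca_effect
            + self.n_ga_effect
            + self.n_sex_effect
        )

    # -- config file round-trip -------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["n_per_group"] = {f"{t}|{a}": n for (t, a), n in self.n_per_group.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "n_per_group" in d:
            d["n_per_group"] = {
                tuple(k.split("|")): int(v) for k, v in d["n_per_group"].items()
            }
        for key in ("archetype_mix", "mixture_fraction_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthTables:
    """Ground truth emitted alongside a synthetic cohort.

    ``planted_cpg_sets`` maps a set name (e.g. ``tissue_specific:amnion``,
    ``celltype_specific:neutrophil``, ``aca_effect``, ``ga_effect``,
    ``sex_effect``) to ``{cpg_id: signed beta-scale effect}``.
    """

    planted_cpg_sets: dict[str, dict[str, float]]
    sample_mixture_fractions: dict[str, float]
    batch_assignments: dict[str, dict[str, str]]
    reference_profiles: pd.DataFrame  # CpG x reference type

    def planted_ids(self, set_name: str) -> list[str]:
        return list(self.planted_cpg_sets.get(set_name, {}))

    def to_json(self, path) -> None:
        payload = {
            "planted_cpg_sets": self.planted_cpg_sets,
            "sample_mixture_fractions": self.sample_mixture_fractions,
            "batch_assignments": self.batch_assignments,
            "reference_profiles": {
                "cpg_ids": list(self.reference_profiles.index),
                "types": list(self.reference_profiles.columns),
                "beta": self.reference_profiles.to_numpy().tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthTables":
        with open(path) as fh:
            payload = json.load(fh)
        rp = payload["reference_profiles"]
        profiles = pd.DataFrame(
            np.asarray(rp["beta"], dtype=float), index=rp["cpg_ids"], columns=rp["types"]
        )
        return cls(
            planted_cpg_sets=payload["planted_cpg_sets"],
            sample_mixture_fractions=payload["sample_mixture_fractions"],
            batch_assignments=payload["batch_assignments"],
            reference_profiles=profiles,
        )


def _build_profiles_and_sets(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Draw archetypes and allocate all planted CpG sets from one rng stream.

    A shared bimodal archetype is drawn per CpG (components: low
    U(0.01, 0.15), intermediate U(0.25, 0.75), high U(0.85, 0.99), mixed per
    ``archetype_mix``).  A single permutation of CpG indices then allocates
    disjoint blocks to the tissue-specific, cell-type-specific, case, GA and
    sex effect sets; each planted shift is ``effect_delta`` toward the far
    side of the scale (sign recorded in the set table).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cpg
    comp = rng.choice(3, size=n, p=np.asarray(config.archetype_mix, dtype=float))
    base = np.empty(n)
    base[comp == 0] = rng.uniform(0.01, 0.15, size=(comp == 0).sum())
    base[comp == 1] = rng.uniform(0.25, 0.75, size=(comp == 1).sum())
    base[comp == 2] = rng.uniform(0.85, 0.99, size=(comp == 2).sum())

    cpg_ids = [f"cg{i:07d}" for i in range(n)]
    profiles = pd.DataFrame(
        np.tile(base[:, None], (1, len(REFERENCE_TYPES))),
        index=cpg_ids,
        columns=list(REFERENCE_TYPES),
    )

    order = rng.permutation(n)
    sets: dict[str, dict[str, float]] = {}
    cursor = 0
    for kind, owners, per in (
        ("tissue_specific", TISSUES, config.n_tissue_specific),
        ("celltype_specific", IMMUNE_CELL_TYPES, config.n_celltype_specific),
    ):
        for owner in owners:
            idx = order[cursor : cursor + per]
            cursor += per
            b = base[idx]
            # magnitude has a U(1, 1.5) margin above effect_delta so the
            # ">= effect_delta" separation survives noise and clipping
            mag = config.effect_delta * rng.uniform(1.0, 1.5, per)
            shift = np.where(b <= 0.5, mag, -mag)
            profiles.iloc[idx, profiles.columns.get_loc(owner)] = b + shift
            sets[f"{kind}:{owner}"] = {cpg_ids[i]: float(s) for i, s in zip(idx, shift)}
    for name, per in (
        ("aca_effect", config.n_aca_effect),
        ("ga_effect", config.n_ga_effect),
        ("sex_effect", config.n_sex_effect),
    ):
        idx = order[cursor : cursor + per]
        cursor += per
        shift = np.where(base[idx] <= 0.5, config.effect_delta, -config.effect_delta)
        sets[name] = {cpg_ids[i]: float(s) for i, s in zip(idx, shift)}
    profiles[:] = np.clip(profiles.to_numpy(), EPS, 1.0 - EPS)
    return profiles, sets


def generate_reference_profiles(config: SimConfig) -> pd.DataFrame:
    """Per-type archetype beta profiles with planted type-specific CpG sets.

    Returns a CpG-by-type DataFrame over the three placental tissues, four
    immune cell classes, and whole blood; each planted tissue- or
    cell-type-specific CpG differs between its owning type and every other
    type by at least ``effect_delta`` on the beta scale.
    """
    profiles, _ = _build_profiles_and_sets(config)
    return profiles


def _planted_sets(config: SimConfig, profiles: pd.DataFrame) -> dict[str, dict[str, float]]:
    _, sets = _build_profiles_and_sets(config)
    return sets


def generate_cohort(
    config: SimConfig, profiles: pd.DataFrame | None = None
) -> tuple[BetaMatrix, SampleSheet, TruthTables]:
    """Simulate the full cohort: beta matrix, sample sheet, truth tables.

    Per sample in tissue t the CpG-level beta is
    ``clip(invlogit(logit(mu_t) + case + GA + sex + chip + row + individual
    + noise))``; aCA chorionic-villi samples are then mixed with the
    neutrophil reference profile as ``(1 - f)·beta + f·beta_neutrophil``
    with f ~ U(f_min, f_max) (f = 0 for all other samples).  Gestational age
    is drawn so that the realised aCA group mean is below the non-aCA mean.
    """
    if profiles is None:
        profiles = generate_reference_profiles(config)
    sets = _planted_sets(config, profiles)
    cpg_ids = list(profiles.index)
    idx_of = {c: i for i, c in enumerate(cpg_ids)}
    n = config.n_cpg
    rng = np.random.default_rng(config.seed + 1)  # cohort stream, distinct from profiles

    # ---- individuals: one per chorionic-villi sample; membranes reuse them
    counts = dict(config.n_per_group)
    n_villi_aca = counts.get(("chorionic_villi", "aCA"), 0)
    n_villi_non = counts.get(("chorionic_villi", "non-aCA"), 0)
    individuals = []
    for j in range(n_villi_aca):
        individuals.append(("aCA", f"IND_A{j:02d}"))
    for j in range(n_villi_non):
        individuals.append(("non-aCA", f"IND_N{j:02d}"))

    # GA: aCA mean below non-aCA mean (redraw until realised means comply)
    for _ in range(200):
        ga_aca = np.clip(rng.normal(config.ga_mean_aca, GA_SD, n_villi_aca), 28.0, 36.0)
        ga_non = np.clip(rng.normal(config.ga_mean_non_aca, GA_SD, n_villi_non), 28.0, 36.7)
        if n_villi_aca == 0 or n_villi_non == 0 or ga_aca.mean() < ga_non.mean():
            break
    ga_by_ind = {}
    sex_by_ind = {}
    anc_by_ind = {}
    for (status, ind), ga in zip(individuals, np.concatenate([ga_aca, ga_non])):
        ga_by_ind[ind] = float(ga)
        sex_by_ind[ind] = "M" if rng.random() < 0.5 else "F"
        pop = rng.random() < 0.5
        anc_by_ind[ind] = (
            float((0.5 if pop else -0.5) + rng.normal(0, 0.1)),
            float(rng.normal(0, 0.1)),
        )
    indiv_eff = {}
    for _, ind in individuals:
        indiv_eff[ind] = (
            rng.normal(0.0, config.individual_effect_sd, n)
            if config.individual_effect_sd > 0
            else np.zeros(n)
        )

    # ---- sample table
    rows = []
    group_order = sorted(counts)  # deterministic
    for tissue, status in group_order:
        pool = [ind for st, ind in individuals if st == status]
        for j in range(counts[(tissue, status)]):
            if tissue == "chorionic_villi":
                ind = pool[j]
            else:
                ind = pool[j % max(len(pool), 1)] if pool else f"IND_X{j:02d}"
            short = {"chorionic_villi": "CV", "chorion": "CH", "amnion": "AM"}[tissue]
            sid = f"{short}_{'A' if status == 'aCA' else 'N'}{j:02d}"
            rows.append((sid, tissue, status, ind))

    n_samp = len(rows)
    # shuffle onto chips so batches are not confounded with group
    placement = rng.permutation(n_samp)
    chip_of = {}
    row_of = {}
    for pos, k in enumerate(placement):
        chip_of[rows[k][0]] = f"chip{pos // config.samples_per_chip:02d}"
        row_of[rows[k][0]] = f"R{pos % config.samples_per_chip + 1:02d}"
    n_chips = int(np.ceil(n_samp / config.samples_per_chip))
    chip_effects = rng.normal(0.0, config.batch_effect_sd, (n_chips, n))
    row_effects = rng.normal(0.0, config.batch_effect_sd, (config.samples_per_chip, n))

    # planted covariate-effect vectors: the logit shift that moves the
    # archetype beta by exactly the signed beta-scale effect (these planted
    # CpG blocks are disjoint from the tissue-specific blocks, so every
    # tissue shares the base archetype there)
    base_beta = profiles["chorionic_villi"].to_numpy()

    def _logit_shift(set_name: str) -> np.ndarray:
        v = np.zeros(n)
        for cpg, signed in sets.get(set_name, {}).items():
            i = idx_of[cpg]
            b = base_beta[i]
            target = float(np.clip(b + signed, EPS, 1.0 - EPS))
            v[i] = float(_logit(np.array(target)) - _logit(np.array(b)))
        return v

    aca_shift = _logit_shift("aca_effect")
    ga_slope = _logit_shift("ga_effect") / GA_SD  # one GA SD moves beta by ~effect_delta
    sex_shift = _logit_shift("sex_effect")

    ga_center = float(np.mean(list(ga_by_ind.values()))) if ga_by_ind else 32.0
    neut = profiles["neutrophil"].to_numpy()
    f_min, f_max = config.mixture_fraction_range

    beta = np.empty((n, n_samp))
    sheet_rows = []
    fractions = {}
    for j, (sid, tissue, status, ind) in enumerate(rows):
        mu = profiles[tissue].to_numpy()
        ga = ga_by_ind.get(ind, 32.0)
        sex = sex_by_ind.get(ind, "F")
        x = _logit(mu)
        if status == "aCA":
            x = x + aca_shift
        x = x + ga_slope * (ga - ga_center)
        if sex == "M":
            x = x + sex_shift
        x = x + chip_effects[int(chip_of[sid][4:])]
        x = x + row_effects[int(row_of[sid][1:]) - 1]
        x = x + indiv_eff.get(ind, 0.0)
        x = x + rng.normal(0.0, config.noise_sd, n)
        b = np.clip(_invlogit(x), EPS, 1.0 - EPS)
        f = 0.0
        if tissue == "chorionic_villi" and status == "aCA":
            f = float(rng.uniform(f_min, f_max))
            b = np.clip((1.0 - f) * b + f * neut, EPS, 1.0 - EPS)
        fractions[sid] = f
        beta[:, j] = b
        anc1, anc2 = anc_by_ind.get(ind, (0.0, 0.0))
        sheet_rows.append(
            {
                "sample_id": sid,
                "tissue": tissue,
                "aca_status": status,
                "ga_weeks": ga,
                "fetal_sex": sex,
                "ancestry_coord_1": anc1,
                "ancestry_coord_2": anc2,
                "chip_id": chip_of[sid],
                "chip_row": row_of[sid],
                "individual_id": ind,
            }
        )

    matrix = BetaMatrix(pd.DataFrame(beta, index=cpg_ids, columns=[r[0] for r in rows]))
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = TruthTables(
        planted_cpg_sets=sets,
        sample_mixture_fractions=fractions,
        batch_assignments={
            sid: {"chip_id": chip_of[sid], "chip_row": row_of[sid]} for sid, *_ in rows
        },
        reference_profiles=profiles,
    )
    return matrix, sheet, truth


def generate_reference_samples(
    config: SimConfig, profiles: pd.DataFrame | None = None
) -> tuple[BetaMatrix, SampleSheet]:
    """Simulate sorted-cell reference samples (immune types + villi controls).

    Emits ``n_reference_per_type`` noisy replicates around each reference
    archetype — the analogue of a public sorted-blood-cell reference dataset
    plus control chorionic villi, used for cell-type signature derivation.
    """
    if profiles is None:
        profiles = generate_reference_profiles(config)
    rng = np.random.default_rng(config.seed + 2)
    types = ("chorionic_villi",) + IMMUNE_CELL_TYPES + ("whole_blood",)
    cols, betas, sheet_rows = [], [], []
    for t in types:
        mu = _logit(profiles[t].to_numpy())
        for j in range(config.n_reference_per_type):
            sid = f"REF_{t}_{j:02d}"
            x = mu + rng.normal(0.0, config.noise_sd, config.n_cpg)
            betas.append(np.clip(_invlogit(x), EPS, 1.0 - EPS))
            cols.append(sid)
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "tissue": t if t in TISSUES else f"immune:{t}" if t != "whole_blood" else "whole_blood",
                    "aca_status": pd.NA,
                    "ga_weeks": pd.NA,
                    "fetal_sex": "F",
                    "chip_id": "ref_chip",
                    "chip_row": "R01",
                    "cell_type": t,
                }
            )
    matrix = BetaMatrix(pd.DataFrame(np.column_stack(betas), index=profiles.index, columns=cols))
    return matrix, SampleSheet(pd.DataFrame(sheet_rows))


def generate_genotypes(
    n_samples: int, n_snp: int, divergence: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two-population diploid genotypes (0/1/2) at ancestry-informative SNPs.

    ``divergence`` is the absolute allele-frequency gap between the two
    latent populations, applied at every SNP with random sign.  Returns the
    genotype matrix (samples x SNPs) and the 0/1 population labels.
    """
    if n_snp < 2:
        raise ConfigError("n_snp must be >= 2")
    if not 0.0 <= divergence <= 0.9:
        raise ConfigError("divergence must be in [0, 0.9]")
    rng = np.random.default_rng(seed)
    p1 = rng.uniform(0.05, 0.95 - divergence, n_snp)
    sign = rng.random(n_snp) < 0.5
    lo = np.where(sign, p1, p1 + divergence)
    hi = np.where(sign, p1 + divergence, p1)
    labels = (rng.random(n_samples) < 0.5).astype(int)
    freqs = np.where(labels[:, None] == 0, lo[None, :], hi[None, :])
    genotypes = rng.binomial(2, freqs).astype(np.int8)
    return genotypes, labels
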