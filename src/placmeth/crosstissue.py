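"""Cross-tissue structure: matched correlations, tissue-pair DM, overlap nulls.

Three questions about how the placental tissues relate:

* Do matched samples (same pregnancy) show correlated methylation across
  tissues beyond chance?  Per-CpG Spearman correlations on M values are
  compared with a null built by shuffling the individual matching.
* Which CpGs distinguish the tissues?  A tissue-pair differential
  methylation run at strict thresholds, paired by individual when possible.
* Does a query DM set overlap a target tissue's DM set more than random
  same-size CpG sets drawn from the tested background?  An empirical
  resampling p-value, with the exact hypergeometric tail as a cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .data import BetaMatrix, DataError, SampleSheet
from .ewas import CpGLinearModel, DesignSpec, DMResults
from .preprocess import beta_to_m


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Correlation of matching rows of A and B (NaN for constant rows)."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    den = np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def _rowwise_spearman(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return _rowwise_pearson(
        stats.rankdata(A, axis=1).astype(float), stats.rankdata(B, axis=1).astype(float)
    )


@dataclass
class MatchedCorrelationReport:
    """Observed per-CpG Spearman correlations against a shuffled-match null."""

    observed: pd.Series  # per-CpG r (NaN where undefined)
    null_q95: float
    n_cpg_tested: int
    n_excluded_constant: int
    n_above_null_q95: int
    expected_above: float
    binomial_p: float
    n_shuffles: int

    def summary(self) -> str:
        frac = self.n_above_null_q95 / max(self.n_cpg_tested, 1)
        return (
            f"matched-tissue correlation: {self.n_above_null_q95}/{self.n_cpg_tested} CpGs "
            f"({frac:.1%}) above the shuffled-null 95th percentile "
            f"(expected 5%); binomial p = {self.binomial_p:.3g}"
        )


def matched_tissue_correlation(
    matrix_a: BetaMatrix,
    sheet_a: SampleSheet,
    matrix_b: BetaMatrix,
    sheet_b: SampleSheet,
    n_shuffles: int = 100,
    seed: int = 0,
) -> MatchedCorrelationReport:
    """Per-CpG Spearman correlation between tissues across matched individuals.

    Samples are matched on ``individual_id``; the null distribution pools
    per-CpG correlations over ``n_shuffles`` random permutations of the
    matching of tissue-a samples to tissue-b samples.  Reports how many CpGs
    exceed the pooled null's 95th percentile and a binomial test of that
    count against the nominal 5%.
    """
    common = matrix_a.cpg_ids.intersection(matrix_b.cpg_ids)
    if not len(common):
        raise DataError("matrices share no CpG ids")
    ia = sheet_a.frame.set_index("individual_id")["sample_id"]
    ib = sheet_b.frame.set_index("individual_id")["sample_id"]
    inds = [i for i in ia.index if i in set(ib.index)]
    if len(inds) < 3:
        raise DataError(f"need >= 3 matched individuals, found {len(inds)}")
    A = beta_to_m(matrix_a.frame.loc[common, ia.loc[inds]]).to_numpy()
    B = beta_to_m(matrix_b.frame.loc[common, ib.loc[inds]]).to_numpy()

    # drop CpGs with fewer than 3 complete matched pairs or zero variance
    ok_pairs = (~np.isnan(A) & ~np.isnan(B)).sum(axis=1)
    usable = ok_pairs >= 3
    r_obs = np.full(len(common), np.nan)
    r_obs[usable] = _rowwise_spearman(A[usable], B[usable])
    defined = np.isfinite(r_obs)
    n_tested = int(defined.sum())
    if n_tested == 0:
        raise DataError("no CpG with a defined matched correlation")

    rng = np.random.default_rng(seed)
    null_pool = np.empty((n_shuffles, n_tested))
    Ad, Bd = A[defined], B[defined]
    for s in range(n_shuffles):
        perm = rng.permutation(len(inds))
        null_pool[s] = _rowwise_spearman(Ad, Bd[:, perm])
    q95 = float(np.nanpercentile(null_pool.ravel(), 95))

    n_above = int((r_obs[defined] > q95).sum())
    btest = stats.binomtest(n_above, n_tested, 0.05, alternative="greater")
    return MatchedCorrelationReport(
        observed=pd.Series(r_obs, index=common, name="spearman_r"),
        null_q95=q95,
        n_cpg_tested=n_tested,
        n_excluded_constant=int(len(common) - n_tested),
        n_above_null_q95=n_above,
        expected_above=0.05 * n_tested,
        binomial_p=float(btest.pvalue),
        n_shuffles=n_shuffles,
    )


def tissue_pair_dm(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    tissue_a: str,
    tissue_b: str,
    fdr_max: float = 0.01,
    delta_beta_min: float = 0.20,
    paired: bool | None = None,
) -> DMResults:
    """Differential methylation between two tissues at strict thresholds.

    Pairing by individual (an individual-indicator block in the design) is
    used when ``individual_id`` is present for individuals sampled in both
    tissues; set ``paired=False`` to force the unpaired contrast.  Positive
    Δβ means higher methylation in ``tissue_a``.
    """
    sf = sheet.frame
    present = set(sf["tissue"])
    for t in (tissue_a, tissue_b):
        if t not in present:
            raise DataError(f"tissue {t!r} not present in the sample sheet")
    keep = sf["tissue"].isin([tissue_a, tissue_b])

    use_pairing = False
    if paired is not False and "individual_id" in sf.columns:
        sub = sf.loc[keep]
        by_ind = sub.groupby("individual_id")["tissue"].nunique()
        both = set(by_ind.index[by_ind == 2])
        if len(both) >= 3:
            use_pairing = True
            keep = keep & sf["individual_id"].isin(both)
        elif paired is True:
            raise DataError("paired=True but fewer than 3 individuals have both tissues")

    keep_ids = list(sf.loc[keep, "sample_id"])
    design = DesignSpec(
        primary="tissue",
        primary_level=tissue_a,
        baseline_level=tissue_b,
        covariates=(),
        extra_indicator="individual_id" if use_pairing else None,
        sample_filter=lambda f: f["sample_id"].isin(keep_ids),
    )
    model = CpGLinearModel(matrix, sheet, design)
    return model.fit(fdr_max=fdr_max, delta_beta_min=delta_beta_min)


@dataclass
class OverlapTest:
    """Random-sampling overlap test of a query CpG set against a DM set."""

    query_size: int  # m
    background_size: int  # N
    target_dm_count: int  # K
    observed_overlap: int  # k_obs
    n_draws: int
    empirical_p: float
    hypergeometric_p: float  # exact tail P(X >= k_obs)
    null_mean: float
    null_sd: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def summary(self) -> str:
        return (
            f"overlap {self.observed_overlap}/{self.query_size} vs {self.target_dm_count}"
            f"/{self.background_size} target DM sites: empirical p = {self.empirical_p:.3g} "
            f"({self.n_draws} draws), hypergeometric p = {self.hypergeometric_p:.3g}"
        )


def dm_overlap_test(
    query_cpg_ids,
    target_dm_flags: pd.Series,
    n_draws: int = 10_000,
    seed: int = 0,
) -> OverlapTest:
    """Is the query set's overlap with the target DM set larger than chance?

    Draws ``n_draws`` random CpG sets of the query's size from the tested
    background (the index of ``target_dm_flags``) without replacement;
    empirical p = (1 + #{draws with overlap >= observed}) / (n_draws + 1).
    The exact hypergeometric tail is reported alongside as a cross-check.
    """
    if n_draws < 1000:
        raise DataError("n_draws must be >= 1000")
    background = target_dm_flags.index
    query = pd.Index(query_cpg_ids)
    outside = query.difference(background)
    if len(outside):
        raise DataError(f"query CpGs outside background: {list(outside[:5])}")
    flags = target_dm_flags.astype(bool).to_numpy()
    N, K, m = len(background), int(flags.sum()), len(query)
    if m > N:
        raise DataError("query larger than background")
    k_obs = int(flags[background.get_indexer(query)].sum())

    rng = np.random.default_rng(seed)
    counts = np.empty(n_draws, dtype=np.int64)
    for d in range(n_draws):
        counts[d] = flags[rng.choice(N, size=m, replace=False)].sum()
    emp_p = (1.0 + float((counts >= k_obs).sum())) / (n_draws + 1.0)
    hyper_p = float(stats.hypergeom.sf(k_obs - 1, N, K, m))
    return OverlapTest(
        query_size=m,
        background_size=N,
        target_dm_count=K,
        observed_overlap=k_obs,
        n_draws=n_draws,
        empirical_p=emp_p,
        hypergeometric_p=hyper_p,
        null_mean=float(counts.mean()),
        null_sd=float(counts.std(ddof=1)),
    )
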