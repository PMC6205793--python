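"""Ancestry inference from SNP panels and group-wise demographic comparisons.

Genetic ancestry is summarised by classical (Torgerson) multidimensional
scaling of a pairwise genotype distance matrix computed from a small panel
of ancestry-informative markers; the leading coordinates are carried as
covariates into the differential-methylation design.  Demographic tables
compare the case and control groups with Wilcoxon–Mann–Whitney tests for
continuous covariates, Fisher's exact test for categorical ones, and
two-sample Kolmogorov–Smirnov tests for the ancestry coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, SampleSheet


@dataclass
class MdsResult:
    """Classical-MDS embedding: centered coordinates and eigenvalues."""

    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # length k, non-increasing
    k: int


def genotype_distances(genotypes: np.ndarray, metric: str = "allele-sharing") -> np.ndarray:
    """Pairwise distances between samples from a 0/1/2 genotype matrix.

    ``allele-sharing``: mean per-SNP allele difference / 2 (1 − IBS/2).
    ``euclidean``: ordinary Euclidean distance on genotype counts.
    Missing genotypes (NaN) are mean-imputed per SNP first.
    """
    G = np.asarray(genotypes, dtype=float)
    if np.isnan(G).all(axis=0).any():
        raise DataError("SNP with all genotypes missing")
    if np.isnan(G).any():
        means = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = means[idx[1]]
    if np.nanvar(G, axis=0).min() == 0:
        raise DataError("SNP with zero variance; remove monomorphic markers")
    if metric == "allele-sharing":
        diff = np.abs(G[:, None, :] - G[None, :, :])
        return diff.mean(axis=2) / 2.0
    if metric == "euclidean":
        sq = ((G[:, None, :] - G[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(sq)
    raise DataError(f"unknown distance metric {metric!r}")


def classical_mds(distances: np.ndarray, k: int) -> MdsResult:
    """Torgerson scaling: double-center −D²/2, eigendecompose, take top k.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); the embedding
    is deterministic up to the sign of each axis.  Negative eigenvalues
    (non-Euclidean distances) contribute zero coordinates.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if k >= n:
        raise DataError(f"k={k} must be smaller than the number of samples ({n})")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    lam = vals[order]
    V = vecs[:, order]
    coords = V * np.sqrt(np.maximum(lam, 0.0))
    return MdsResult(coordinates=coords, eigenvalues=lam, k=k)


def ancestry_mds(
    genotypes: np.ndarray, k: int = 2, distance: str = "allele-sharing"
) -> MdsResult:
    """MDS embedding of samples from an AIM-SNP genotype matrix."""
    return classical_mds(genotype_distances(genotypes, metric=distance), k)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table via hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed that of the observed table.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError("Fisher test needs a non-negative 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def compare_group_covariates(
    sheet: SampleSheet,
    grouping: str = "aca_status",
    continuous: tuple[str, ...] = ("ga_weeks",),
    categorical: tuple[str, ...] = ("fetal_sex",),
) -> pd.DataFrame:
    """Demographics table comparing two groups, one row per covariate.

    Continuous covariates: two-sided Wilcoxon–Mann–Whitney (exact
    distribution for combined n ≤ 30, normal approximation with tie
    correction otherwise); categorical: two-sided Fisher exact; ancestry
    MDS coordinates: two-sample KS.  A covariate constant in both groups is
    reported with p = 1 and a note.
    """
    sf = sheet.frame
    groups = [g for g in pd.unique(sf[grouping].dropna())]
    if len(groups) != 2:
        raise DataError(f"grouping {grouping!r} must have exactly 2 levels, got {groups}")
    g1 = sf[sf[grouping] == groups[0]]
    g2 = sf[sf[grouping] == groups[1]]
    if not len(g1) or not len(g2):
        raise DataError("both groups must be nonempty")

    rows = []

    def _summary(v: pd.Series) -> str:
        v = pd.to_numeric(v, errors="coerce").dropna()
        if not len(v):
            return "NA"
        return f"{v.min():.3g}-{v.max():.3g} ({v.mean():.4g})"

    for cov in continuous:
        a = pd.to_numeric(g1[cov], errors="coerce").dropna().to_numpy()
        b = pd.to_numeric(g2[cov], errors="coerce").dropna().to_numpy()
        note = ""
        if len(np.unique(np.concatenate([a, b]))) == 1:
            p = 1.0
            note = "constant in both groups"
        else:
            method = "exact" if (len(a) + len(b) <= 30 and not _has_ties(a, b)) else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
        rows.append(
            {
                "covariate": cov,
                "test": "wilcoxon",
                f"group_{groups[0]}": _summary(g1[cov]),
                f"group_{groups[1]}": _summary(g2[cov]),
                "p": p,
                "note": note,
            }
        )

    for cov in categorical:
        vals = sorted(pd.unique(sf[cov].dropna().astype(str)))
        note = ""
        if len(vals) == 1:
            p, table_str = 1.0, f"{len(g1)} vs {len(g2)} (all {vals[0]})"
            note = "constant in both groups"
        elif len(vals) == 2:
            tab = [
                [int((g1[cov].astype(str) == vals[0]).sum()), int((g1[cov].astype(str) == vals[1]).sum())],
                [int((g2[cov].astype(str) == vals[0]).sum()), int((g2[cov].astype(str) == vals[1]).sum())],
            ]
            p = fisher_exact_2x2(tab)
            table_str = f"{tab[0][0]}/{len(g1)} vs {tab[1][0]}/{len(g2)} {vals[0]}"
        else:
            raise DataError(f"categorical covariate {cov!r} has more than 2 levels")
        rows.append(
            {
                "covariate": cov,
                "test": "fisher",
                f"group_{groups[0]}": table_str,
                f"group_{groups[1]}": "",
                "p": p,
                "note": note,
            }
        )

    for cov in sheet.ancestry_columns:
        a = pd.to_numeric(g1[cov], errors="coerce").dropna().to_numpy()
        b = pd.to_numeric(g2[cov], errors="coerce").dropna().to_numpy()
        note = ""
        if len(np.unique(np.concatenate([a, b]))) == 1:
            p = 1.0
            note = "constant in both groups"
        else:
            p = float(stats.ks_2samp(a, b).pvalue)
        rows.append(
            {
                "covariate": cov,
                "test": "ks",
                f"group_{groups[0]}": _summary(g1[cov]),
                f"group_{groups[1]}": _summary(g2[cov]),
                "p": p,
                "note": note,
            }
        )

    return pd.DataFrame(rows)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)
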