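"""Preprocessing: beta/M transforms, probe filtering, QC, normalization, ComBat.

The processing order follows standard methylation-array practice: filter
probes, (optionally) normalize between samples, then remove known technical
batch structure with a parametric empirical-Bayes adjustment (ComBat) on
M values, protecting the biological design.  Two sequential ComBat passes —
chip row, then chip id — mirror the two technical variables recorded on
Illumina arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BetaMatrix, DataError, ProbeAnnotation, SampleSheet

DEFAULT_EPS = 1e-6


# ---------------------------------------------------------------------------
# beta <-> M
# ---------------------------------------------------------------------------

def beta_to_m(beta, eps: float = DEFAULT_EPS):
    """M = log2(beta / (1 - beta)); beta at 0/1 clipped to ``eps`` first.

    Accepts scalars, arrays, DataFrames or a :class:`BetaMatrix`; returns the
    matching container of M values (a DataFrame for a BetaMatrix).
    """
    if isinstance(beta, BetaMatrix):
        beta = beta.frame
    arr = np.asarray(beta, dtype=float)
    n_clip = int(np.sum((arr <= 0) | (arr >= 1)))
    if n_clip:
        warnings.warn(f"{n_clip} beta value(s) at or beyond [0, 1] clipped to eps", stacklevel=2)
    clipped = np.clip(arr, eps, 1.0 - eps)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m if np.ndim(beta) else float(m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (2**M + 1)."""
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(m_to_beta(m.to_numpy()), index=m.index, columns=m.columns)
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    return out if np.ndim(m) else float(out)


# ---------------------------------------------------------------------------
# probe filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterSpec:
    """Which probe-removal criteria to apply, in a fixed order.

    Criteria are applied in the order: custom blocklist, cross-reactive,
    polymorphic, sex chromosomes, missingness, detection failure.
    """

    max_missing_fraction: float = 1.0
    detection_p_threshold: float | None = None
    max_detection_fail_fraction: float = 0.0
    drop_cross_reactive: bool = False
    drop_polymorphic: bool = False
    drop_sex_chromosomes: bool = False
    custom_blocklist: frozenset = field(default_factory=frozenset)
    drop_unannotated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise DataError("max_missing_fraction must be in [0, 1]")


def filter_probes(
    matrix: BetaMatrix,
    annotation: ProbeAnnotation | None,
    spec: FilterSpec,
    detection_p: pd.DataFrame | None = None,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Remove CpGs by annotation flags, blocklists, missingness and detection.

    Returns the filtered matrix and a report table with one row per
    criterion (criterion, n_removed, order), counting removals in
    application order (a CpG hit by several criteria counts at the first).
    """
    keep = pd.Series(True, index=matrix.cpg_ids)
    report_rows = []
    order = 0

    def _apply(criterion: str, drop_ids) -> None:
        nonlocal order
        order += 1
        drop = keep.index.isin(drop_ids) & keep.to_numpy()
        report_rows.append({"criterion": criterion, "n_removed": int(drop.sum()), "order": order})
        keep[drop] = False

    _apply("custom_blocklist", set(spec.custom_blocklist))

    if annotation is not None:
        ann_ids = set(annotation.cpg_ids)
        for flag, enabled in (
            ("cross_reactive", spec.drop_cross_reactive),
            ("polymorphic", spec.drop_polymorphic),
            ("sex_chromosome", spec.drop_sex_chromosomes),
        ):
            _apply(flag, set(annotation.flagged(flag)) if enabled else set())
        if spec.drop_unannotated:
            _apply("unannotated", [c for c in matrix.cpg_ids if c not in ann_ids])

    if spec.max_missing_fraction < 1.0:
        frac = matrix.frame.isna().mean(axis=1)
        _apply("missingness", frac.index[frac > spec.max_missing_fraction])
    if spec.detection_p_threshold is not None and detection_p is not None:
        fail = (detection_p.reindex(matrix.cpg_ids) > spec.detection_p_threshold).mean(axis=1)
        _apply("detection", fail.index[fail > spec.max_detection_fail_fraction])

    if not keep.any():
        raise DataError("filter spec removes every CpG")
    report = pd.DataFrame(report_rows)
    return BetaMatrix(matrix.frame.loc[keep]), report


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

def sample_qc(matrix: BetaMatrix, sheet: SampleSheet, outlier_k: float = 3.0) -> dict:
    """Replicate concordance and within-tissue outlier flags (advisory only).

    Replicate pairs are compared by Pearson correlation of M values.  Within
    each tissue, a sample whose mean correlation to the other samples falls
    below median − k·IQR is flagged; removal is left to the caller.
    """
    if matrix.n_samples < 2:
        raise DataError("sample QC needs at least 2 samples")
    sheet = sheet.aligned_to(matrix)
    m = beta_to_m(matrix.frame).to_numpy()

    report: dict = {"replicates": [], "outliers": [], "notes": []}
    sf = sheet.frame
    if "replicate_group" in sf.columns and sf["replicate_group"].notna().any():
        for grp, sub in sf[sf["replicate_group"].notna()].groupby("replicate_group"):
            ids = list(sub["sample_id"])
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    ia = list(matrix.sample_ids).index(ids[a])
                    ib = list(matrix.sample_ids).index(ids[b])
                    ok = ~np.isnan(m[:, ia]) & ~np.isnan(m[:, ib])
                    r = float(np.corrcoef(m[ok, ia], m[ok, ib])[0, 1])
                    report["replicates"].append(
                        {"group": str(grp), "sample_a": ids[a], "sample_b": ids[b], "pearson_r": r}
                    )
    else:
        report["notes"].append("no replicates")

    for tissue, sub in sf.groupby("tissue"):
        ids = list(sub["sample_id"])
        if len(ids) < 3:
            continue
        cols = [list(matrix.sample_ids).index(s) for s in ids]
        with np.errstate(invalid="ignore"):
            cm = np.corrcoef(m[:, cols].T)
        mean_r = (cm.sum(axis=1) - 1.0) / (len(ids) - 1)
        med = float(np.median(mean_r))
        iqr = float(np.subtract(*np.percentile(mean_r, [75, 25])))
        thresh = med - outlier_k * max(iqr, 1e-12)
        for s, r in zip(ids, mean_r):
            if r < thresh:
                report["outliers"].append(
                    {"sample_id": s, "tissue": str(tissue), "mean_r": float(r), "threshold": thresh}
                )
    return report


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Map every sample to the cross-sample mean of sorted value vectors.

    Ranks are preserved within a sample; ties receive the mean of the
    reference values across their span.  Missing values are not supported
    here (filter first).
    """
    x = frame.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise DataError("quantile normalization needs >= 2 samples")
    if np.isnan(x).any():
        raise DataError("quantile normalization requires complete data; filter missing CpGs first")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(len(order))
        col = ref[ranks]
        # ties share the mean reference value over their span
        vals, inverse, counts = np.unique(x[:, j], return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inverse, weights=col)
            col = (sums / counts)[inverse]
        out[:, j] = col
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted batch-adjustment parameters for one ComBat pass."""

    batch_variable: str
    batch_levels: list
    gamma_star: np.ndarray  # batches x features, EB-shrunk location shifts
    delta_star: np.ndarray  # batches x features, EB-shrunk scale factors
    gamma_bar: np.ndarray  # per-batch normal hyper-mean of locations
    tau_sq: np.ndarray  # per-batch normal hyper-variance
    a_prior: np.ndarray  # per-batch inverse-gamma shape
    b_prior: np.ndarray  # per-batch inverse-gamma rate
    n_iter: int


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def combat_adjust(
    frame: pd.DataFrame,
    sheet: SampleSheet,
    batch_variable: str,
    covariates: list[str] | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[pd.DataFrame, BatchModel]:
    """Parametric empirical-Bayes batch adjustment of M values.

    Per feature, a least-squares fit of the protected design plus batch
    indicators (with batch effects constrained to a weighted zero sum)
    yields residual-standardised data; batch locations are shrunk toward a
    normal prior and batch scales toward an inverse-gamma prior, both with
    method-of-moments hyperparameters estimated across features, via the
    usual fixed-point iteration.  Batch effects are then removed and the
    protected design restored.

    ``covariates`` names sample-sheet columns to protect (numeric columns
    enter as-is, others as indicator sets).
    """
    sheet = sheet.aligned_to(frame)
    sf = sheet.frame
    if batch_variable not in sf.columns:
        raise DataError(f"unknown batch variable {batch_variable!r}")
    batch = sf[batch_variable].astype(str).to_numpy()
    levels = sorted(pd.unique(batch))
    if len(levels) < 2:
        # nothing to adjust; identity with a trivial model
        model = BatchModel(batch_variable, levels, np.zeros((1, frame.shape[0])),
                           np.ones((1, frame.shape[0])), np.zeros(1), np.ones(1),
                           np.full(1, np.nan), np.full(1, np.nan), 0)
        return frame.copy(), model
    counts = np.array([(batch == lv).sum() for lv in levels])
    if (counts < 2).any():
        bad = [lv for lv, c in zip(levels, counts) if c < 2]
        raise DataError(f"batch level(s) with a single sample: {bad}")

    n_feat, n_samp = frame.shape
    Y = frame.to_numpy(dtype=float)  # features x samples
    B = np.column_stack([(batch == lv).astype(float) for lv in levels])

    # protected biological design (intercept absorbed by the batch block)
    cov_cols = []
    cov_names: list[str] = []
    for cov in covariates or []:
        col = sf[cov]
        if pd.api.types.is_numeric_dtype(col):
            v = col.astype(float).to_numpy()
            cov_cols.append(v - v.mean())
            cov_names.append(cov)
        else:
            vals = sorted(pd.unique(col.astype(str)))
            for lv in vals[1:]:
                cov_cols.append((col.astype(str) == lv).astype(float).to_numpy())
                cov_names.append(f"{cov}[{lv}]")
    C = np.column_stack(cov_cols) if cov_cols else np.empty((n_samp, 0))

    X = np.hstack([B, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError(
            f"design singular: batch {batch_variable!r} confounded with covariates {cov_names}"
        )

    beta_hat = np.linalg.lstsq(X, Y.T, rcond=None)[0]  # (n_batch + n_cov) x features
    w = counts / n_samp
    grand_mean = w @ beta_hat[: len(levels)]  # weighted zero-sum constraint
    fitted_full = (X @ beta_hat).T
    var_pooled = ((Y - fitted_full) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[:, None] * np.ones((1, n_samp))
    if C.shape[1]:
        stand_mean = stand_mean + (C @ beta_hat[len(levels):]).T
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    # per-batch location/scale estimates on standardized data
    gamma_hat = np.linalg.lstsq(B, Z.T, rcond=None)[0]  # batches x features
    delta_hat = np.vstack([Z[:, batch == lv].var(axis=1, ddof=1) for lv in levels])

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    a_pr = np.array([_aprior(delta_hat[i]) for i in range(len(levels))])
    b_pr = np.array([_bprior(delta_hat[i]) for i in range(len(levels))])

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    n_iter_total = 0
    for i, lv in enumerate(levels):
        n_i = counts[i]
        Zi = Z[:, batch == lv]
        g_old, d_old = gamma_hat[i].copy(), delta_hat[i].copy()
        for it in range(max_iter):
            g_new = (n_i * tau_sq[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                n_i * tau_sq[i] + d_old
            )
            sse = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (2.0 * b_pr[i] + sse) / (n_i + 2.0 * a_pr[i] - 2.0)
            change = max(
                np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-8)),
                np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-8)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        n_iter_total = max(n_iter_total, it + 1)
        gamma_star[i], delta_star[i] = g_old, d_old

    adjusted = Z.copy()
    for i, lv in enumerate(levels):
        sel = batch == lv
        adjusted[:, sel] = (Z[:, sel] - gamma_star[i][:, None]) / np.sqrt(delta_star[i])[:, None]
    adjusted = adjusted * sd + stand_mean

    out = pd.DataFrame(adjusted, index=frame.index, columns=frame.columns)
    model = BatchModel(
        batch_variable, levels, gamma_star, delta_star, gamma_bar, tau_sq, a_pr, b_pr,
        n_iter_total,
    )
    return out, model


def combat_sequential(
    frame: pd.DataFrame,
    sheet: SampleSheet,
    batch_variables: tuple[str, str] = ("chip_row", "chip_id"),
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, list[BatchModel]]:
    """Sequential ComBat passes, chip row then chip id by default."""
    models = []
    out = frame
    for bv in batch_variables:
        out, model = combat_adjust(out, sheet, bv, covariates=covariates)
        models.append(model)
    return out, models
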