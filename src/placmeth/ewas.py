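"""Per-CpG covariate-adjusted differential methylation.

The model is an ordinary least-squares regression fitted independently at
every CpG, by default on the M-value scale:

    M_c = b0 + b1 * primary + b2 * GA + b3 * sex + b4.. * ancestry + e

The primary-term coefficient, its (optionally empirical-Bayes moderated)
t statistic and two-sided p-value are combined with a Benjamini–Hochberg
q-value and a beta-scale effect size Δβ (mean beta in cases minus mean beta
in controls); a site is called differentially methylated when q < fdr_max
and |Δβ| > delta_beta_min.

The public surface is statsmodels-flavoured: build a :class:`CpGLinearModel`
from a beta matrix and sample sheet, call :meth:`~CpGLinearModel.fit`, and
read estimates, diagnostics and calls off the returned :class:`DMResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import BetaMatrix, DataError, SampleSheet
from .preprocess import beta_to_m


# ---------------------------------------------------------------------------
# design specification
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """What to regress on what, and on which subset.

    ``primary`` is a sample-sheet column; for a categorical primary,
    ``primary_level`` is the level coded 1 (positive coefficients mean
    higher methylation in that level) and ``baseline_level`` optionally
    restricts the comparison to two named levels.  ``covariates`` are
    additive adjustment columns (numeric used as-is, categorical expanded to
    indicators).  ``extra_indicator`` names a column expanded to a full
    indicator block (e.g. individual id for paired designs).
    """

    primary: str = "aca_status"
    primary_level: str | None = "aCA"
    baseline_level: str | None = None
    covariates: tuple[str, ...] = ("ga_weeks", "fetal_sex", "ancestry_coord_1", "ancestry_coord_2")
    extra_indicator: str | None = None
    response_scale: str = "M"
    sample_filter: Callable[[pd.DataFrame], pd.Series] | None = None
    cpg_subset: tuple[str, ...] | None = None
    moderation: str = "empirical_bayes"

    def __post_init__(self) -> None:
        if self.response_scale not in ("M", "beta"):
            raise DataError("response_scale must be 'M' or 'beta'")
        if self.moderation not in ("empirical_bayes", "none"):
            raise DataError("moderation must be 'empirical_bayes' or 'none'")


# ---------------------------------------------------------------------------
# moderation helpers (limma-style squeezing of residual variances)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of residual variances toward a common prior.

    Method of moments on log residual variances: the prior degrees of
    freedom d0 and prior variance s0² are chosen so that the observed mean
    and excess variance of log(s²) match a scaled-F model.  Returns
    (posterior variances (d0·s0² + d·s²)/(d0 + d), d0, s0²); d0 may be inf
    when the variances are effectively constant.
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    z = np.log(s2[ok])
    dg = df[ok].astype(float)
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1) - np.mean(special.polygamma(1, dg / 2.0)))
    if evar > 0:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
        post = np.full_like(s2, s0_sq)
    return post, float(d0), s0_sq


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def _build_design(sheet_frame: pd.DataFrame, design: DesignSpec) -> tuple[np.ndarray, list[str], pd.Series]:
    """Return (X, column names, analysis mask over sheet rows).

    The analysis subset keeps rows passing ``sample_filter``, belonging to
    the two compared primary levels (for a categorical primary), and
    complete in every design column.
    """
    sf = sheet_frame
    mask = pd.Series(True, index=sf.index)
    if design.sample_filter is not None:
        mask &= design.sample_filter(sf).astype(bool)

    col = sf[design.primary]
    categorical = not pd.api.types.is_numeric_dtype(col)
    if categorical:
        if design.primary_level is None:
            raise DataError("categorical primary term needs primary_level")
        levels = pd.unique(col[mask].dropna().astype(str))
        if design.baseline_level is not None:
            mask &= col.astype(str).isin([design.primary_level, design.baseline_level])
        elif len(levels) > 2:
            raise DataError(
                f"primary {design.primary!r} has {len(levels)} levels; give baseline_level"
            )

    used_cols = [design.primary, *design.covariates]
    if design.extra_indicator:
        used_cols.append(design.extra_indicator)
    for c in used_cols:
        if c not in sf.columns:
            raise DataError(f"design column {c!r} not in sample sheet")
        mask &= sf[c].notna()

    sub = sf.loc[mask]
    if categorical:
        prim = (sub[design.primary].astype(str) == design.primary_level).astype(float).to_numpy()
    else:
        prim = sub[design.primary].astype(float).to_numpy()
    if np.all(prim == prim[0] if len(prim) else True):
        raise DataError(f"primary term {design.primary!r} is constant in the analyzed subset")

    cols = [np.ones(len(sub)), prim]
    names = ["intercept", f"{design.primary}[{design.primary_level}]" if categorical else design.primary]
    for cov in design.covariates:
        c = sub[cov]
        if pd.api.types.is_numeric_dtype(c):
            cols.append(c.astype(float).to_numpy())
            names.append(cov)
        else:
            levels = sorted(pd.unique(c.astype(str)))
            for lv in levels[1:]:
                cols.append((c.astype(str) == lv).astype(float).to_numpy())
                names.append(f"{cov}[{lv}]")
    if design.extra_indicator:
        levels = sorted(pd.unique(sub[design.extra_indicator].astype(str)))
        for lv in levels[1:]:
            cols.append((sub[design.extra_indicator].astype(str) == lv).astype(float).to_numpy())
            names.append(f"{design.extra_indicator}[{lv}]")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise DataError(f"rank-deficient design; aliased columns: {aliased}")
    return X, names, mask


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-10
    return [names[j] for j in range(X.shape[1]) if diag[j] < tol]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_cpg_linear_models(
    matrix: BetaMatrix, sheet: SampleSheet, design: DesignSpec
) -> pd.DataFrame:
    """OLS per CpG; returns a table (estimate, se, t, df, p) indexed by CpG.

    CpGs with missing values are fitted on their row-wise complete cases
    with the residual degrees of freedom reduced accordingly.  With
    ``moderation='empirical_bayes'`` residual variances are squeezed toward
    a common prior and the t degrees of freedom augmented by the prior df.
    """
    sheet = sheet.aligned_to(matrix)
    work = matrix
    if design.cpg_subset is not None:
        work = matrix.select_cpgs(design.cpg_subset)
    X, names, mask = _build_design(sheet.frame, design)
    n, p = X.shape
    if n <= p + 1:
        raise DataError(f"too few samples ({n}) for {p} design columns")

    resp = work.frame.loc[:, sheet.frame.loc[mask, "sample_id"]]
    Y = beta_to_m(resp).to_numpy() if design.response_scale == "M" else resp.to_numpy()

    xtx_inv = np.linalg.inv(X.T @ X)
    j = 1  # primary-term column
    est = np.full(work.n_cpg, np.nan)
    s2 = np.full(work.n_cpg, np.nan)
    df = np.full(work.n_cpg, np.nan)
    se_unit = np.full(work.n_cpg, np.nan)  # sqrt((X'X)^-1_jj), per-CpG for missing rows

    complete = ~np.isnan(Y).any(axis=1)
    if complete.any():
        Yc = Y[complete]
        B = xtx_inv @ X.T @ Yc.T  # p x n_complete_cpgs
        resid = Yc.T - X @ B
        rss = (resid**2).sum(axis=0)
        est[complete] = B[j]
        df[complete] = n - p
        s2[complete] = rss / (n - p)
        se_unit[complete] = np.sqrt(xtx_inv[j, j])
    for i in np.where(~complete)[0]:
        ok = ~np.isnan(Y[i])
        Xi = X[ok]
        if Xi.shape[0] <= p or np.linalg.matrix_rank(Xi) < p:
            continue  # unestimable at this CpG; stays NaN
        xtxi = np.linalg.inv(Xi.T @ Xi)
        b = xtxi @ Xi.T @ Y[i, ok]
        r = Y[i, ok] - Xi @ b
        est[i] = b[j]
        df[i] = Xi.shape[0] - p
        s2[i] = (r**2).sum() / df[i]
        se_unit[i] = np.sqrt(xtxi[j, j])

    if design.moderation == "empirical_bayes":
        finite = np.isfinite(s2)
        post = s2.copy()
        post[finite], d0, s0_sq = squeeze_variances(s2[finite], df[finite])
        t_df = df + (d0 if np.isfinite(d0) else np.inf)
        var_used = post
    else:
        d0, s0_sq = 0.0, np.nan
        t_df = df
        var_used = s2

    se = np.sqrt(var_used) * se_unit
    with np.errstate(invalid="ignore", divide="ignore"):
        t = est / se
    # exact fits: zero residual variance means t = 0 for a zero estimate
    # (no evidence either way) and +-inf otherwise
    exact = (se == 0) & np.isfinite(est)
    t[exact] = np.where(np.isclose(est[exact], 0.0, atol=1e-8), 0.0,
                        np.inf * np.sign(est[exact]))
    pvals = np.full_like(t, np.nan)
    fin = np.isfinite(t) & np.isfinite(t_df)
    pvals[fin] = 2.0 * stats.t.sf(np.abs(t[fin]), t_df[fin])
    inf_df = np.isfinite(t) & np.isinf(t_df)  # d0 = inf under moderation
    pvals[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))

    out = pd.DataFrame(
        {"estimate": est, "se": se, "t": t, "df": t_df, "p": pvals},
        index=work.cpg_ids,
    )
    out.attrs["design_columns"] = names
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    out.attrs["n_samples"] = n
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN inputs propagate to NaN."""
    arr = np.asarray(p, dtype=float)
    if np.nanmin(arr, initial=0.0) < 0 or np.nanmax(arr, initial=0.0) > 1:
        raise DataError("p-values must lie in [0, 1]")
    q = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ok.any():
        q[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return q


def delta_beta(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    grouping: str = "aca_status",
    case_level: str = "aCA",
    control_level: str = "non-aCA",
) -> pd.Series:
    """Δβ = mean beta in cases − mean beta in controls, per CpG.

    Positive values mean hypermethylated in the case group.  A CpG with one
    group entirely missing gets NaN.
    """
    sheet = sheet.aligned_to(matrix)
    sf = sheet.frame
    case_ids = sf.loc[sf[grouping].astype(str) == case_level, "sample_id"]
    ctrl_ids = sf.loc[sf[grouping].astype(str) == control_level, "sample_id"]
    if not len(case_ids) or not len(ctrl_ids):
        raise DataError(f"both {case_level!r} and {control_level!r} must be present")
    mc = matrix.frame[case_ids].mean(axis=1, skipna=True)
    mn = matrix.frame[ctrl_ids].mean(axis=1, skipna=True)
    return (mc - mn).rename("delta_beta")


def call_dm_sites(
    fit_table: pd.DataFrame,
    delta: pd.Series,
    fdr_max: float = 0.15,
    delta_beta_min: float = 0.05,
) -> pd.DataFrame:
    """Joint FDR + effect-size calling: q < fdr_max and |Δβ| > delta_beta_min."""
    for name, v in (("fdr_max", fdr_max), ("delta_beta_min", delta_beta_min)):
        if not 0.0 <= v <= 1.0:
            raise DataError(f"{name} must be in [0, 1]")
    tab = fit_table.copy()
    tab["q"] = bh_adjust(tab["p"].to_numpy())
    tab["delta_beta"] = delta.reindex(tab.index)
    tab["dm_call"] = (tab["q"] < fdr_max) & (tab["delta_beta"].abs() > delta_beta_min)
    tab["direction"] = np.where(
        tab["dm_call"], np.where(tab["delta_beta"] > 0, "hyper", "hypo"), ""
    )
    tab.attrs.update(fit_table.attrs)
    tab.attrs["fdr_max"] = fdr_max
    tab.attrs["delta_beta_min"] = delta_beta_min
    return tab


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class CpGLinearModel:
    """Differential-methylation model over a cohort.

    Parameters
    ----------
    matrix
        Beta-value matrix (the response is transformed to M values unless
        the design says otherwise).
    sheet
        Sample sheet supplying the primary term and covariates.
    design
        :class:`DesignSpec`; defaults model case status adjusted for
        gestational age, fetal sex and two ancestry coordinates.
    """

    def __init__(
        self,
        matrix: BetaMatrix,
        sheet: SampleSheet,
        design: DesignSpec | None = None,
    ) -> None:
        self.matrix = matrix
        self.sheet = sheet.aligned_to(matrix)
        self.design = design or DesignSpec()

    @classmethod
    def from_dataframe(
        cls, beta: pd.DataFrame, sheet: pd.DataFrame, design: DesignSpec | None = None
    ) -> "CpGLinearModel":
        return cls(BetaMatrix(beta), SampleSheet(sheet), design)

    def fit(self, fdr_max: float = 0.15, delta_beta_min: float = 0.05) -> "DMResults":
        fit_table = fit_cpg_linear_models(self.matrix, self.sheet, self.design)
        d = self.design
        if d.primary_level is not None and not pd.api.types.is_numeric_dtype(
            self.sheet.frame[d.primary]
        ):
            levels = pd.unique(self.sheet.frame[d.primary].dropna().astype(str))
            control = d.baseline_level or next(l for l in levels if l != d.primary_level)
            work = self.matrix if d.cpg_subset is None else self.matrix.select_cpgs(d.cpg_subset)
            sub_sheet = self.sheet
            if d.sample_filter is not None:
                keep = d.sample_filter(self.sheet.frame).astype(bool)
                sub_sheet = self.sheet.subset(keep)
                work = work.select_samples(sub_sheet.frame["sample_id"])
            delta = delta_beta(work, sub_sheet, d.primary, d.primary_level, control)
        else:
            # numeric primary: report the coefficient mapped to the beta scale
            delta = pd.Series(np.nan, index=fit_table.index, name="delta_beta")
        table = call_dm_sites(fit_table, delta, fdr_max, delta_beta_min)
        return DMResults(self, table)


class DMResults:
    """Fitted per-CpG results with q-values, Δβ and DM calls.

    Attributes
    ----------
    table
        DataFrame indexed by CpG with columns estimate, se, t, df, p, q,
        delta_beta, dm_call, direction.
    """

    def __init__(self, model: CpGLinearModel, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table

    @property
    def dm_sites(self) -> pd.Index:
        return self.table.index[self.table["dm_call"].fillna(False)]

    @property
    def n_dm(self) -> int:
        return int(self.table["dm_call"].sum())

    @property
    def fdr_max(self) -> float:
        return self.table.attrs["fdr_max"]

    @property
    def delta_beta_min(self) -> float:
        return self.table.attrs["delta_beta_min"]

    def summary(self) -> str:
        t = self.table
        n_hyper = int((t["direction"] == "hyper").sum())
        n_hypo = int((t["direction"] == "hypo").sum())
        d0 = t.attrs.get("prior_df", 0.0)
        lines = [
            "Differential methylation (per-CpG linear models)",
            "=" * 52,
            f"CpGs tested:          {len(t)}",
            f"Samples analyzed:     {t.attrs.get('n_samples', 'NA')}",
            f"Design columns:       {', '.join(t.attrs.get('design_columns', []))}",
            f"Moderation prior df:  {d0:.2f}" if np.isfinite(d0) else "Moderation prior df:  inf",
            f"Thresholds:           q < {self.fdr_max}, |delta beta| > {self.delta_beta_min}",
            f"DM sites:             {self.n_dm} ({n_hyper} hyper, {n_hypo} hypo)",
        ]
        return "\n".join(lines)

    def volcano_table(self) -> pd.DataFrame:
        """Volcano-plot-ready table: Δβ, −log10 q, call."""
        t = self.table
        with np.errstate(divide="ignore"):
            neglog = -np.log10(t["q"].to_numpy(dtype=float))
        return pd.DataFrame(
            {"delta_beta": t["delta_beta"], "neg_log10_q": neglog, "dm_call": t["dm_call"],
             "direction": t["direction"]},
            index=t.index,
        )

    def to_tsv(self, path) -> None:
        cols = ["estimate", "se", "t", "df", "p", "q", "delta_beta", "dm_call", "direction"]
        self.table[cols].to_csv(path, sep="\t", index_label="cpg_id", na_rep="NA")

    def plot_volcano(self, ax=None):
        """Scatter Δβ against −log10 q, DM calls highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        v = self.volcano_table()
        base = ~v["dm_call"].fillna(False)
        ax.scatter(v.loc[base, "delta_beta"], v.loc[base, "neg_log10_q"], s=4, c="0.7")
        hyper = v["direction"] == "hyper"
        hypo = v["direction"] == "hypo"
        ax.scatter(v.loc[hyper, "delta_beta"], v.loc[hyper, "neg_log10_q"], s=6, c="firebrick")
        ax.scatter(v.loc[hypo, "delta_beta"], v.loc[hypo, "neg_log10_q"], s=6, c="steelblue")
        ax.set_xlabel("delta beta (case - control)")
        ax.set_ylabel("-log10 q")
        return ax
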