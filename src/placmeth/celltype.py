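"""Immune-cell-type signatures and signature-based sample clustering.

The cell-type analysis asks whether bulk placental methylation carries the
imprint of infiltrating immune cells:

* A cell type's *signature* is the set of CpGs differentially methylated
  between that cell type and chorionic villi AND between it and every other
  immune class — sites that distinguish the cell type from both the tissue
  and its haematopoietic neighbours.
* *Trend concordance* checks whether case-vs-control methylation shifts at
  DM sites point in the same direction as cell-vs-control shifts, against
  both a binomial(0.5) null and an empirical random-CpG-set null.
* Samples are clustered on signature CpGs (Euclidean, average linkage by
  default).  Cluster support uses pvclust-style multiscale bootstrap of the
  features: bootstrap probabilities (BP) at several resampling scales are
  extrapolated to an approximately unbiased (AU) support value per node.
  A Monte-Carlo cluster-index test (diagonal-covariance Gaussian null)
  scores the significance of the two-way split, and a Fisher exact test
  measures enrichment of a phenotype across the two clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .covariates import compare_group_covariates, fisher_exact_2x2
from .data import BetaMatrix, DataError, SampleSheet, IMMUNE_CELL_TYPES
from .ewas import CpGLinearModel, DesignSpec, DMResults
from .preprocess import beta_to_m


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

@dataclass
class CellSignature:
    """CpGs specific to one cell type, with per-contrast evidence.

    ``evidence`` is indexed by CpG over the union of contrast DM sets with
    a (q, delta_beta) column pair per contrast; ``specific_cpg_ids`` is the
    intersection across all contrasts.
    """

    cell_type: str
    specific_cpg_ids: list[str]
    evidence: pd.DataFrame
    fdr_max: float
    delta_beta_min: float
    contrasts: list[str]

    def __len__(self) -> int:
        return len(self.specific_cpg_ids)

    def to_tsv(self, path) -> None:
        self.evidence.loc[self.specific_cpg_ids].to_csv(
            path, sep="\t", index_label="cpg_id", na_rep="NA"
        )


def derive_cell_specific_cpgs(
    reference: BetaMatrix,
    ref_sheet: SampleSheet,
    cell_type: str,
    fdr_max: float = 0.05,
    delta_beta_min: float = 0.20,
    villi_label: str = "chorionic_villi",
) -> CellSignature:
    """Intersect DM sets of the target cell type against villi and each other
    immune class.

    The reference sheet must carry a ``cell_type`` column covering the
    target, ``villi_label`` and every other immune class; each contrast is a
    two-group differential-methylation run (moderated M-value regression,
    no covariates) at the given thresholds, and the signature is the set of
    CpGs DM in *all* contrasts.
    """
    sf = ref_sheet.frame
    if "cell_type" not in sf.columns:
        raise DataError("reference sheet needs a 'cell_type' column")
    present = set(sf["cell_type"].dropna())
    if cell_type not in IMMUNE_CELL_TYPES:
        raise DataError(f"unknown immune cell type {cell_type!r}")
    partners = [villi_label] + [t for t in IMMUNE_CELL_TYPES if t != cell_type]
    missing = [p for p in [cell_type, *partners] if p not in present]
    if missing:
        raise DataError(f"missing contrast class(es): {missing}")
    for cls in [cell_type, *partners]:
        if (sf["cell_type"] == cls).sum() < 2:
            raise DataError(f"contrast class {cls!r} has fewer than 2 samples")

    dm_sets: list[set[str]] = []
    evid: dict[str, pd.Series] = {}
    contrasts = []
    for partner in partners:
        name = f"{cell_type}_vs_{partner}"
        contrasts.append(name)
        keep_ids = list(sf.loc[sf["cell_type"].isin([cell_type, partner]), "sample_id"])
        design = DesignSpec(
            primary="cell_type",
            primary_level=cell_type,
            baseline_level=partner,
            covariates=(),
            sample_filter=lambda f, ids=tuple(keep_ids): f["sample_id"].isin(ids),
        )
        res = CpGLinearModel(reference, ref_sheet, design).fit(
            fdr_max=fdr_max, delta_beta_min=delta_beta_min
        )
        dm_sets.append(set(res.dm_sites))
        evid[f"{name}:q"] = res.table["q"]
        evid[f"{name}:delta_beta"] = res.table["delta_beta"]

    specific = set.intersection(*dm_sets) if dm_sets else set()
    union = sorted(set.union(*dm_sets)) if dm_sets else []
    evidence = pd.DataFrame(evid).loc[union] if union else pd.DataFrame(evid)
    return CellSignature(
        cell_type=cell_type,
        specific_cpg_ids=sorted(specific),
        evidence=evidence,
        fdr_max=fdr_max,
        delta_beta_min=delta_beta_min,
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# trend concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    """Direction agreement of case shifts with a cell-type reference."""

    n_evaluable: int
    n_concordant: int
    fraction: float
    binomial_p: float
    empirical_p: float
    n_dropped_absent: int  # DM sites missing from the reference platform
    n_dropped_tied: int  # exactly zero direction on either side
    per_site: pd.DataFrame
    n_draws: int

    def summary(self) -> str:
        return (
            f"{self.n_concordant}/{self.n_evaluable} "
            f"({self.fraction:.1%}) DM sites concordant with the reference; "
            f"binomial p = {self.binomial_p:.3g}, empirical p = {self.empirical_p:.3g}"
        )


def trend_concordance_test(
    dm_site_ids,
    villi: BetaMatrix,
    villi_sheet: SampleSheet,
    reference: BetaMatrix,
    n_draws: int = 10_000,
    seed: int = 0,
    grouping: str = "aca_status",
    case_level: str = "aCA",
    control_level: str = "non-aCA",
) -> ConcordanceResult:
    """Do DM sites shift in the same direction in cases and in the cell type?

    Per site, direction_a = sign(mean beta case − mean beta control) and
    direction_b = sign(mean beta reference − mean beta control villi); the
    site is concordant when both are nonzero and equal.  DM sites absent
    from the reference are dropped and counted.  Alongside the binomial(0.5)
    tail p, an empirical p draws ``n_draws`` random same-size CpG sets from
    the background shared by both platforms and recomputes the concordant
    fraction each time.
    """
    dm_ids = pd.Index(dm_site_ids)
    if not len(dm_ids):
        raise DataError("empty DM site set")
    background = villi.cpg_ids.intersection(reference.cpg_ids)
    avail = dm_ids.intersection(background)
    n_absent = int(len(dm_ids) - len(avail))
    if not len(avail):
        raise DataError("no DM site available on the reference platform")

    sf = villi_sheet.aligned_to(villi).frame
    case_ids = sf.loc[sf[grouping].astype(str) == case_level, "sample_id"]
    ctrl_ids = sf.loc[sf[grouping].astype(str) == control_level, "sample_id"]
    case_mean = villi.frame.loc[background, case_ids].mean(axis=1)
    ctrl_mean = villi.frame.loc[background, ctrl_ids].mean(axis=1)
    ref_mean = reference.frame.loc[background].mean(axis=1)

    dir_a = np.sign(case_mean - ctrl_mean)
    dir_b = np.sign(ref_mean - ctrl_mean)
    evaluable = (dir_a != 0) & (dir_b != 0)
    concordant = evaluable & (dir_a == dir_b)

    sel = background.get_indexer(avail)
    ev = evaluable.to_numpy()[sel]
    co = concordant.to_numpy()[sel]
    n_eval = int(ev.sum())
    n_conc = int(co.sum())
    n_tied = int(len(avail) - n_eval)
    if n_eval == 0:
        raise DataError("zero evaluable sites (all directions tied)")
    frac = n_conc / n_eval
    binom_p = float(stats.binomtest(n_conc, n_eval, 0.5, alternative="greater").pvalue)

    rng = np.random.default_rng(seed)
    ev_all = evaluable.to_numpy()
    co_all = concordant.to_numpy()
    m = len(avail)
    n_ge = 0
    for _ in range(n_draws):
        idx = rng.choice(len(background), size=m, replace=False)
        ne = ev_all[idx].sum()
        if ne and co_all[idx].sum() / ne >= frac:
            n_ge += 1
    emp_p = (1.0 + n_ge) / (n_draws + 1.0)

    per_site = pd.DataFrame(
        {
            "direction_case": dir_a.to_numpy()[sel],
            "direction_reference": dir_b.to_numpy()[sel],
            "concordant": co,
        },
        index=avail,
    )
    return ConcordanceResult(
        n_evaluable=n_eval,
        n_concordant=n_conc,
        fraction=frac,
        binomial_p=binom_p,
        empirical_p=emp_p,
        n_dropped_absent=n_absent,
        n_dropped_tied=n_tied,
        per_site=per_site,
        n_draws=n_draws,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _sample_matrix(matrix: BetaMatrix, signature_cpgs, scale: str) -> np.ndarray:
    """Samples-by-features array restricted to the signature CpGs."""
    if signature_cpgs is not None:
        ids = pd.Index(signature_cpgs)
        if not len(ids):
            raise DataError("empty signature CpG set")
        sub = matrix.select_cpgs(ids).frame
    else:
        sub = matrix.frame
    if sub.isna().any().any():
        raise DataError("clustering requires complete data over the signature CpGs")
    X = sub.to_numpy().T
    if scale == "M":
        X = beta_to_m(X)
    return X


def _node_masks(Z: np.ndarray, n: int) -> list[int]:
    """Leaf-set bitmasks of the internal nodes, in linkage merge order."""
    masks = [1 << i for i in range(n)]
    out = []
    for a, b, *_ in Z:
        m = masks[int(a)] | masks[int(b)]
        masks.append(m)
        out.append(m)
    return out


@dataclass
class ClusterTree:
    """Agglomerative clustering of samples on signature CpGs."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray
    method: str
    metric: str
    assignments_k2: pd.Series  # sample_id -> 1/2

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def node_leafsets(self) -> list[frozenset]:
        return [
            frozenset(self.sample_ids[i] for i in range(self.n_samples) if m >> i & 1)
            for m in _node_masks(self.linkage_matrix, self.n_samples)
        ]


def hierarchical_cluster(
    matrix: BetaMatrix,
    signature_cpgs=None,
    method: str = "average",
    metric: str = "euclidean",
    scale: str = "beta",
) -> ClusterTree:
    """Deterministic agglomerative clustering of samples; k=2 cut included.

    Distances are Euclidean over the signature CpGs on the beta scale by
    default (``scale='M'`` clusters M values).  Ties in merge distance
    resolve to the lowest pair index (scipy's deterministic order).
    """
    if matrix.n_samples < 2:
        raise DataError("clustering needs at least 2 samples")
    X = _sample_matrix(matrix, signature_cpgs, scale)
    Z = scipy_linkage(X, method=method, metric=metric)
    k2 = fcluster(Z, 2, criterion="maxclust")
    return ClusterTree(
        sample_ids=list(matrix.sample_ids),
        linkage_matrix=Z,
        method=method,
        metric=metric,
        assignments_k2=pd.Series(k2, index=matrix.sample_ids, name="cluster"),
    )


def multiscale_bootstrap_au(
    matrix: BetaMatrix,
    signature_cpgs=None,
    method: str = "average",
    metric: str = "euclidean",
    scale_values: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    scale: str = "beta",
    tree: ClusterTree | None = None,
) -> pd.DataFrame:
    """Per-node BP and AU support via multiscale bootstrap of the CpGs.

    For each scale r the CpGs (features) are resampled with replacement to
    round(r·n_cpg) and the samples reclustered; BP_r of a node is the
    fraction of bootstrap trees containing its exact leaf set.  The probit
    transforms z_r = Φ⁻¹(1 − BP_r) are regressed on (√r, 1/√r) by weighted
    least squares with binomial-variance weights, giving signed distance v
    and curvature c; AU = 1 − Φ(v − c).  The BP column reports the plain
    bootstrap proportion at r = 1.  A node never recovered at any scale is
    flagged and assigned AU 0.
    """
    if n_boot < 100:
        raise DataError("n_boot must be >= 100")
    scales = np.linspace(0.5, 1.4, 10) if scale_values is None else np.asarray(scale_values, float)
    if scales.size < 2:
        raise DataError("need >= 2 bootstrap scales")
    X = _sample_matrix(matrix, signature_cpgs, scale)
    n, p = X.shape
    if tree is None:
        tree = hierarchical_cluster(matrix, signature_cpgs, method, metric, scale)
    obs_masks = _node_masks(tree.linkage_matrix, n)
    node_index = {m: i for i, m in enumerate(obs_masks)}
    n_nodes = len(obs_masks)

    rng = np.random.default_rng(seed)
    bp = np.zeros((scales.size, n_nodes))
    for si, r in enumerate(scales):
        size = max(int(round(r * p)), 2)
        hits = np.zeros(n_nodes)
        for _ in range(n_boot):
            idx = rng.integers(0, p, size)
            Zb = scipy_linkage(X[:, idx], method=method, metric=metric)
            for m in _node_masks(Zb, n):
                j = node_index.get(m)
                if j is not None:
                    hits[j] += 1
        bp[si] = hits / n_boot

    # probit extrapolation per node
    lo, hi = 0.5 / n_boot, 1.0 - 0.5 / n_boot
    sq = np.sqrt(scales)
    au = np.zeros(n_nodes)
    v_fit = np.full(n_nodes, np.nan)
    c_fit = np.full(n_nodes, np.nan)
    flags = np.zeros(n_nodes, dtype=bool)
    r1 = int(np.argmin(np.abs(scales - 1.0)))
    for j in range(n_nodes):
        bpj = bp[:, j]
        if bpj.max() == 0.0:
            flags[j] = True
            au[j] = 0.0
            continue
        if bpj.min() >= hi:  # recovered in essentially every tree at all scales
            au[j] = 1.0
            continue
        pb = np.clip(bpj, lo, hi)
        z = stats.norm.ppf(1.0 - pb)
        w = n_boot * stats.norm.pdf(z) ** 2 / (pb * (1.0 - pb))
        A = np.column_stack([sq, 1.0 / sq])
        WA = A * w[:, None]
        coef, *_ = np.linalg.lstsq(WA.T @ A, WA.T @ z, rcond=None)
        v, c = coef
        v_fit[j], c_fit[j] = v, c
        au[j] = float(1.0 - stats.norm.cdf(v - c))

    leafsets = tree.node_leafsets()
    return pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "n_leaves": [len(s) for s in leafsets],
            "leaf_set": [",".join(sorted(s)) for s in leafsets],
            "bp": bp[r1],
            "au": au,
            "v": v_fit,
            "c": c_fit,
            "never_observed": flags,
        }
    )


def root_split_support(tree: ClusterTree, support: pd.DataFrame) -> list[float | None]:
    """AU values of the two children of the dendrogram root.

    A leaf child (singleton split) has no node support and is reported as
    None; a two-cluster structure counts as AU-stable only when both
    children are internal nodes with AU at or above the chosen level.
    """
    Z, n = tree.linkage_matrix, tree.n_samples
    au = support["au"].to_numpy()
    out: list[float | None] = []
    for side in (0, 1):
        child = int(Z[-1, side])
        out.append(float(au[child - n]) if child >= n else None)
    return out


def cluster_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Two-cluster index: within-split sum of squares / total sum of squares."""
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    if total == 0:
        return 1.0
    within = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return within / total


def cluster_significance(
    matrix: BetaMatrix,
    signature_cpgs=None,
    labels: pd.Series | None = None,
    n_sim: int = 1000,
    seed: int = 0,
    method: str = "average",
    metric: str = "euclidean",
    scale: str = "beta",
) -> tuple[float, float]:
    """Monte-Carlo significance of a two-way split (cluster-index statistic).

    The observed statistic is the cluster index of the k=2 split (given as
    ``labels`` or taken from the dendrogram cut).  Null datasets of the same
    shape are drawn from a single Gaussian with diagonal covariance equal to
    the per-CpG sample variances, clustered identically, and their best
    two-split cluster index recorded; p = (1 + #{null CI ≤ observed}) /
    (n_sim + 1).  Returns (observed CI, p).
    """
    if n_sim < 100:
        raise DataError("n_sim must be >= 100")
    X = _sample_matrix(matrix, signature_cpgs, scale)
    n = X.shape[0]
    if labels is None:
        labels = hierarchical_cluster(matrix, signature_cpgs, method, metric, scale).assignments_k2
    lab = labels.reindex(matrix.sample_ids).to_numpy()
    sizes = pd.Series(lab).value_counts()
    if len(sizes) != 2 or sizes.min() < 2:
        raise DataError("split must have two sides with >= 2 samples each")
    ci_obs = cluster_index(X, lab)

    sd = X.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_sim):
        Xn = rng.normal(0.0, 1.0, X.shape) * sd
        Zn = scipy_linkage(Xn, method=method, metric=metric)
        ln = fcluster(Zn, 2, criterion="maxclust")
        ci_null = 1.0 if len(np.unique(ln)) < 2 else cluster_index(Xn, ln)
        if ci_null <= ci_obs:
            n_le += 1
    p = (1.0 + n_le) / (n_sim + 1.0)
    return ci_obs, p


# ---------------------------------------------------------------------------
# enrichment + report
# ---------------------------------------------------------------------------

def cluster_phenotype_enrichment(
    assignments: pd.Series,
    sheet: SampleSheet,
    phenotype: str = "aca_status",
    continuous: tuple[str, ...] = ("ga_weeks",),
    categorical: tuple[str, ...] = ("fetal_sex",),
) -> dict:
    """2x2 cluster-by-phenotype table with Fisher exact p, plus per-cluster
    comparisons of the remaining clinical covariates."""
    sf = (sheet.frame.set_index("sample_id").loc[assignments.index]
          .rename_axis("sample_id").reset_index())
    sf["cluster"] = assignments.to_numpy()
    clusters = sorted(sf["cluster"].unique())
    if len(clusters) != 2:
        raise DataError("enrichment needs exactly two clusters")
    levels = sorted(sf[phenotype].dropna().astype(str).unique())
    if len(levels) != 2:
        raise DataError(f"phenotype {phenotype!r} must have two levels")
    tab = [
        [
            int(((sf["cluster"] == c) & (sf[phenotype].astype(str) == lv)).sum())
            for lv in levels
        ]
        for c in clusters
    ]
    if min(sum(row) for row in tab) == 0:
        raise DataError("empty cluster")
    p = fisher_exact_2x2(tab)
    demo = compare_group_covariates(
        SampleSheet(sf), grouping="cluster", continuous=continuous, categorical=categorical
    )
    return {
        "table": tab,
        "clusters": [str(c) for c in clusters],
        "phenotype_levels": levels,
        "fisher_p": p,
        "covariate_comparisons": demo,
    }


@dataclass
class ClusterReport:
    """Full clustering report: tree, node support, split p, enrichment."""

    tree: ClusterTree
    node_support: pd.DataFrame
    split_ci: float
    split_p: float
    enrichment: dict

    def to_json(self, path) -> None:
        payload = {
            "sample_ids": self.tree.sample_ids,
            "method": self.tree.method,
            "metric": self.tree.metric,
            "linkage": self.tree.linkage_matrix.tolist(),
            "assignments_k2": {
                s: int(c) for s, c in self.tree.assignments_k2.items()
            },
            "node_support": self.node_support.drop(columns=["leaf_set"]).to_dict("records"),
            "split_cluster_index": self.split_ci,
            "split_p": self.split_p,
            "enrichment": {
                k: (v.to_dict("records") if isinstance(v, pd.DataFrame) else v)
                for k, v in self.enrichment.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_newick(self) -> str:
        """Dendrogram as Newick with AU/BP node annotations."""
        Z = self.tree.linkage_matrix
        ids = self.tree.sample_ids
        n = len(ids)
        au = self.node_support["au"].to_numpy()
        bp = self.node_support["bp"].to_numpy()
        heights = Z[:, 2]

        def render(node: int, parent_h: float) -> str:
            if node < n:
                return f"{ids[node]}:{parent_h:.6g}"
            k = node - n
            h = heights[k]
            left = render(int(Z[k, 0]), h)
            right = render(int(Z[k, 1]), h)
            label = f"au{au[k]:.2f}_bp{bp[k]:.2f}"
            return f"({left},{right}){label}:{max(parent_h - h, 0.0):.6g}"

        root = 2 * n - 2
        return render(root, heights[-1]) + ";"
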