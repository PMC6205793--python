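"""Cell-type signatures, concordance, clustering support and enrichment."""

import numpy as np
import pandas as pd
import pytest

from placmeth.celltype import (
    cluster_index,
    cluster_phenotype_enrichment,
    cluster_significance,
    derive_cell_specific_cpgs,
    hierarchical_cluster,
    multiscale_bootstrap_au,
    trend_concordance_test,
    ClusterReport,
)
from placmeth.data import BetaMatrix, DataError, SampleSheet
from placmeth.simulate import (
    SimConfig,
    generate_cohort,
    generate_reference_profiles,
    generate_reference_samples,
    _planted_sets,
)
from tests.conftest import villi_subset


def _beta(frame_dict, index) -> BetaMatrix:
    return BetaMatrix(pd.DataFrame(frame_dict, index=index))


def _ref_sheet(cell_types) -> SampleSheet:
    rows = []
    for i, ct in enumerate(cell_types):
        rows.append({"sample_id": f"s{i}", "tissue": "chorionic_villi",
                     "aca_status": pd.NA, "ga_weeks": pd.NA, "fetal_sex": "F",
                     "chip_id": "c", "chip_row": "r", "cell_type": ct})
    return SampleSheet(pd.DataFrame(rows))


class TestSignatureDerivation:
    def test_toy_intersection_keeps_only_site_dm_in_all_contrasts(self):
        """CpG1 separates neutrophils everywhere; CpG2 fails one contrast."""
        rng = np.random.default_rng(0)
        classes = (["neutrophil"] * 3 + ["chorionic_villi"] * 3 + ["eosinophil"] * 3
                   + ["monocyte"] * 3 + ["lymphoid"] * 3)
        base = {"cg1": 0.1, "cg2": 0.1, "cg3": 0.5}
        cols = {}
        for i, ct in enumerate(classes):
            v = np.array([base["cg1"], base["cg2"], base["cg3"]])
            if ct == "neutrophil":
                v[0] = 0.9
                v[1] = 0.9
            if ct == "eosinophil":
                v[1] = 0.9  # cg2 not DM in neutrophil-vs-eosinophil
            cols[f"s{i}"] = np.clip(v + rng.normal(0, 0.005, 3), 0.001, 0.999)
        matrix = _beta(cols, ["cg1", "cg2", "cg3"])
        sig = derive_cell_specific_cpgs(matrix, _ref_sheet(classes), "neutrophil",
                                        fdr_max=0.05, delta_beta_min=0.2)
        assert sig.specific_cpg_ids == ["cg1"]

    def test_no_planted_sites_gives_empty_signature(self):
        cfg = SimConfig(n_cpg=1000, n_tissue_specific=0, n_celltype_specific=0,
                        n_ga_effect=0, n_sex_effect=0, seed=2)
        ref, ref_sheet = generate_reference_samples(cfg)
        sig = derive_cell_specific_cpgs(ref, ref_sheet, "neutrophil")
        assert len(sig) == 0

    def test_planted_sites_recovered_without_cross_contamination(self):
        cfg = SimConfig(n_cpg=20000, effect_delta=0.25, seed=7)
        ref, ref_sheet = generate_reference_samples(cfg)
        sets = _planted_sets(cfg, generate_reference_profiles(cfg))
        sig = derive_cell_specific_cpgs(ref, ref_sheet, "neutrophil")
        planted = set(sets["celltype_specific:neutrophil"])
        assert len(planted & set(sig.specific_cpg_ids)) >= 45
        for other in ("eosinophil", "monocyte", "lymphoid"):
            assert not set(sets[f"celltype_specific:{other}"]) & set(sig.specific_cpg_ids)

    def test_tightening_thresholds_never_grows_signature(self):
        cfg = SimConfig(n_cpg=3000, n_celltype_specific=40, effect_delta=0.25,
                        n_tissue_specific=0, n_ga_effect=0, n_sex_effect=0, seed=9)
        ref, ref_sheet = generate_reference_samples(cfg)
        loose = derive_cell_specific_cpgs(ref, ref_sheet, "monocyte",
                                          fdr_max=0.10, delta_beta_min=0.10)
        tight = derive_cell_specific_cpgs(ref, ref_sheet, "monocyte",
                                          fdr_max=0.01, delta_beta_min=0.25)
        assert set(tight.specific_cpg_ids) <= set(loose.specific_cpg_ids)

    def test_missing_contrast_class_listed(self):
        classes = ["neutrophil"] * 3 + ["chorionic_villi"] * 3 + ["eosinophil"] * 3
        rng = np.random.default_rng(1)
        matrix = _beta({f"s{i}": rng.uniform(0.2, 0.8, 5) for i in range(9)},
                       [f"cg{i}" for i in range(5)])
        with pytest.raises(DataError, match="monocyte"):
            derive_cell_specific_cpgs(matrix, _ref_sheet(classes), "neutrophil")


@pytest.fixture(scope="module")
def mixture_cohort():
    cfg = SimConfig(n_cpg=4000, n_celltype_specific=50, n_tissue_specific=0,
                    n_ga_effect=0, n_sex_effect=0,
                    mixture_fraction_range=(0.3, 0.3), seed=13)
    return generate_cohort(cfg)


class TestTrendConcordance:
    def test_reference_equal_to_case_means_is_fully_concordant(self):
        rng = np.random.default_rng(4)
        n = 200
        case = rng.uniform(0.2, 0.8, n)
        ctrl = np.clip(case + rng.choice([-0.1, 0.1], n), 0.05, 0.95)
        villi = _beta({"a1": case, "a2": case, "n1": ctrl, "n2": ctrl},
                      [f"cg{i}" for i in range(n)])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": ["a1", "a2", "n1", "n2"],
            "tissue": "chorionic_villi",
            "aca_status": ["aCA", "aCA", "non-aCA", "non-aCA"],
            "ga_weeks": 30.0, "fetal_sex": "F", "chip_id": "c", "chip_row": "r"}))
        ref = _beta({"r1": case, "r2": case}, list(villi.cpg_ids))
        res = trend_concordance_test(villi.cpg_ids[:50], villi, sheet, ref,
                                     n_draws=1000, seed=0)
        assert res.fraction == 1.0

    def test_independent_reference_near_half(self, mixture_cohort):
        matrix, sheet, truth = mixture_cohort
        villi, vsheet = villi_subset(matrix, sheet)
        rng = np.random.default_rng(8)
        ref = _beta({"r1": rng.uniform(0.05, 0.95, villi.n_cpg),
                     "r2": rng.uniform(0.05, 0.95, villi.n_cpg)}, list(villi.cpg_ids))
        dm = list(villi.cpg_ids[:300])
        res = trend_concordance_test(dm, villi, vsheet, ref, n_draws=1000, seed=1)
        assert 0.4 < res.fraction < 0.6

    def test_neutrophil_mixture_drives_concordance(self, mixture_cohort):
        matrix, sheet, truth = mixture_cohort
        villi, vsheet = villi_subset(matrix, sheet)
        profiles = truth.reference_profiles
        ref = BetaMatrix(profiles[["neutrophil"]].rename(columns={"neutrophil": "r1"}))
        dm = truth.planted_ids("celltype_specific:neutrophil")
        res = trend_concordance_test(dm, villi, vsheet, ref, n_draws=2000, seed=2)
        assert res.fraction > 0.5
        assert res.binomial_p < 0.01
        assert res.empirical_p < 0.01

    def test_sites_absent_from_reference_are_dropped_and_counted(self, mixture_cohort):
        matrix, sheet, truth = mixture_cohort
        villi, vsheet = villi_subset(matrix, sheet)
        sub_ref = BetaMatrix(truth.reference_profiles[["neutrophil"]]
                             .rename(columns={"neutrophil": "r1"}).iloc[: villi.n_cpg // 2])
        dm = list(villi.cpg_ids[:100])
        res = trend_concordance_test(dm, villi, vsheet, sub_ref, n_draws=1000, seed=3)
        n_present = sum(1 for c in dm if c in set(sub_ref.cpg_ids))
        assert res.n_dropped_absent == 100 - n_present


class TestHierarchicalClustering:
    def test_two_samples_merge_at_their_distance(self):
        m = _beta({"a": [0.1, 0.1], "b": [0.3, 0.3]}, ["cg1", "cg2"])
        tree = hierarchical_cluster(m)
        assert tree.linkage_matrix.shape == (1, 4)
        assert tree.linkage_matrix[0, 2] == pytest.approx(np.sqrt(2 * 0.2**2))

    def test_three_collinear_points_average_linkage(self):
        # 1-D configuration (0), (1), (10): first merge {0,1} at 1, then at 9.5
        frame = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [10.0]}, index=["cg1"])
        # use raw values via a matrix in [0,1]: scale by 1/10 and check heights x10
        scaled = BetaMatrix(frame / 10.0)
        tree = hierarchical_cluster(scaled)
        Z = tree.linkage_matrix
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] * 10 == pytest.approx(1.0)
        assert Z[1, 2] * 10 == pytest.approx(9.5)

    def test_duplicated_sample_merges_first_at_zero_height(self, small_cohort):
        matrix, sheet, _ = small_cohort
        villi, _ = villi_subset(matrix, sheet)
        frame = villi.frame.iloc[:, :6].copy()
        frame["dup"] = frame.iloc[:, 0]
        tree = hierarchical_cluster(BetaMatrix(frame))
        Z = tree.linkage_matrix
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 6}

    def test_k2_partition_covers_all_samples(self, small_cohort):
        matrix, sheet, _ = small_cohort
        villi, _ = villi_subset(matrix, sheet)
        tree = hierarchical_cluster(villi, list(villi.cpg_ids[:100]))
        assert set(tree.assignments_k2.index) == set(villi.sample_ids)
        assert set(tree.assignments_k2.unique()) == {1, 2}

    def test_empty_signature_rejected(self, small_cohort):
        matrix, _, _ = small_cohort
        with pytest.raises(DataError, match="empty signature"):
            hierarchical_cluster(matrix, [])


def _two_cluster_matrix(n_feat=400, n_per=15, sep=0.25, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.3, 0.7, n_feat)
    cols = {}
    for j in range(n_per):
        cols[f"a{j}"] = np.clip(base + rng.normal(0, 0.03, n_feat), 0.01, 0.99)
    for j in range(n_per):
        cols[f"b{j}"] = np.clip(base + sep + rng.normal(0, 0.03, n_feat), 0.01, 0.99)
    return BetaMatrix(pd.DataFrame(cols, index=[f"cg{i}" for i in range(n_feat)]))


class TestBootstrapSupport:
    def test_separated_clusters_get_high_au_and_bp(self):
        m = _two_cluster_matrix()
        tree = hierarchical_cluster(m)
        sup = multiscale_bootstrap_au(m, n_boot=200, seed=1, tree=tree)
        Z, n = tree.linkage_matrix, m.n_samples
        kids = [int(Z[-1, s]) - n for s in (0, 1) if int(Z[-1, s]) >= n]
        assert len(kids) == 2
        assert (sup["au"].to_numpy()[kids] >= 0.95).all()
        assert (sup["bp"].to_numpy()[kids] >= 0.9).all()

    def test_bp_at_unit_scale_equals_plain_bootstrap(self):
        """BP at r=1 is the plain bootstrap proportion, by definition."""
        from scipy.cluster.hierarchy import linkage as scipy_linkage

        from placmeth.celltype import _node_masks

        m = _two_cluster_matrix(n_feat=200, sep=0.12, seed=3)
        tree = hierarchical_cluster(m)
        sup = multiscale_bootstrap_au(m, scale_values=np.array([0.7, 1.0, 1.3]),
                                      n_boot=400, seed=5, tree=tree)
        # independent plain bootstrap at r = 1 with a different seed
        X = m.frame.to_numpy().T
        n, p = X.shape
        obs = _node_masks(tree.linkage_matrix, n)
        idx_of = {mask: i for i, mask in enumerate(obs)}
        rng = np.random.default_rng(123)
        hits = np.zeros(len(obs))
        n_boot = 400
        for _ in range(n_boot):
            Zb = scipy_linkage(X[:, rng.integers(0, p, p)], method="average")
            for mask in _node_masks(Zb, n):
                j = idx_of.get(mask)
                if j is not None:
                    hits[j] += 1
        plain = hits / n_boot
        se = np.sqrt(np.maximum(plain * (1 - plain), 0.25 / n_boot) / n_boot) * 2
        mc_tol = 4 * se + 0.02
        assert (np.abs(sup["bp"].to_numpy() - plain) <= mc_tol).all()

    def test_minimum_iterations_enforced(self, small_cohort):
        matrix, _, _ = small_cohort
        with pytest.raises(DataError, match="n_boot"):
            multiscale_bootstrap_au(matrix, list(matrix.cpg_ids[:10]), n_boot=10)


class TestClusterSignificance:
    def test_cluster_index_definition(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        labels = np.array([1, 1, 2, 2])
        assert cluster_index(X, labels) == pytest.approx(0.0)
        assert cluster_index(X, np.array([1, 2, 1, 2])) == pytest.approx(1.0)

    def test_separated_clusters_significant(self):
        m = _two_cluster_matrix(seed=7)
        ci, p = cluster_significance(m, n_sim=300, seed=2)
        assert p <= 0.01
        assert ci < 0.5

    def test_identical_split_sides_give_p_near_one(self):
        # the two split sides are identical point sets: the split explains
        # nothing (CI = 1) and any noisy null does better
        vals = np.tile(np.linspace(0.2, 0.8, 6), (50, 1))
        frame = pd.DataFrame(np.hstack([vals, vals]),
                             index=[f"cg{i}" for i in range(50)],
                             columns=[f"s{j}" for j in range(12)])
        labels = pd.Series([1] * 6 + [2] * 6, index=frame.columns)
        ci, p = cluster_significance(BetaMatrix(frame), labels=labels,
                                     n_sim=200, seed=3)
        assert ci == pytest.approx(1.0)
        assert p > 0.9

    def test_single_cloud_not_significant_at_fixed_seed(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(rng.uniform(0.3, 0.7, (200, 20)),
                             index=[f"cg{i}" for i in range(200)],
                             columns=[f"s{j}" for j in range(20)])
        labels = pd.Series([1] * 10 + [2] * 10, index=frame.columns)
        _, p = cluster_significance(BetaMatrix(frame), labels=labels,
                                    n_sim=300, seed=4)
        assert p > 0.05


class TestEnrichment:
    def test_balanced_table_gives_p_one(self, small_cohort):
        _, sheet, _ = small_cohort
        villi = sheet.subset(sheet.frame["tissue"] == "chorionic_villi")
        ids = list(villi.frame["sample_id"])
        # alternate clusters within each status: perfectly balanced
        status = villi.frame.set_index("sample_id")["aca_status"]
        assign = {}
        for lv in ("aCA", "non-aCA"):
            members = [s for s in ids if status[s] == lv]
            for i, s in enumerate(members):
                assign[s] = 1 + (i % 2)
        res = cluster_phenotype_enrichment(pd.Series(assign), villi)
        assert res["fisher_p"] == pytest.approx(1.0)

    def test_perfect_separation_matches_enumeration(self):
        from tests.test_covariates import fisher_two_sided_oracle

        sheet = SampleSheet(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(10)],
            "tissue": "chorionic_villi",
            "aca_status": ["aCA"] * 5 + ["non-aCA"] * 5,
            "ga_weeks": 30.0, "fetal_sex": "F", "chip_id": "c", "chip_row": "r"}))
        assign = pd.Series([1] * 5 + [2] * 5, index=sheet.frame["sample_id"])
        res = cluster_phenotype_enrichment(assign, sheet)
        assert res["fisher_p"] == pytest.approx(2 / 252)
        assert res["fisher_p"] == pytest.approx(fisher_two_sided_oracle(res["table"]))

    def test_report_roundtrip_and_newick(self, tmp_path, small_cohort):
        matrix, sheet, _ = small_cohort
        villi, vsheet = villi_subset(matrix, sheet)
        sig = list(villi.cpg_ids[:80])
        tree = hierarchical_cluster(villi, sig)
        sup = multiscale_bootstrap_au(villi, sig, n_boot=100, seed=0, tree=tree,
                                      scale_values=np.array([0.8, 1.0, 1.2]))
        half = villi.n_samples // 2
        labels = pd.Series([1] * half + [2] * (villi.n_samples - half),
                           index=villi.sample_ids)
        ci, p = cluster_significance(villi, sig, labels=labels, n_sim=100, seed=0)
        enr = cluster_phenotype_enrichment(labels, vsheet)
        report = ClusterReport(tree, sup, ci, p, enr)
        report.to_json(tmp_path / "report.json")
        nwk = report.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == villi.n_samples - 1
        for sid in villi.sample_ids:
            assert sid in nwk
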