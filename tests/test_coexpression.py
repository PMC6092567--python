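"""Network construction, TOM algebra, module detection, hubs, enrichment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ppx.coexpression_modules import (
    NetworkMatrices,
    build_network,
    detect_modules,
    hub_candidates,
    module_enrichment,
    scale_free_fit,
    tom_from_adjacency,
)
from ppx.diffexpr import ExpressionStudy
from ppx.synthetic_data import ModuleSpec, StudySpec, make_study


def tom_oracle(a):
    """Direct triple-loop evaluation of the TOM formula."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def net_from_adjacency(a, beta=1.0):
    genes = pd.Index([f"g{i}" for i in range(a.shape[0])])
    s = a ** (1.0 / beta) if beta != 1.0 else a.copy()
    np.fill_diagonal(s, 1.0)
    return NetworkMatrices(
        similarity=pd.DataFrame(s, index=genes, columns=genes),
        adjacency=pd.DataFrame(a, index=genes, columns=genes),
        connectivity=pd.Series(a.sum(axis=1), index=genes),
        tom=pd.DataFrame(tom_from_adjacency(a), index=genes, columns=genes),
        beta=beta,
    )


class TestBuildNetwork:
    def test_soft_threshold_power_arithmetic(self, two_module_study):
        net = build_network(two_module_study, beta=10)
        s = net.similarity.to_numpy()
        a = net.adjacency.to_numpy()
        off = ~np.eye(len(s), dtype=bool)
        assert a[off] == pytest.approx(s[off] ** 10)

    def test_beta_one_is_identity(self, two_module_study):
        net = build_network(two_module_study, beta=1)
        off = ~np.eye(net.similarity.shape[0], dtype=bool)
        assert net.adjacency.to_numpy()[off] == pytest.approx(
            net.similarity.to_numpy()[off]
        )

    def test_three_gene_toy_tom(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = tom_from_adjacency(a)
        # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert tom[0, 1] == pytest.approx(0.5)
        assert np.diag(tom) == pytest.approx(np.ones(3))

    def test_tom_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            s = rng.uniform(0, 1, size=(10, 10))
            a = (s + s.T) / 2
            np.fill_diagonal(a, 0.0)
            assert tom_from_adjacency(a) == pytest.approx(tom_oracle(a), abs=1e-12)

    def test_tom_bounds_and_symmetry(self, two_module_study):
        net = build_network(two_module_study, beta=10)
        tom = net.tom.to_numpy()
        a = net.adjacency.to_numpy()
        k = net.connectivity.to_numpy()
        assert ((tom >= 0) & (tom <= 1)).all()
        assert tom == pytest.approx(tom.T)
        lower = a / (np.minimum.outer(k, k) + 1 - a)
        off = ~np.eye(len(k), dtype=bool)
        assert (tom[off] >= lower[off] - 1e-12).all()

    def test_raising_beta_weakly_decreases_adjacency(self, two_module_study):
        a10 = build_network(two_module_study, beta=10).adjacency.to_numpy()
        a12 = build_network(two_module_study, beta=12).adjacency.to_numpy()
        assert (a12 <= a10 + 1e-12).all()

    def test_constant_gene_warns_and_zeroes(self, two_module_study):
        mat = two_module_study.matrix.copy()
        mat.iloc[0] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            net = build_network(mat, beta=2)
        assert net.adjacency.iloc[0, 1:].to_numpy() == pytest.approx(0.0)

    def test_scale_free_criterion_prefers_high_beta(self):
        """Averaged over generator replicates, the signed scale-free fit at
        beta=10 exceeds the fit at beta=1 for planted-module studies."""
        fits_soft, fits_raw = [], []
        for seed in range(5):
            study = make_study(StudySpec(seed=seed))
            fits_soft.append(scale_free_fit(build_network(study, beta=10).connectivity))
            fits_raw.append(scale_free_fit(build_network(study, beta=1).connectivity))
        assert np.mean(fits_soft) > np.mean(fits_raw)


class TestDetectModules:
    def test_planted_blocks_recovered_exactly(self, two_module_study):
        net = build_network(two_module_study, beta=10)
        assignment = detect_modules(net)
        truth = two_module_study.genes["true_module"]
        assert adjusted_rand_score(truth, assignment.labels) == 1.0
        sizes = assignment.labels.value_counts()
        assert sizes.get("M1", 0) == 50 and sizes.get("M2", 0) == 50

    def test_pure_noise_mostly_unassigned(self):
        study = make_study(StudySpec(n_genes=200, module_specs=(), seed=21))
        net = build_network(study, beta=10)
        assignment = detect_modules(net)
        assert (assignment.labels == "unassigned").mean() >= 0.9

    def test_small_block_stays_unassigned(self):
        spec = StudySpec(
            n_genes=120,
            module_specs=(ModuleSpec(size=20, within_correlation=0.8),),
            seed=22,
        )
        net = build_network(make_study(spec), beta=10)
        assignment = detect_modules(net, min_module_size=30)
        planted = assignment.labels.iloc[:20]
        assert (planted == "unassigned").all()

    def test_gene_order_invariance(self, two_module_study):
        perm = list(two_module_study.matrix.index[::-1])
        shuffled = two_module_study.subset_genes(perm)
        l1 = detect_modules(build_network(two_module_study, beta=10)).labels
        l2 = detect_modules(build_network(shuffled, beta=10)).labels
        # same partition up to label names
        assert adjusted_rand_score(l1.loc[l1.index], l2.loc[l1.index]) == 1.0

    def test_all_equal_distances_single_module(self):
        a = np.full((40, 40), 0.5)
        np.fill_diagonal(a, 0.0)
        net = net_from_adjacency(a)
        with pytest.warns(UserWarning, match="single module"):
            assignment = detect_modules(net)
        assert (assignment.labels == "M1").all()

    def test_invalid_deep_split_rejected(self, two_module_study):
        net = build_network(two_module_study, beta=10)
        with pytest.raises(ValueError):
            detect_modules(net, deep_split=7)


class TestHubCandidates:
    @staticmethod
    def _study_with_hub():
        rng = np.random.default_rng(30)
        n = 20
        driver = rng.normal(0, 1, n)
        rows = {
            "hubA": 10.0 + driver,  # high intensity, drives 3 partners
            "p1": 8.0 + driver + rng.normal(0, 0.1, n),
            "p2": 8.0 + driver + rng.normal(0, 0.1, n),
            "p3": 8.0 + driver + rng.normal(0, 0.1, n),
            "hubB": 10.0 + rng.normal(0, 1, n),  # high intensity, no partners
            "dim": 5.0 + driver,  # low intensity despite connectivity
        }
        other = rng.normal(0, 1, n)
        rows["hubB"] = 10.0 + other
        rows["q1"] = 8.0 + other + rng.normal(0, 0.3, n)
        matrix = pd.DataFrame(rows).T
        matrix.columns = [f"s{j}" for j in range(n)]
        samples = pd.DataFrame(index=matrix.columns)
        genes = pd.DataFrame(
            {"is_tf": [True, False, False, False, True, True, False]},
            index=matrix.index,
        )
        return ExpressionStudy(matrix=matrix, samples=samples, genes=genes)

    def test_partner_count_ranking_and_filters(self, two_module_study):
        study = self._study_with_hub()
        net = build_network(study.matrix, beta=2)
        labels = pd.Series("M1", index=study.matrix.index, name="module")
        from ppx.coexpression_modules import ModuleAssignment

        modules = ModuleAssignment(labels, np.empty((0, 4)), 1, 2)
        report = hub_candidates(study, modules, intensity_min=9.0, cor_min=0.7)
        table = report.table.set_index("gene")
        # dim gene excluded by the intensity rule; non-TF partners excluded by flag
        assert "dim" not in table.index
        assert "p1" not in table.index
        assert table.loc["hubA", "partner_count"] >= 3
        assert table.loc["hubA", "rank"] < table.loc["hubB", "rank"]

    def test_empty_partner_set_rejected(self, two_module_study):
        from ppx.coexpression_modules import ModuleAssignment

        study = self._study_with_hub()
        labels = pd.Series("M1", index=study.matrix.index, name="module")
        modules = ModuleAssignment(labels, np.empty((0, 4)), 1, 2)
        with pytest.raises(ValueError, match="partner"):
            hub_candidates(study, modules, partner_set=["not_a_gene"])


class TestModuleEnrichment:
    @staticmethod
    def _modules(labels: dict[str, str]):
        from ppx.coexpression_modules import ModuleAssignment

        ser = pd.Series(labels, name="module")
        return ModuleAssignment(ser, np.empty((0, 4)), 1, 2)

    def test_hand_arithmetic_odds_ratio(self):
        # module: 10 genes, 8 positive; background: 100 genes, 20 positive
        genes = [f"g{i}" for i in range(100)]
        labels = {g: ("M1" if i < 10 else "unassigned") for i, g in enumerate(genes)}
        positive = {g: (i < 8 or 10 <= i < 22) for i, g in enumerate(genes)}
        res = module_enrichment(self._modules(labels), pd.Series(positive))["M1"]
        assert res.odds_ratio == pytest.approx(26.0)
        assert res.p_value < 1e-4

    def test_equal_proportions_or_one(self):
        genes = [f"g{i}" for i in range(40)]
        labels = {g: ("M1" if i < 20 else "unassigned") for i, g in enumerate(genes)}
        positive = {g: (i % 2 == 0) for i, g in enumerate(genes)}
        res = module_enrichment(self._modules(labels), pd.Series(positive))["M1"]
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_property_equals_membership_is_degenerate(self):
        genes = [f"g{i}" for i in range(30)]
        labels = {g: ("M1" if i < 10 else "unassigned") for i, g in enumerate(genes)}
        positive = {g: (i < 10) for i, g in enumerate(genes)}
        res = module_enrichment(self._modules(labels), pd.Series(positive))["M1"]
        assert res.odds_ratio == np.inf
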