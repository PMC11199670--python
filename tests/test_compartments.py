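"""Segmentation, compartment assignment, concentration tables,
background correction, ANOVA and tissue genotype calls."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

import fumamap as fm
from fumamap.compartments import (
    ClusterResult,
    CompartmentAssignment,
    CompartmentTable,
    anova_oneway,
    assign_compartments,
    background_correct,
    classify_tissue_status,
    compartment_concentrations,
    kmeans_manhattan,
)
from fumamap.core import SpectralMap
from fumamap.preprocess import despike_map, mean_center_scan
from fumamap.quantify import ConcentrationMap
from fumamap.synth import (
    PhantomConfig,
    build_component_library,
    generate_tissue_phantom,
)


def _toy_map(X, axis):
    n, c = X.shape
    return SpectralMap(axis, X.reshape(n, 1, c), step_um=1.0, dwell=1.0)


def _brute_force_lloyd_l1(X, labels, k, iters=200):
    """Independent naive Lloyd-with-L1 oracle (loops, no vectorisation)."""
    labels = labels.copy()
    for _ in range(iters):
        cents = []
        for j in range(k):
            members = [x for x, l in zip(X, labels) if l == j]
            cents.append(np.mean(members, axis=0))
        new = np.array([
            int(np.argmin([np.abs(x - c).sum() for c in cents])) for x in X
        ])
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


class TestKmeansManhattan:
    def test_separable_clouds_perfect_partition(self, rng):
        axis = np.linspace(400, 500, 30)
        a = rng.normal(0, 0.2, (20, 30)) + 10
        b = rng.normal(0, 0.2, (20, 30)) - 10
        X = np.vstack([a, b])
        for seed in (0, 1, 2):
            res = kmeans_manhattan(_toy_map(X, axis), k=2, seed=seed)
            lab = res.labels.ravel()
            assert len(set(lab[:20])) == 1 and len(set(lab[20:])) == 1
            assert lab[0] != lab[-1]

    def test_matches_brute_force_oracle_from_same_init(self, rng):
        axis = np.linspace(400, 520, 25)
        X = rng.uniform(0, 10, (12, 25))
        init = rng.integers(0, 3, 12)
        for j in range(3):
            if not np.any(init == j):
                init[j] = j
        res = kmeans_manhattan(_toy_map(X, axis), k=3, seed=0,
                               init_labels=init)
        oracle = _brute_force_lloyd_l1(X, init, 3)
        assert np.array_equal(res.labels.ravel(), oracle)

    def test_deterministic_given_seed(self, ko19_phantom):
        smap, _ = ko19_phantom
        centered = mean_center_scan(smap)
        a = kmeans_manhattan(centered, k=4, seed=3, n_init=1)
        b = kmeans_manhattan(centered, k=4, seed=3, n_init=1)
        assert np.array_equal(a.labels, b.labels)

    def test_loadings_on_original_scale(self, rng):
        axis = np.linspace(400, 500, 10)
        X = np.vstack([np.full((5, 10), 4.0), np.full((5, 10), 40.0)])
        Xc = X - X.mean(axis=0)
        res = kmeans_manhattan(_toy_map(Xc, axis), k=2, seed=0,
                               original=_toy_map(X, axis))
        assert sorted(res.loadings[:, 0]) == [4.0, 40.0]

    def test_k_bounds(self, rng):
        axis = np.linspace(400, 500, 5)
        X = rng.uniform(0, 1, (4, 5))
        with pytest.raises(ValueError):
            kmeans_manhattan(_toy_map(X, axis), k=1)
        with pytest.raises(ValueError):
            kmeans_manhattan(_toy_map(X, axis), k=5)

    def test_seed_stability_on_separable_phantom(self):
        # five compartments, five classes: different optimiser seeds must
        # recover essentially the same partition
        from sklearn.metrics import adjusted_rand_score
        from fumamap.synth import cell_phantom_config, generate_cell_phantom
        smap, _ = generate_cell_phantom(cell_phantom_config("WT", seed=1))
        centered = mean_center_scan(despike_map(smap))
        runs = [kmeans_manhattan(centered, k=5, seed=s).labels.ravel()
                for s in (0, 1)]
        assert adjusted_rand_score(runs[0], runs[1]) >= 0.95


class TestAssignCompartments:
    def _loading_for(self, weights, axis, conf_mm=0.0, marker=0.0):
        lib = build_component_library(wavenumbers=axis)
        out = np.zeros_like(axis)
        for comp, w in weights.items():
            out = out + w * lib.render(comp, axis)
        out = out + conf_mm * lib.render("cytc_redox", axis)
        out = out + marker * lib.render("cytc_marker", axis)
        return out

    def test_ground_truth_loadings_assigned_exactly(self, axis):
        profiles = {
            "substrate": dict(weights={"quartz": 1.0, "water": 0.4}),
            "nucleus": dict(weights={"dna": 2.8, "protein": 1.0,
                                     "phe": 1.0, "lipid": 0.3}),
            "membrane": dict(weights={"lipid": 2.2, "lipid_twist": 2.2,
                                      "protein": 0.4}),
            "cytoplasm": dict(weights={"protein": 1.5, "phe": 1.5,
                                       "lipid": 0.6}, marker=0.4),
            "mitochondria": dict(weights={"protein": 1.0, "lipid": 1.0},
                                 marker=2.0),
        }
        names = list(profiles)
        loadings = np.stack([
            self._loading_for(p["weights"], axis, marker=p.get("marker", 0))
            for p in profiles.values()
        ])
        res = ClusterResult(labels=np.arange(5), loadings=loadings,
                            wavenumbers=axis, k=5, seed=0)
        a = assign_compartments(res)
        assert {names[j]: name for j, name in a.mapping.items()} == {
            n: n for n in names}

    def test_all_substrate_classes(self, axis):
        weights = {"quartz": 1.0, "water": 0.3}
        loadings = np.stack([self._loading_for(weights, axis),
                             1.01 * self._loading_for(weights, axis)])
        res = ClusterResult(labels=np.array([0, 1]), loadings=loadings,
                            wavenumbers=axis, k=2, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = assign_compartments(res)
        assert set(a.mapping.values()) == {"substrate"}

    def test_two_mitochondria_like_classes_both_mapped(self, axis):
        mk = {"protein": 1.0, "lipid": 1.0}
        loadings = np.stack([
            self._loading_for({"quartz": 1.0}, axis),
            self._loading_for(mk, axis, marker=2.0),
            self._loading_for(mk, axis, marker=1.7),
            self._loading_for({"dna": 2.8, "protein": 1.0}, axis),
            self._loading_for({"lipid": 2.2, "lipid_twist": 2.2}, axis),
            self._loading_for({"protein": 1.5, "phe": 1.5}, axis),
        ])
        res = ClusterResult(labels=np.arange(6), loadings=loadings,
                            wavenumbers=axis, k=6, seed=0)
        a = assign_compartments(res)
        assert a.mapping[1] == a.mapping[2] == "mitochondria"

    def test_fewer_classes_warns(self, axis):
        loadings = np.stack([self._loading_for({"quartz": 1.0}, axis),
                             self._loading_for({"protein": 1.5}, axis)])
        res = ClusterResult(labels=np.array([0, 1]), loadings=loadings,
                            wavenumbers=axis, k=2, seed=0)
        with pytest.warns(UserWarning, match="fewer classes"):
            assign_compartments(res)


def _assignment(mapping):
    return CompartmentAssignment(mapping=mapping, scores=pd.DataFrame())


class TestCompartmentTable:
    def test_uniform_map_means(self):
        cmap = ConcentrationMap(np.full((3, 3), 10.0), np.ones((3, 3), bool))
        labels = np.tile(np.array([0, 1, 2]), (3, 1))
        tab = compartment_concentrations(
            cmap, _assignment({0: "nucleus", 1: "cytoplasm",
                               2: "mitochondria"}), labels)
        assert (tab.table["mean_mM"] == 10.0).all()
        assert (tab.table["sd_mM"] == 0.0).all()

    def test_hand_built_three_by_three(self):
        vals = np.arange(9.0).reshape(3, 3)
        labels = np.array([[0, 0, 1], [1, 1, 2], [2, 2, 2]])
        tab = compartment_concentrations(
            ConcentrationMap(vals, np.ones((3, 3), bool)),
            _assignment({0: "nucleus", 1: "membrane", 2: "mitochondria"}),
            labels)
        assert tab.mean("nucleus") == pytest.approx(np.mean([0, 1]))
        assert tab.mean("membrane") == pytest.approx(np.mean([2, 3, 4]))
        assert tab.mean("mitochondria") == pytest.approx(
            np.mean([5, 6, 7, 8]))
        assert tab.table["n"].sum() == 9

    def test_label_permutation_invariance(self):
        vals = np.arange(16.0).reshape(4, 4)
        labels = np.repeat(np.arange(4), 4).reshape(4, 4)
        t1 = compartment_concentrations(
            ConcentrationMap(vals, np.ones((4, 4), bool)),
            _assignment({0: "substrate", 1: "nucleus", 2: "membrane",
                         3: "cytoplasm"}), labels)
        perm = (labels + 1) % 4
        t2 = compartment_concentrations(
            ConcentrationMap(vals, np.ones((4, 4), bool)),
            _assignment({1: "substrate", 2: "nucleus", 3: "membrane",
                         0: "cytoplasm"}), perm)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_empty_compartment_entry(self):
        cmap = ConcentrationMap(np.ones((2, 2)), np.ones((2, 2), bool))
        tab = compartment_concentrations(
            cmap, _assignment({0: "nucleus", 7: "membrane"}),
            np.zeros((2, 2), int))
        assert tab.table.loc["membrane", "n"] == 0
        assert np.isnan(tab.table.loc["membrane", "mean_mM"])


def _table(means, cell_line=""):
    df = pd.DataFrame({
        "compartment": list(means), "mean_mM": list(means.values()),
        "sd_mM": [1.0] * len(means), "n": [10] * len(means),
    }).set_index("compartment")
    return CompartmentTable(table=df, cell_line=cell_line)


class TestBackgroundCorrect:
    def test_reference_table_arithmetic(self):
        ko = _table({"nucleus": 9, "membrane": 14, "cytoplasm": 24,
                     "mitochondria": 37}, "KO19")
        wt = _table({"nucleus": 4, "membrane": 4, "cytoplasm": 6,
                     "mitochondria": 10}, "WT")
        corr = background_correct(ko, wt)
        assert corr.corrected
        assert corr.mean("nucleus") == 5
        assert corr.mean("membrane") == 10
        assert corr.mean("cytoplasm") == 18
        assert corr.mean("mitochondria") == 27

    def test_identical_tables_give_zero(self):
        t = _table({"nucleus": 5, "cytoplasm": 7})
        corr = background_correct(t, t)
        assert (corr.table["mean_mM"] == 0).all()

    def test_mismatched_compartments_rejected(self):
        with pytest.raises(ValueError):
            background_correct(_table({"nucleus": 5}),
                               _table({"cytoplasm": 5}))


class TestAnova:
    def test_hand_computed_toy_table(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]),
                  np.array([4.0, 5, 6])]
        f, p = anova_oneway(groups)
        assert f == pytest.approx(7.0)           # hand computation
        assert p == pytest.approx(stats.f.sf(7.0, 2, 6))

    def test_matches_scipy_cross_check(self, rng):
        groups = [rng.normal(i, 1, 30) for i in range(3)]
        f, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_extreme_separation(self, rng):
        groups = [rng.normal(0, 1, 50), rng.normal(10, 1, 50)]
        _, p = anova_oneway(groups)
        assert p < 1e-10

    def test_null_behaviour(self):
        ps = []
        for rep in range(40):
            r = np.random.default_rng(rep)
            groups = [r.normal(0, 1, 20) for _ in range(3)]
            ps.append(anova_oneway(groups)[1])
        # p approximately uniform under the null
        assert 0.2 < np.mean(ps) < 0.8

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0, 1.0]), np.array([1.0, 1.0])])


class TestTissueCall:
    def test_trivial_calls(self):
        mask = np.ones((2, 2), bool)
        lo = ConcentrationMap(np.zeros((2, 2)), mask)
        hi = ConcentrationMap(np.full((2, 2), 40.0), mask)
        assert classify_tissue_status(lo, 8.0, mask) == ("Fh1fl/fl", 0.0)
        assert classify_tissue_status(hi, 8.0, mask) == ("Fh1-/-", 1.0)

    def test_empty_mask_rejected(self):
        cmap = ConcentrationMap(np.ones((2, 2)), np.ones((2, 2), bool))
        with pytest.raises(ValueError):
            classify_tissue_status(cmap, 8.0, np.zeros((2, 2), bool))

    def test_null_phantom_called_correctly_across_seeds(self,
                                                        noiseless_model):
        # the FH-null phantom is called correctly in >= 95 % of repeats
        calls = []
        for seed in range(20):
            cfg = PhantomConfig(shape=(20, 20), seed=seed)
            smap, truth = generate_tissue_phantom("-/-", cfg)
            cmap = fm.concentration_map_auc(smap, noiseless_model,
                                            despike=False)
            call, _ = classify_tissue_status(cmap, 8.0, truth.labels == 1)
            calls.append(call == "Fh1-/-")
        assert np.mean(calls) >= 0.95
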