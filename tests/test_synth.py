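"""Forward model: component library, solution spectra, calibration
series, phantoms and line-scan datasets."""

import numpy as np
import pytest

import fumamap as fm
from fumamap.preprocess import band_auc
from fumamap.synth import (
    COMPARTMENTS,
    PhantomConfig,
    build_component_library,
    cell_phantom_config,
    generate_cell_phantom,
    generate_calibration_series,
    generate_linescan_dataset,
    generate_solution_spectrum,
    generate_tissue_phantom,
)


class TestComponentLibrary:
    def test_solution_triplet_band_positions(self):
        lib = build_component_library("none")
        centers = {b.center for b in lib.components["fumarate_solution"]}
        assert centers == {1277.0, 1401.0, 1652.0}

    def test_isotope_variant_shifts_quantitative_band(self):
        lib = build_component_library("13C4")
        centers = {b.center for b in lib.components["fumarate_solution"]}
        assert 1373.0 in centers and 1401.0 not in centers

    def test_unknown_variant_rejected_with_allowed_tags(self):
        with pytest.raises(ValueError, match="13C4"):
            build_component_library("deuterated")

    def test_1401_band_calibrated_to_sensitivity(self, axis):
        # rendering at 1 mM / 1 s and integrating the standard window
        # recovers the sensitivity (trapezoid oracle, 19.2 +/- 0.2)
        lib = build_component_library()
        band = [b for b in lib.components["fumarate_solution"]
                if b.center == 1401.0][0]
        spec = fm.Spectrum(axis, band.render(axis), dwell=1.0)
        assert band_auc(spec) == pytest.approx(19.2, abs=0.2)

    def test_round_trips_through_dict(self):
        lib = build_component_library()
        clone = type(lib).from_dict(lib.to_dict())
        assert clone.components == lib.components
        assert clone.sensitivity == lib.sensitivity


class TestSolutionSpectrum:
    def test_zero_concentration_is_flat_offset(self, axis):
        s = generate_solution_spectrum(0.0, dwell=1.0, noise_sd=0.0)
        assert np.allclose(s.counts, s.counts[0])

    def test_auc_round_trip_at_30_mm(self):
        s = generate_solution_spectrum(30.0, dwell=1.0, noise_sd=0.0)
        assert band_auc(s) == pytest.approx(19.2 * 30, rel=1e-6)

    def test_counts_scale_with_dwell(self):
        s1 = generate_solution_spectrum(10.0, dwell=1.0, noise_sd=0.0)
        s3 = generate_solution_spectrum(10.0, dwell=3.0, noise_sd=0.0)
        assert np.allclose(s3.counts, 3 * s1.counts)

    def test_seed_determinism(self):
        a = generate_solution_spectrum(10.0, noise_sd=7.5, seed=7)
        b = generate_solution_spectrum(10.0, noise_sd=7.5, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            generate_solution_spectrum(-1.0)

    def test_linearity_of_band_auc_in_concentration(self):
        concs = [5, 10, 20, 40, 80]
        aucs = [band_auc(generate_solution_spectrum(c, dwell=1.0,
                                                    noise_sd=0.0))
                for c in concs]
        slope = np.polyfit(concs, aucs, 1)[0]
        assert slope == pytest.approx(19.2, rel=1e-6)


class TestCalibrationSeries:
    def test_noiseless_intensities_by_construction(self):
        series = generate_calibration_series([0, 10, 20], replicates=3,
                                             dwell=1.0, noise_sd=0.0)
        by_conc = series.table.groupby("concentration")["intensity"]
        assert by_conc.nunique().max() == 1
        np.testing.assert_allclose(
            by_conc.first().to_numpy(), [0.0, 192.0, 384.0], atol=1e-9)

    def test_single_replicate_series_still_fits(self):
        series = generate_calibration_series([0, 10], replicates=1,
                                             noise_sd=0.0)
        model = fm.fit_calibration(series)
        assert model.sensitivity == pytest.approx(19.2, rel=1e-9)
        with pytest.raises(ValueError):
            fm.estimate_lod(series)

    def test_seed_determinism(self):
        a = generate_calibration_series([0, 5, 10], seed=3)
        b = generate_calibration_series([0, 5, 10], seed=3)
        assert a.table.equals(b.table)

    def test_empty_concs_rejected(self):
        with pytest.raises(ValueError):
            generate_calibration_series([])


class TestCellPhantom:
    def test_null_phantom_band_auc_zero(self, axis):
        # truly empty phantom (no composition at all): exact zero
        cfg = PhantomConfig(shape=(8, 8), noise_floor=0.0,
                            baseline_amplitude=0.0, cosmic_ray_rate=0.0)
        for spec in cfg.compartments.values():
            spec.weights = {}
            spec.cytc_marker = 0.0
        smap, _ = generate_cell_phantom(cfg)
        for r in range(0, 8, 3):
            for c in range(0, 8, 3):
                assert band_auc(smap.pixel(r, c)) == pytest.approx(
                    0.0, abs=1e-9)
        # with cellular background but zero fumarate/confounder, the
        # raw flat-baseline integral carries only the CH2-shoulder leak
        # (a few mM-equivalent for lipid-rich pixels)
        cfg2 = PhantomConfig(shape=(8, 8), noise_floor=0.0,
                             baseline_amplitude=0.0, cosmic_ray_rate=0.0)
        smap2, _ = generate_cell_phantom(cfg2)
        for r in range(0, 8, 3):
            for c in range(0, 8, 3):
                assert abs(band_auc(smap2.pixel(r, c))) < 19.2 * 6

    def test_labels_partition_grid(self, ko19_phantom):
        smap, truth = ko19_phantom
        assert truth.labels.shape == smap.shape
        assert set(np.unique(truth.labels)) <= set(range(len(COMPARTMENTS)))

    def test_ground_truth_means_match_config(self):
        cfg = cell_phantom_config("KO19", seed=5)
        _, truth = generate_cell_phantom(cfg)
        for cid, name in enumerate(COMPARTMENTS):
            sel = truth.labels == cid
            m, sd = cfg.compartments[name].fumarate_mm
            if sel.sum() < 10 or m == 0:
                continue
            se = sd / np.sqrt(sel.sum())
            assert abs(truth.concentration[sel].mean() - m) < 2 * se + 1e-9

    def test_additivity_of_fumarate_band(self):
        base_cfg = cell_phantom_config("WT", seed=2, rel_sd=0.0)
        for spec in base_cfg.compartments.values():
            spec.confounder_mm = (0.0, 0.0)
        base_cfg.noise_floor = 0.0
        base_cfg.baseline_amplitude = 0.0
        base_cfg.cosmic_ray_rate = 0.0
        base_cfg.weight_jitter = 0.0
        plus_cfg = cell_phantom_config("WT", seed=2, rel_sd=0.0)
        for spec in plus_cfg.compartments.values():
            spec.confounder_mm = (0.0, 0.0)
            spec.fumarate_mm = (15.0, 0.0)
        plus_cfg.noise_floor = 0.0
        plus_cfg.baseline_amplitude = 0.0
        plus_cfg.cosmic_ray_rate = 0.0
        plus_cfg.weight_jitter = 0.0
        a, _ = generate_cell_phantom(base_cfg)
        b, truth_b = generate_cell_phantom(plus_cfg)
        lib = build_component_library(wavenumbers=a.wavenumbers)
        unit = lib.render("fumarate_solution", a.wavenumbers)
        diff = b.counts - a.counts
        expected = truth_b.concentration[..., None] * unit * a.dwell
        # common-mode jitter is shared through the same rng stream
        assert np.allclose(diff, expected, rtol=1e-6, atol=1e-6)

    def test_seed_determinism(self):
        cfg = cell_phantom_config("KO1", seed=9)
        a, _ = generate_cell_phantom(cfg)
        b, _ = generate_cell_phantom(cell_phantom_config("KO1", seed=9))
        assert np.array_equal(a.counts, b.counts)

    def test_unknown_component_rejected(self):
        cfg = cell_phantom_config("WT")
        cfg.compartments["nucleus"].weights["unobtainium"] = 1.0
        with pytest.raises(ValueError, match="unobtainium"):
            generate_cell_phantom(cfg)

    def test_wt_preset_apparent_means_near_reference_table(self):
        # apparent concentration = confounder only for the FH-proficient
        # preset; check against the reference column via direct band AUC
        cfg = cell_phantom_config("WT", seed=4, noise_floor=0.0,
                                  baseline_amplitude=0.0,
                                  cosmic_ray_rate=0.0)
        smap, truth = generate_cell_phantom(cfg)
        apparent = truth.concentration + truth.confounder
        ref = {"substrate": 2, "nucleus": 4, "membrane": 4,
               "cytoplasm": 6, "mitochondria": 10}
        for cid, name in enumerate(COMPARTMENTS):
            sel = truth.labels == cid
            se = 0.2 * ref[name] / np.sqrt(sel.sum())
            assert apparent[sel].mean() == pytest.approx(
                ref[name], abs=3 * se + 0.05)


class TestTissuePhantom:
    @pytest.mark.parametrize("genotype,above", [("fl/fl", False),
                                                ("-/-", True)])
    def test_fraction_above_lod_by_genotype(self, genotype, above):
        cfg = PhantomConfig(shape=(24, 24), noise_floor=0.0, seed=2)
        _, truth = generate_tissue_phantom(genotype, cfg)
        tissue = truth.labels == 1
        frac = (truth.concentration[tissue] > 8.0).mean()
        assert (frac > 0.5) == above

    def test_outline_band_contrast(self):
        cfg = PhantomConfig(shape=(24, 24), seed=2)
        smap, truth = generate_tissue_phantom("-/-", cfg)
        bmap = fm.band_intensity_map(smap, band_center=1130.0, half_width=10)
        on = bmap[truth.labels == 1].mean()
        off = np.abs(bmap[truth.labels == 0]).mean()
        assert on > 50 * max(off, 1e-9)

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError):
            generate_tissue_phantom("+/+")


class TestLinescan:
    def test_shapes_and_labels(self):
        data = generate_linescan_dataset(n_per_class=30, points_per_scan=20,
                                         seed=0)
        assert len(data) == 3 * 600
        assert set(np.unique(data.labels)) == {"WT", "KO1", "KO19"}

    def test_minimal_single_point_dataset(self):
        data = generate_linescan_dataset(n_per_class=1, points_per_scan=1,
                                         seed=0)
        assert len(data) == 3
        assert data.X.shape[1] == data.wavenumbers.size

    def test_seed_determinism(self):
        a = generate_linescan_dataset(n_per_class=2, points_per_scan=10,
                                      seed=5)
        b = generate_linescan_dataset(n_per_class=2, points_per_scan=10,
                                      seed=5)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.labels, b.labels)

    def test_per_class_counts(self):
        data = generate_linescan_dataset(
            n_per_class={"WT": 4, "KO1": 3, "KO19": 2}, points_per_scan=10,
            seed=1)
        counts = {c: int((data.labels == c).sum())
                  for c in np.unique(data.labels)}
        assert counts == {"WT": 40, "KO1": 30, "KO19": 20}


class TestPhantomConfig:
    def test_round_trip_through_dict(self):
        cfg = cell_phantom_config("KO19", seed=11)
        clone = PhantomConfig.from_dict(cfg.to_dict())
        assert clone.to_dict() == cfg.to_dict()

    def test_unknown_key_rejected(self):
        d = PhantomConfig().to_dict()
        d["coffee"] = 1
        with pytest.raises(ValueError, match="coffee"):
            PhantomConfig.from_dict(d)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            cell_phantom_config("KO42")
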