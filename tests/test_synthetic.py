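"""The generators: kernel scans with ground truth and DH populations."""

import numpy as np
import pytest

from pericolor.pipeline import SegmentationParams, extract_kernel_table
from pericolor.segmentation import segment_image
from pericolor.segregation import STANDARD_MODELS
from pericolor.simulate import (
    PlacementError,
    ScanSpec,
    SimTruth,
    default_marker_map,
    generate_kernel_scan,
    haldane_cm_to_recfrac,
    simulate_dh_population,
)


class TestKernelScan:
    def test_zero_kernels_blank_background(self):
        image, truth = generate_kernel_scan(
            ScanSpec(n_kernels=0, height=100, width=100, noise_sd=0.0), seed=1
        )
        assert truth.kernel_count == 0
        assert image.max() <= 20  # near-black background only

    def test_disjoint_kernels_recovered_by_segmentation(self, clean_scan):
        image, truth = clean_scan
        labeled, _ = segment_image(image)
        assert labeled.n_components == truth.kernel_count == 12

    def test_uniform_body_kernel_yields_closed_form_hue(self):
        """A kernel of pure (139,69,19) with no cap/tip measures hue 25."""
        spec = ScanSpec(
            n_kernels=1, height=200, width=200, with_cap=False,
            with_tip=False, noise_sd=0.0, body_hues=[25.0],
        )
        image, truth = generate_kernel_scan(spec, seed=2)
        # overwrite the body with the reference brown before measuring
        image = image.copy()
        image[truth.kernel_mask(1)] = (139, 69, 19)
        table = extract_kernel_table(
            image, "img", SegmentationParams(min_luminance=0.25,
                                             n_subsamples=3000)
        )
        assert len(table) == 1 and table["retained"].iloc[0]
        assert table["hue"].iloc[0] == pytest.approx(25.0, abs=0.3)

    def test_bit_reproducible_given_seed(self):
        spec = ScanSpec(n_kernels=5, height=250, width=250, n_debris=2,
                        damaged_fraction=0.5)
        img1, _ = generate_kernel_scan(spec, seed=7)
        img2, _ = generate_kernel_scan(spec, seed=7)
        assert np.array_equal(img1, img2)

    def test_impossible_placement_raises(self):
        spec = ScanSpec(n_kernels=60, height=200, width=200,
                        max_place_tries=50)
        with pytest.raises(PlacementError):
            generate_kernel_scan(spec, seed=1)

    def test_truth_invariants(self, clean_scan):
        _, truth = clean_scan
        for k in truth.per_kernel:
            assert k.length_px >= k.width_px > 0
            assert all(0 <= c <= 255 for c in k.body_rgb)
        labels = np.unique(truth.labels)
        assert labels.max() == truth.kernel_count


class TestDHPopulation:
    @pytest.mark.parametrize(
        "model_name,markers",
        [("Single gene", {"A": "c1m5"}),
         ("Function in 3 genes", {"A": "c1m5", "B": "c2m5", "C": "c3m5"})],
    )
    def test_pigment_fraction_matches_expectation(self, model_name, markers):
        model = next(m for m in STANDARD_MODELS if m.name == model_name)
        mm = default_marker_map(3, 10, 10.0)
        truth = SimTruth(model=model, causal_markers=markers, qtl=[], seed=5)
        sim = simulate_dh_population(10_000, mm, truth, n_reps=1,
                                     two_rep_fraction=0.0)
        frac = sim.pheno["pigment_class"].mean()
        p = float(model.expected_pigmented)
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(frac - p) <= 3 * se

    def test_all_six_models_converge(self):
        mm = default_marker_map(3, 4, 25.0)
        markers = {"A": "c1m2", "B": "c2m2", "C": "c3m2"}
        for model in STANDARD_MODELS:
            causal = {k: markers[k] for k in model.loci}
            truth = SimTruth(model=model, causal_markers=causal, qtl=[], seed=9)
            sim = simulate_dh_population(10_000, mm, truth, n_reps=1,
                                         two_rep_fraction=0.0)
            p = float(model.expected_pigmented)
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs(sim.pheno["pigment_class"].mean() - p) <= 3 * se, model.name

    def test_allele_frequency_half_at_every_marker(self):
        mm = default_marker_map(2, 10, 10.0)
        truth = SimTruth(model=STANDARD_MODELS[0],
                         causal_markers={"A": "c1m5"}, qtl=[], seed=13)
        sim = simulate_dh_population(10_000, mm, truth, n_reps=1,
                                     two_rep_fraction=0.0, missing_rate=0.0,
                                     error_rate=0.0)
        freq_b = (sim.population.genotypes.to_numpy() == "B").mean(axis=0)
        se = np.sqrt(0.25 / 10_000)
        assert np.all(np.abs(freq_b - 0.5) <= 3 * se + 1e-12)

    def test_crossover_count_matches_map_expectation(self):
        mm = default_marker_map(3, 40, 2.5)
        truth = SimTruth(model=STANDARD_MODELS[0],
                         causal_markers={"A": "c1m10"}, qtl=[], seed=17)
        sim = simulate_dh_population(10_000, mm, truth, n_reps=1,
                                     two_rep_fraction=0.0, missing_rate=0.0,
                                     error_rate=0.0)
        geno = (sim.population.genotypes.to_numpy() == "B").astype(int)
        switches = 0
        per_chrom = 40
        for c in range(3):
            block = geno[:, c * per_chrom:(c + 1) * per_chrom]
            switches += (np.diff(block, axis=1) != 0).sum()
        r = haldane_cm_to_recfrac(2.5)
        expected = 3 * 39 * r
        sd = np.sqrt(3 * 39 * r * (1 - r))
        mean_obs = switches / 10_000
        assert abs(mean_obs - expected) <= 3 * sd / np.sqrt(10_000)

    def test_zero_distance_means_no_crossovers(self):
        import pandas as pd

        mm = pd.DataFrame(
            {"marker": ["m1", "m2"], "chrom": ["1", "1"],
             "pos_cm": [0.0, 1e-9]}
        )
        truth = SimTruth(model=STANDARD_MODELS[0],
                         causal_markers={"A": "m1"}, qtl=[], seed=19)
        sim = simulate_dh_population(10_000, mm, truth, n_reps=1,
                                     two_rep_fraction=0.0, missing_rate=0.0,
                                     error_rate=0.0)
        geno = sim.population.genotypes
        assert (geno["m1"] == geno["m2"]).all()

    def test_causal_marker_must_be_on_map(self):
        mm = default_marker_map(1, 5, 10.0)
        truth = SimTruth(model=STANDARD_MODELS[0],
                         causal_markers={"A": "nowhere"}, qtl=[], seed=1)
        with pytest.raises(ValueError, match="nowhere"):
            simulate_dh_population(100, mm, truth)

    def test_reproducible_given_seed(self):
        mm = default_marker_map(2, 8, 5.0)
        truth = SimTruth(model=STANDARD_MODELS[0],
                         causal_markers={"A": "c1m4"}, qtl=[("c1m4", 2.0)],
                         seed=23)
        s1 = simulate_dh_population(200, mm, truth)
        s2 = simulate_dh_population(200, mm, truth)
        assert s1.population.genotypes.equals(s2.population.genotypes)
        assert s1.pheno.equals(s2.pheno)

    def test_unbalanced_replicate_structure(self, single_qtl_sim):
        sim, _ = single_qtl_sim
        reps_per_line = sim.pheno.groupby("line_id")["replicate"].nunique()
        assert (reps_per_line == 2).sum() == round(0.33 * 150)
        assert set(reps_per_line.unique()) == {1, 2}

    def test_qtl_effect_enters_phenotype(self, single_qtl_sim):
        sim, _ = single_qtl_sim
        geno = sim.population.genotypes["c1m10"]
        merged = sim.pheno.groupby("line_id")["hue"].mean()
        carriers = merged[geno[geno == "A"].index.intersection(merged.index)]
        others = merged[geno[geno == "B"].index.intersection(merged.index)]
        assert carriers.mean() < others.mean() - 1.0  # 2-degree QTL
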