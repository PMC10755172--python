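"""Marker/individual QC, HMM posteriors, the LOD scan and its supports."""

import numpy as np
import pandas as pd
import pytest

from pericolor import qtl
from pericolor.phenotype import fit_line_blues
from pericolor.simulate import SimTruth, default_marker_map, simulate_dh_population
from pericolor.segregation import STANDARD_MODELS


def _tiny_map(n=3, spacing=5.0):
    return pd.DataFrame(
        {"marker": [f"m{i}" for i in range(1, n + 1)], "chrom": "1",
         "pos_cm": [i * spacing for i in range(n)]}
    )


class TestQC:
    def test_clean_population_untouched(self, single_qtl_sim):
        sim, mm = single_qtl_sim
        pop, rep = qtl.filter_markers_individuals(
            sim.population.genotypes, mm
        )
        assert rep.removed_individuals.empty
        assert rep.n_individuals_kept == 150
        assert rep.n_markers_kept == 120

    def test_alternating_individual_removed(self):
        mm = pd.DataFrame(
            {"marker": [f"m{i}" for i in range(500)], "chrom": "1",
             "pos_cm": np.arange(500) * 0.5}
        )
        rng = np.random.default_rng(0)
        base = np.where(rng.random((30, 500)) < 0.5, "A", "B")
        # make most individuals low-crossover, one alternating
        for i in range(29):
            base[i, :] = "A" if i % 2 else "B"
        base[29, :] = np.where(np.arange(500) % 2 == 0, "A", "B")
        geno = pd.DataFrame(base, columns=mm["marker"],
                            index=[f"ind{i}" for i in range(30)])
        # keep markers polymorphic
        pop, rep = qtl.filter_markers_individuals(geno, mm, min_maf=0.0)
        assert "ind29" in set(rep.removed_individuals["individual"])
        assert (rep.removed_individuals.set_index("individual")
                .loc["ind29", "reason"] == "crossovers")

    def test_mostly_missing_marker_removed(self, single_qtl_sim):
        sim, mm = single_qtl_sim
        geno = sim.population.genotypes.copy()
        geno.iloc[: int(0.8 * len(geno)),
                  geno.columns.get_loc("c2m7")] = None
        pop, rep = qtl.filter_markers_individuals(geno, mm)
        removed = rep.removed_markers.set_index("marker")
        assert removed.loc["c2m7", "reason"] == "missingness"

    def test_low_maf_marker_removed(self, single_qtl_sim):
        sim, mm = single_qtl_sim
        geno = sim.population.genotypes.copy()
        col = geno.columns.get_loc("c3m3")
        geno.iloc[:, col] = "A"
        geno.iloc[0, col] = "B"  # MAF ~ 0.7%
        pop, rep = qtl.filter_markers_individuals(geno, mm)
        assert "c3m3" in set(rep.removed_markers["marker"])

    def test_all_markers_removed_raises(self):
        mm = _tiny_map(2)
        geno = pd.DataFrame([["A", "A"], ["A", "A"]], columns=["m1", "m2"],
                            index=["i1", "i2"])
        with pytest.raises(ValueError, match="all markers"):
            qtl.filter_markers_individuals(geno, mm)


def _one_individual_pop(calls: list, spacing=5.0):
    mm = _tiny_map(len(calls), spacing)
    geno = pd.DataFrame([calls], columns=mm["marker"], index=["i1"])
    return qtl.DHPopulation(geno, mm)


def _enumerate_posterior(obs, rec, error_rate):
    """Exhaustive 2-state HMM posterior by summing all state paths."""
    m = len(obs)
    paths = []
    for bits in range(2 ** m):
        states = [(bits >> j) & 1 for j in range(m)]
        p = 0.5
        for j in range(1, m):
            r = rec[j - 1]
            p *= r if states[j] != states[j - 1] else 1 - r
        for j, o in enumerate(obs):
            if o is not None:
                p *= (1 - error_rate) if o == states[j] else error_rate
        paths.append((states, p))
    total = sum(p for _, p in paths)
    post_a = [
        sum(p for s, p in paths if s[j] == 0) / total for j in range(m)
    ]
    return post_a


class TestHMM:
    def test_fully_observed_zero_error_is_certain(self):
        pop = _one_individual_pop(["A", "B", "A"])
        probs = qtl.dh_genotype_probabilities(pop, error_rate=0.0)
        assert np.allclose(probs.p_a[0], [1.0, 0.0, 1.0])

    def test_missing_midpoint_matches_exhaustive_oracle(self):
        pop = _one_individual_pop(["A", None, "A"], spacing=5.0)
        probs = qtl.dh_genotype_probabilities(pop, error_rate=0.0)
        rec = 0.5 * (1 - np.exp(-2 * 5.0 / 100))
        oracle = _enumerate_posterior([0, None, 0], [rec, rec], 0.0)
        assert np.allclose(probs.p_a[0], oracle, atol=1e-12)
        assert probs.p_a[0, 1] > 0.98

    def test_error_rate_softens_posteriors(self):
        pop = _one_individual_pop(["A", "B", "A"])
        probs = qtl.dh_genotype_probabilities(pop, error_rate=0.01)
        oracle = _enumerate_posterior([0, 1, 0],
                                      [0.5 * (1 - np.exp(-0.1))] * 2, 0.01)
        assert np.allclose(probs.p_a[0], oracle, atol=1e-12)
        assert 0.0 < probs.p_a[0, 1] < 1.0

    def test_posteriors_normalize(self, single_qtl_sim):
        sim, _ = single_qtl_sim
        pop, _ = qtl.filter_markers_individuals(
            sim.population.genotypes, sim.population.marker_map
        )
        probs = qtl.dh_genotype_probabilities(pop)
        assert np.allclose(probs.p_a + probs.p_b, 1.0, atol=1e-9)
        assert probs.p_a.min() >= 0 and probs.p_a.max() <= 1


@pytest.fixture(scope="module")
def scan_setup():
    mm = default_marker_map(3, 40, 2.5)
    truth = SimTruth(model=STANDARD_MODELS[0], causal_markers={"A": "c1m10"},
                     qtl=[("c1m10", 2.0)], seed=11)
    sim = simulate_dh_population(150, mm, truth)
    pop, _ = qtl.filter_markers_individuals(
        sim.population.genotypes, sim.population.marker_map
    )
    blues = fit_line_blues(sim.pheno).blues.set_index("line_id")["blue"]
    probs = qtl.dh_genotype_probabilities(pop)
    return sim, probs, blues


class TestScan:
    def test_single_marker_lod_matches_rss_oracle(self, scan_setup):
        sim, probs, blues = scan_setup
        lod_table = qtl.hk_scan(probs, blues)
        y = blues.reindex(probs.individuals).to_numpy()
        j = 30  # arbitrary marker
        x = probs.p_a[:, j]
        X = np.column_stack([np.ones_like(x), x])
        beta, rss1, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss0 = ((y - y.mean()) ** 2).sum()
        n = len(y)
        oracle = (n / 2) * np.log10(rss0 / rss1[0])
        assert lod_table["lod"].iloc[j] == pytest.approx(oracle, abs=1e-8)

    def test_peak_at_causal_marker(self, scan_setup):
        _, probs, blues = scan_setup
        lod_table = qtl.hk_scan(probs, blues)
        top = lod_table.loc[lod_table["lod"].idxmax()]
        truth_pos = 9 * 2.5
        assert top["chrom"] == "1"
        assert abs(top["pos_cm"] - truth_pos) <= 5.0

    def test_perfect_fit_capped_and_flagged(self, scan_setup):
        _, probs, _ = scan_setup
        y = pd.Series(probs.p_a[:, 10], index=probs.individuals)
        lod_table = qtl.hk_scan(probs, y)
        assert lod_table["lod"].iloc[10] == qtl.LOD_CAP
        assert lod_table["lod_capped"].iloc[10]

    def test_monomorphic_position_scores_zero(self):
        mm = _tiny_map(3)
        geno = pd.DataFrame(
            [["A", "A", "B"]] * 15 + [["B", "A", "A"]] * 15,
            columns=mm["marker"], index=[f"i{k}" for k in range(30)],
        )
        pop = qtl.DHPopulation(geno, mm)
        probs = qtl.dh_genotype_probabilities(pop, error_rate=0.0)
        y = pd.Series(np.random.default_rng(1).normal(size=30),
                      index=pop.genotypes.index)
        lod_table = qtl.hk_scan(probs, y)
        assert lod_table["lod"].iloc[1] == 0.0

    def test_too_few_phenotypes_rejected(self, scan_setup):
        _, probs, blues = scan_setup
        with pytest.raises(ValueError, match="< 20"):
            qtl.hk_scan(probs, blues.iloc[:10])


class TestPermutationThreshold:
    def test_constant_phenotype_gives_zero(self, scan_setup):
        _, probs, _ = scan_setup
        y = pd.Series(1.0, index=probs.individuals)
        thr, maxes = qtl.permutation_threshold(probs, y, n_perm=100)
        assert thr == 0.0 and np.all(maxes == 0.0)

    def test_threshold_nonincreasing_in_alpha(self, scan_setup):
        _, probs, blues = scan_setup
        thrs = [
            qtl.permutation_threshold(probs, blues, n_perm=300, alpha=a,
                                      seed=2)[0]
            for a in (0.01, 0.05, 0.2)
        ]
        assert thrs[0] >= thrs[1] >= thrs[2]

    def test_null_trait_max_lod_moderate(self, scan_setup, rng):
        _, probs, _ = scan_setup
        y = pd.Series(rng.normal(size=len(probs.individuals)),
                      index=probs.individuals)
        lod_table = qtl.hk_scan(probs, y)
        assert lod_table["lod"].max() < 4.5

    def test_few_permutations_warn(self, scan_setup):
        _, probs, blues = scan_setup
        with pytest.warns(UserWarning, match="unstable"):
            qtl.permutation_threshold(probs, blues, n_perm=50)


class TestPeaks:
    def test_flat_curve_no_peaks(self):
        table = pd.DataFrame(
            {"marker": [f"m{i}" for i in range(10)], "chrom": "1",
             "pos_cm": np.arange(10.0), "lod": np.full(10, 0.5)}
        )
        assert qtl.peak_intervals(table, threshold=3.0) == []

    def test_delta_spike_concentrated_interval(self):
        lod = np.full(30, 0.1)
        lod[14] = 12.0
        table = pd.DataFrame(
            {"marker": [f"m{i}" for i in range(30)], "chrom": "1",
             "pos_cm": np.arange(30.0), "lod": lod}
        )
        peaks = qtl.peak_intervals(table, threshold=3.0)
        assert len(peaks) == 1
        pk = peaks[0]
        assert pk.pos_cm == 14.0
        assert pk.interval_hi - pk.interval_lo <= 2.0
        assert pk.interval_lo <= pk.pos_cm <= pk.interval_hi

    def test_lod_drop_interval_contains_peak(self, scan_setup):
        _, probs, blues = scan_setup
        lod_table = qtl.hk_scan(probs, blues)
        peaks = qtl.peak_intervals(lod_table, threshold=3.0,
                                   method="lod_drop", drop=1.5)
        assert peaks
        for pk in peaks:
            assert pk.interval_lo <= pk.pos_cm <= pk.interval_hi
            assert pk.lod >= 3.0


class TestBLUPEffect:
    def test_null_phenotype_shrinks_toward_zero(self, scan_setup, rng):
        _, probs, _ = scan_setup
        x = probs.p_a[:, 20]
        y = rng.normal(size=len(x))
        eff, _ = qtl.blup_allele_effect(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        ols = (xc @ yc) / (xc @ xc)
        assert abs(eff) <= abs(ols) + 1e-12
        assert abs(eff) < 0.5

    def test_recovers_simulated_effect_and_donor(self, scan_setup):
        sim, probs, blues = scan_setup
        j = list(probs.marker_map["marker"]).index("c1m10")
        y = blues.reindex(probs.individuals).to_numpy()
        eff, donor = qtl.blup_allele_effect(probs.p_a[:, j], y,
                                            parents=("parentA", "parentB"))
        assert eff == pytest.approx(-2.0, abs=0.6)
        assert donor == "parentA"

    def test_recoding_flips_sign_only(self, scan_setup):
        sim, probs, blues = scan_setup
        j = list(probs.marker_map["marker"]).index("c1m10")
        y = blues.reindex(probs.individuals).to_numpy()
        eff_a, _ = qtl.blup_allele_effect(probs.p_a[:, j], y)
        eff_b, _ = qtl.blup_allele_effect(1.0 - probs.p_a[:, j], y)
        assert eff_b == pytest.approx(-eff_a, abs=1e-9)


class TestLDAndVariance:
    def test_ld_identity_and_symmetry(self, rng):
        x = rng.integers(0, 2, 500)
        d = pd.DataFrame({"m1": x, "m2": x, "m3": rng.integers(0, 2, 500)})
        r2 = qtl.ld_r2(d)
        assert r2.loc["m1", "m1"] == pytest.approx(1.0)
        assert r2.loc["m1", "m2"] == pytest.approx(1.0)  # co-inherited
        assert np.allclose(r2, r2.T)
        assert ((r2.fillna(0) >= -1e-12) & (r2.fillna(0) <= 1 + 1e-12)).all().all()

    def test_independent_markers_near_zero(self, rng):
        d = pd.DataFrame(rng.integers(0, 2, size=(10_000, 2)),
                         columns=["m1", "m2"])
        assert qtl.ld_r2(d).loc["m1", "m2"] < 0.01

    def test_variance_explained_extremes(self, rng):
        x = rng.integers(0, 2, 400).astype(float)
        assert qtl.variance_explained(3 - 2 * x, x) == pytest.approx(1.0)
        y = rng.normal(size=1000)
        xi = rng.integers(0, 2, 1000).astype(float)
        assert abs(qtl.variance_explained(y, xi)) < 0.02
        assert np.isnan(qtl.variance_explained(y[:10], np.ones(10)))


def test_bonferroni_threshold():
    assert qtl.bonferroni_threshold(0.05, 100) == pytest.approx(5e-4)
    with pytest.raises(ValueError):
        qtl.bonferroni_threshold(0.05, 0)
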