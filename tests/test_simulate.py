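"""Synthetic cohorts: coalescent panels, relatives, and sparse observations."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from ldid import (
    Diploid,
    PairingConfig,
    SimScenario,
    compare_samples,
    enumerate_pairs,
    mate,
    run_replicates,
    sample_observations,
    simulate_cohort,
)
from ldid.likelihood import llr_pair

from conftest import make_panel


class TestScenario:
    def test_defaults_are_study_conditions(self):
        sc = SimScenario()
        assert sc.n_segments * sc.segment_length_bp == 1_500_000_000
        assert sc.panel_haplotypes == 200
        assert sc.effective_size == 10_000
        assert sc.maf_floor == 0.10

    @pytest.mark.parametrize(
        "kwargs", [{"n_segments": 0}, {"maf_floor": 0.6}, {"panel_haplotypes": 1}]
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimScenario(**kwargs)


class TestSimulateCohort:
    def test_maf_floor_respected(self, small_cohort):
        panel = small_cohort.panel
        alt = panel.haplotypes.sum(axis=0).astype(int)
        minor = np.minimum(alt, panel.n_haplotypes - alt)
        assert (minor >= 0.10 * panel.n_haplotypes).all()

    def test_segments_are_pseudo_chromosomes(self, small_cohort):
        panel = small_cohort.panel
        ranges = panel.chrom_ranges()
        assert all(name.startswith("seg") for name in ranges)
        for name, (start, stop) in ranges.items():
            pos = panel.positions[start:stop]
            assert (np.diff(pos) > 0).all()
            assert pos[-1] <= 500_000

    def test_individuals_defined_on_panel_sites(self, small_cohort):
        for ind in small_cohort.individuals:
            assert ind.haplotypes.shape == (2, small_cohort.panel.n_sites)
            assert set(np.unique(ind.haplotypes)) <= {0, 1}

    def test_panel_size_and_determinism(self):
        sc = SimScenario(n_segments=3, seed=5)
        a = simulate_cohort(sc, n_individuals=2)
        b = simulate_cohort(sc, n_individuals=2)
        assert a.panel.n_haplotypes == 200
        assert a.panel == b.panel
        assert np.array_equal(
            a.individuals[0].haplotypes, b.individuals[0].haplotypes
        )

    def test_split_model_runs(self):
        sc = SimScenario(n_segments=3, split_generations=500, seed=5)
        cohort = simulate_cohort(sc, n_individuals=2)
        assert cohort.provenance["individuals_population"] == "samples"
        assert cohort.provenance["panel_population"] == "panel"
        assert cohort.panel.population_label == "sim-split"


class TestMate:
    @pytest.fixture
    def parents(self, small_cohort):
        return small_cohort.individuals

    def test_zero_recombination_transmits_whole_haplotypes(self, small_cohort):
        p1, p2 = small_cohort.individuals
        panel = small_cohort.panel
        child = mate(p1, p2, panel, recombination_rate=0.0, seed=9)
        for copy, parent in ((0, p1), (1, p2)):
            for chrom, (start, stop) in panel.chrom_ranges().items():
                seg = child.haplotypes[copy, start:stop]
                assert any(
                    np.array_equal(seg, parent.haplotypes[h, start:stop])
                    for h in (0, 1)
                )

    def test_mendelian_consistency_everywhere(self, small_cohort):
        p1, p2 = small_cohort.individuals
        panel = small_cohort.panel
        child = mate(p1, p2, panel, recombination_rate=1e-8, seed=10)
        for copy, parent in ((0, p1), (1, p2)):
            carried = (child.haplotypes[copy] == parent.haplotypes[0]) | (
                child.haplotypes[copy] == parent.haplotypes[1]
            )
            assert carried.all()

    def test_site_mismatch_fails(self, small_cohort):
        panel = make_panel([[0, 0], [0, 1], [1, 0], [1, 1]], [100, 200])
        p1, p2 = small_cohort.individuals
        with pytest.raises(ValueError, match="panel sites"):
            mate(p1, p2, panel, 1e-8, seed=1)


class TestSampleObservations:
    def _uniform_individual(self, n_sites=100_000):
        cols = np.tile([[0], [0], [1], [1]], (1, n_sites)).astype(np.uint8)
        panel = make_panel(cols, np.arange(1, n_sites + 1))
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, size=(2, n_sites)).astype(np.uint8)
        return Diploid("u", haps), panel

    def test_observed_fraction_matches_discard_formula(self):
        """P(site observed) = 2 r (1 - r): each copy drawn at rate r,
        double draws discarded. At r=0.01 that is ~0.0198."""
        ind, panel = self._uniform_individual()
        n = panel.n_sites
        for rate in (0.01, 0.5):
            obs = sample_observations(ind, panel, rate=rate, seed=31)
            p = 2 * rate * (1 - rate)
            lo, hi = scipy_stats.binom.ppf([1e-6, 1 - 1e-6], n, p)
            assert lo <= len(obs) <= hi

    def test_high_rate_discards_almost_everything(self):
        ind, panel = self._uniform_individual(10_000)
        obs = sample_observations(ind, panel, rate=0.99, seed=3)
        # expected fraction 2*0.99*0.01 ~ 2%
        assert len(obs) < 0.05 * panel.n_sites

    def test_observed_allele_is_carried_by_individual(self, small_cohort):
        ind = small_cohort.individuals[0]
        obs = sample_observations(ind, small_cohort.panel, rate=0.05, seed=8)
        for o in obs.observations:
            assert o.allele_code in ind.haplotypes[:, o.site_index]

    def test_deterministic_and_seed_sensitive(self, small_cohort):
        ind = small_cohort.individuals[0]
        a = sample_observations(ind, small_cohort.panel, 0.01, seed=1)
        b = sample_observations(ind, small_cohort.panel, 0.01, seed=1)
        c = sample_observations(ind, small_cohort.panel, 0.01, seed=2)
        assert a.observations == b.observations
        assert a.observations != c.observations

    def test_bad_rate_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            sample_observations(small_cohort.individuals[0], small_cohort.panel, 1.0, 1)


class TestEndToEnd:
    def test_gamma_lower_bound_on_all_simulated_pairs(self, small_cohort):
        panel = small_cohort.panel
        a, b = small_cohort.individuals
        o1 = sample_observations(a, panel, 0.01, seed=21)
        o2 = sample_observations(b, panel, 0.01, seed=22)
        windows = enumerate_pairs(o1, o2, panel, PairingConfig(seed=0))
        n_checked = 0
        for cands in windows.values():
            for c in cands:
                g = llr_pair(panel, c.site_i, c.allele_a, c.site_j, c.allele_b)
                assert g.llr >= -1.0
                n_checked += 1
        assert n_checked > 0

    def test_windows_bounded_by_genome_tiling(self, small_cohort):
        panel = small_cohort.panel
        a, _ = small_cohort.individuals
        o1 = sample_observations(a, panel, 0.02, seed=23)
        o2 = sample_observations(a, panel, 0.02, seed=24)
        res = compare_samples(o1, o2, panel, PairingConfig(seed=0))
        assert res.n_windows_used <= 60  # one 500-kb tile per segment

    def test_more_observations_more_signal(self, small_cohort):
        """Expected |mean Lambda| grows with observation density (generous
        tolerance; same-individual comparisons)."""
        panel = small_cohort.panel
        a, _ = small_cohort.individuals
        means = []
        for rate in (0.005, 0.02):
            vals = []
            for s in range(3):
                o1 = sample_observations(a, panel, rate, seed=100 + s)
                o2 = sample_observations(a, panel, rate, seed=200 + s)
                vals.append(
                    compare_samples(o1, o2, panel, PairingConfig(seed=s)).mean_llr
                )
            means.append(abs(np.mean(vals)))
        assert means[1] >= means[0] - 0.5


class TestRunReplicates:
    def test_table_structure_and_determinism(self):
        sc = SimScenario(n_segments=12, seed=77)
        t1 = run_replicates(sc, 2, relatives=True)
        t2 = run_replicates(sc, 2, relatives=True)
        assert t1.equals(t2)
        assert set(t1["comparison"]) == {
            "within_sample",
            "same_individual",
            "different_individuals",
            "parent_child",
            "siblings",
        }
        assert len(t1) == 2 * 7
        assert {"mean_llr", "ci_low", "ci_high", "verdict"} <= set(t1.columns)
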