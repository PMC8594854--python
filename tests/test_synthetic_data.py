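import math
from collections import Counter

import numpy as np
import pytest

import temara as tm
from conftest import ma_config


def params(u01=0.0, u12=0.0, u10=0.0, u21=0.0, **kw):
    return tm.SimulationParams(
        rates=tm.RatesConfig(u01=u01, u12=u12, u10=u10, u21=u21), **kw
    )


class TestMakeAncestor:
    def test_exact_copy_numbers_and_degenerate_het(self):
        anc = tm.make_ancestor(params(het_fraction=0.0), {"Gypsy": 100}, seed=1)
        assert anc.copy_number == {"Gypsy": 100}
        assert (anc.zygosity == 2).all()

    def test_empty_spec_is_valid(self):
        anc = tm.make_ancestor(params(), {}, seed=1)
        assert anc.sites == [] and anc.copy_number == {}

    def test_het_fraction_within_binomial_band(self):
        # P(|Binomial(100, .5) - 50| > 15) < 1e-4: [35, 65] is a 99.99% band
        anc = tm.make_ancestor(
            params(het_fraction=0.5), {"Gypsy": 100, "Pao": 50}, seed=3
        )
        gypsy_het = sum(
            1 for s, z in zip(anc.sites, anc.zygosity)
            if s.family_id == "Gypsy" and z == 1
        )
        assert 35 <= gypsy_het <= 65

    def test_candidate_pool_disjoint_from_occupied(self):
        anc = tm.make_ancestor(params(), {"Gypsy": 50}, seed=2, candidate_pool=200)
        occupied = {(s.contig, s.position) for s in anc.sites}
        assert occupied.isdisjoint(set(anc.candidate_positions))
        assert len(anc.candidate_positions) == 200

    def test_targets_exceeding_positions_error(self):
        with pytest.raises(tm.ValidationError):
            tm.make_ancestor(
                params(), {"Gypsy": 1000}, genome_size=50, n_contigs=1,
                candidate_pool=10, seed=1,
            )


class TestPropagateLine:
    def test_null_process(self):
        anc = tm.make_ancestor(params(het_fraction=0.4), {"Gypsy": 80}, seed=4)
        res = tm.propagate_line(anc, params(generations=20), seed=5)
        assert res.events == []
        assert np.array_equal(res.zygosity, anc.zygosity)

    def test_forced_loss(self):
        p = params(u10=1.0, generations=1, het_fraction=1.0)
        anc = tm.make_ancestor(p, {"Gypsy": 30}, seed=6)
        res = tm.propagate_line(anc, p, seed=7)
        assert (res.zygosity == 0).all()
        assert Counter(e.type for e in res.events) == {"loss10": 30}

    def test_gain_rate_matches_poisson_expectation(self):
        # E[gains per line] = N * u01 * G = 1000 * 1e-3 * 10 = 10
        p = params(u01=1e-3, generations=10, het_fraction=0.0)
        anc = tm.make_ancestor(p, {"Gypsy": 1000}, seed=8, candidate_pool=3000)
        counts = [
            sum(e.type == "gain01" for e in tm.propagate_line(anc, p, seed=100 + i).events)
            for i in range(200)
        ]
        expectation = 10.0
        se = math.sqrt(expectation / len(counts))
        assert abs(np.mean(counts) - expectation) < 3 * se

    def test_conservation_invariant(self):
        # occupied-site delta == #gain01 - #loss10 for every line
        p = params(u01=5e-3, u12=2e-3, u10=5e-3, u21=2e-3,
                   generations=12, het_fraction=0.5)
        anc = tm.make_ancestor(p, {"Gypsy": 300, "Pao": 100}, seed=9)
        for i in range(10):
            res = tm.propagate_line(anc, p, seed=200 + i)
            delta = int((res.zygosity >= 1).sum()) - len(anc.sites)
            c = Counter(e.type for e in res.events)
            assert delta == c["gain01"] - c["loss10"]

    def test_pool_exhaustion_is_advised(self):
        p = params(u01=0.5, generations=10)
        anc = tm.make_ancestor(p, {"Gypsy": 100}, seed=10, candidate_pool=5)
        with pytest.raises(tm.ValidationError, match="candidate_pool"):
            tm.propagate_line(anc, p, seed=11)

    def test_determinism(self):
        p = params(u01=1e-2, u10=1e-2, generations=12, het_fraction=0.5)
        anc = tm.make_ancestor(p, {"Gypsy": 200}, seed=12)
        a = tm.propagate_line(anc, p, seed=13)
        b = tm.propagate_line(anc, p, seed=13)
        assert a.events == b.events
        assert np.array_equal(a.zygosity, b.zygosity)


class TestSimulateEvidence:
    def test_noiseless_extremes(self):
        p = params(epsilon=0.0, depth=40, het_fraction=0.0)
        anc = tm.make_ancestor(p, {"Gypsy": 50}, seed=14)
        hom = tm.simulate_evidence(anc.sites, np.full(50, 2), p, seed=15)
        assert (hom.absence_reads == 0).all()
        absent = tm.simulate_evidence(anc.sites, np.zeros(50, dtype=int), p, seed=16)
        assert (absent.presence_reads == 0).all()

    def test_het_presence_fraction(self):
        p = params(depth=50, epsilon=0.0)
        anc = tm.make_ancestor(p, {"Gypsy": 10_000}, seed=17, candidate_pool=100)
        ev = tm.simulate_evidence(anc.sites, np.ones(10_000, dtype=int), p, seed=18)
        frac = ev.presence_reads.sum() / (ev.presence_reads + ev.absence_reads).sum()
        se = 0.5 / math.sqrt(50 * 10_000)
        assert abs(frac - 0.5) < 3 * se

    def test_determinism(self):
        p = params(depth=30)
        anc = tm.make_ancestor(p, {"Gypsy": 40}, seed=19)
        a = tm.simulate_evidence(anc.sites, anc.zygosity, p, seed=20)
        b = tm.simulate_evidence(anc.sites, anc.zygosity, p, seed=20)
        assert a.equals(b)


class TestEvolveCopies:
    def test_null_mutation(self):
        copies = tm.evolve_copies("ACGTACGT", 5, 0.0, seed=21)
        assert copies == ["ACGTACGT"] * 5

    def test_two_branch_divergence_expectation(self):
        # per-site: both branches mutate independently with p; they differ with
        # probability 2p(1-p) + p^2 * 2/3 (two uniform picks among 3 bases)
        p = 0.05
        expected = 2 * p * (1 - p) + p * p * (2 / 3)
        consensus = "ACGT" * 2500
        a, b = tm.evolve_copies(consensus, 2, p, seed=22)
        observed = sum(x != y for x, y in zip(a, b)) / len(consensus)
        se = math.sqrt(expected * (1 - expected) / len(consensus))
        assert abs(observed - expected) < 3 * se

    def test_single_copy_gives_undefined_mpd(self):
        (copy,) = tm.evolve_copies("ACGT" * 10, 1, 0.05, seed=23)
        res = tm.mean_pairwise_divergence([copy])
        assert res.mpd is None and res.n_pairs == 0

    def test_empty_consensus_rejected(self):
        with pytest.raises(tm.ValidationError):
            tm.evolve_copies("", 2, 0.05)


class TestPopulationPanel:
    def test_all_singletons(self):
        tip = tm.make_population_panel(3, 3, 0, 0, 9, seed=24)
        assert (tip.matrix.sum(axis=1) == 1).all()

    def test_shared_sites_span_populations(self):
        tip = tm.make_population_panel(3, 3, 5, 0, 0, seed=25)
        pops = np.array([tip.population_of(g) for g in tip.genotypes])
        for _, row in tip.matrix.iterrows():
            assert len(set(pops[row.to_numpy().astype(bool)])) >= 2

    def test_round_trip_with_polymorphism_summary(self):
        tip = tm.make_population_panel(3, 3, 4, 6, 5, seed=26)
        summary = tm.polymorphism_summary(tip)
        assert summary.shared == 4
        assert summary.population_specific == 6
        assert summary.singletons == 5

    def test_private_requires_two_genotypes(self):
        with pytest.raises(tm.ValidationError):
            tm.make_population_panel(3, 1, 0, 2, 0, seed=27)


class TestExperiment:
    def test_truth_log_consistent_with_dataset(self, small_experiment):
        truth = small_experiment.truth
        ds = small_experiment.dataset
        assert set(truth.line_id) <= set(ds.lineages.line_id)
        assert set(truth.site_id) <= set(ds.sites.site_id)
        assert set(truth.type) <= set(tm.EVENT_TYPES)
        gens = truth.generation
        assert ((gens >= 1) & (gens <= 12)).all()

    def test_identical_seed_identical_outputs(self):
        cfg = ma_config(seed=31, n_ma_lines=2, families={"Gypsy": 60})
        a = tm.simulate_experiment(cfg)
        b = tm.simulate_experiment(cfg)
        assert a.dataset.evidence.equals(b.dataset.evidence)
        assert a.truth.equals(b.truth)
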