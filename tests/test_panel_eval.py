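import numpy as np
import pytest

import aimeval as av

from conftest import make_gm


@pytest.fixture(scope="module")
def reference_Q(three_pop_sim, est_freqs):
    _, _, gm = three_pop_sim
    return av.genome_ancestry_reference(gm, est_freqs)


class TestReference:
    def test_unadmixed_individuals_strongly_assigned(
        self, three_pop_sim, est_freqs, reference_Q
    ):
        _, _, gm = three_pop_sim
        own = [reference_Q.Q[i, est_freqs.pops.index(p)]
               for i, p in enumerate(gm.pop_labels)]
        assert np.mean(own) > 0.97

    def test_full_panel_reproduces_reference_bit_exactly(
        self, three_pop_sim, est_freqs, reference_Q
    ):
        _, _, gm = three_pop_sim
        panel = av.PanelDefinition("all", list(gm.loci))
        sub, _ = av.subset_by_panel(gm, panel)
        Q = av.supervised_ancestry(sub, est_freqs).Q.Q
        np.testing.assert_array_equal(Q, reference_Q.Q)


class TestRsnpResampling:
    def test_dispersion_larger_for_smaller_panels(
        self, three_pop_sim, est_freqs
    ):
        _, _, gm = three_pop_sim
        summ = av.rsnp_resampling(gm, est_freqs, [400, 40], n_reps=30,
                                  seed=60)
        sd = {(s.group, s.panel_size): s.sd for s in summ
              if s.group == s.ancestry}
        for g in est_freqs.pops:
            assert sd[(g, 40)] > sd[(g, 400)]

    def test_full_size_panel_has_zero_replicate_sd(
        self, three_pop_sim, est_freqs
    ):
        _, _, gm = three_pop_sim
        summ = av.rsnp_resampling(gm, est_freqs, [gm.n_loci], n_reps=5,
                                  seed=61)
        assert all(s.sd == 0 for s in summ)

    def test_deterministic_under_seed(self, three_pop_sim, est_freqs):
        _, _, gm = three_pop_sim
        a = av.rsnp_resampling(gm, est_freqs, [50], n_reps=5, seed=62)
        b = av.rsnp_resampling(gm, est_freqs, [50], n_reps=5, seed=62)
        assert [(s.mean, s.sd) for s in a] == [(s.mean, s.sd) for s in b]

    def test_oversized_panel_rejected(self, three_pop_sim, est_freqs):
        _, _, gm = three_pop_sim
        with pytest.raises(ValueError, match="panel size"):
            av.rsnp_resampling(gm, est_freqs, [gm.n_loci + 1], n_reps=1,
                               seed=0)

    def test_admixed_group_reports_every_component(
        self, three_pop_sim, est_freqs
    ):
        _, _, gm = three_pop_sim
        aa = av.make_aa_genomes(gm, 6, seed=63)
        summ = av.rsnp_resampling(aa, est_freqs, [100], n_reps=5, seed=64)
        assert {s.ancestry for s in summ} == set(est_freqs.pops)
        for s in summ:
            assert abs(s.mean - 100 / 3) < 15


class TestEvaluatePanel:
    def test_effective_size_recorded_for_partial_overlap(
        self, three_pop_sim, est_freqs
    ):
        _, _, gm = three_pop_sim
        panel = av.PanelDefinition("p", list(gm.loci[:20]) + ["absent1"])
        summ = av.evaluate_panel(gm, est_freqs, panel)
        assert all(s.panel_size == 20 for s in summ)

    def test_summary_rows_are_per_individual(self, three_pop_sim, est_freqs):
        cfg, _, gm = three_pop_sim
        panel = av.PanelDefinition("p", list(gm.loci[:50]))
        summ = av.evaluate_panel(gm, est_freqs, panel)
        own = [s for s in summ if s.group == s.ancestry]
        assert len(own) == 3
        assert all(s.n_replicates == cfg.n_per_pop for s in own)
        assert all(s.minimum <= s.mean <= s.maximum for s in own)

    def test_disjoint_panel_rejected(self, three_pop_sim, est_freqs):
        _, _, gm = three_pop_sim
        with pytest.raises(ValueError, match="no loci"):
            av.evaluate_panel(gm, est_freqs,
                              av.PanelDefinition("p", ["nope"]))


class TestPanelError:
    def _props(self, Q):
        return av.AncestryProportions(
            [f"s{i}" for i in range(len(Q))], ["A", "B"], np.asarray(Q)
        )

    def test_identical_estimates_give_zero_error(self):
        q = self._props([[0.7, 0.3], [0.2, 0.8]])
        rep = av.panel_error(q, q)
        assert all(e == 0 for e in rep.errors.values())

    def test_constant_offset_recovered_exactly(self):
        ref = self._props([[0.6, 0.4]] * 10)
        panel = self._props([[0.65, 0.35]] * 10)
        rep = av.panel_error(panel, ref)
        assert rep.errors["A"] == pytest.approx(0.05)
        assert rep.errors["B"] == pytest.approx(0.05)

    def test_random_perturbation_recovers_sigma(self):
        rng = np.random.default_rng(70)
        sigma = 0.02
        base = np.full((3000, 2), 0.5)
        eps = rng.normal(0, sigma, size=3000)
        panel = np.column_stack([0.5 + eps, 0.5 - eps])
        rep = av.panel_error(self._props(panel), self._props(base))
        assert rep.errors["A"] == pytest.approx(sigma, rel=0.1)

    def test_sample_mismatch_rejected(self):
        a = self._props([[0.5, 0.5]])
        b = av.AncestryProportions(["other"], ["A", "B"],
                                   np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError, match="different samples"):
            av.panel_error(a, b)


class TestSampleSize:
    def test_interval_narrows_with_sample_size(self, three_pop_sim, est_freqs):
        _, _, gm = three_pop_sim
        panel = av.PanelDefinition("p", list(gm.loci[:60]))
        res = av.sample_size_experiment(gm, est_freqs, panel,
                                        sizes=(5, 25), n_subsamples=300,
                                        seed=71)
        for g in est_freqs.pops:
            rows = {r.size: r for r in res
                    if r.group == g and r.ancestry == g}
            assert (rows[25].ci_high - rows[25].ci_low) < \
                (rows[5].ci_high - rows[5].ci_low)

    def test_single_full_draw_equals_population_mean(
        self, three_pop_sim, est_freqs
    ):
        cfg, _, gm = three_pop_sim
        panel = av.PanelDefinition("p", list(gm.loci))
        res = av.sample_size_experiment(gm, est_freqs, panel,
                                        sizes=(cfg.n_per_pop,),
                                        n_subsamples=1, seed=72)
        Q = av.supervised_ancestry(gm, est_freqs).Q.Q
        labels = np.asarray(gm.pop_labels)
        for r in (x for x in res if x.group == x.ancestry):
            expect = Q[labels == r.group,
                       est_freqs.pops.index(r.ancestry)].mean() * 100
            assert r.mean == pytest.approx(expect)
            assert r.ci_low == pytest.approx(r.ci_high)

    def test_oversized_subsample_rejected(self, three_pop_sim, est_freqs):
        cfg, _, gm = three_pop_sim
        panel = av.PanelDefinition("p", list(gm.loci[:30]))
        with pytest.raises(ValueError, match="exceeds"):
            av.sample_size_experiment(gm, est_freqs, panel,
                                      sizes=(cfg.n_per_pop + 1,),
                                      n_subsamples=2, seed=73)

    def test_low_call_rate_profiles_filtered_first(self, est_freqs,
                                                   three_pop_sim):
        _, _, gm = three_pop_sim
        G = gm.G.copy()
        G[0, : int(0.2 * gm.n_loci)] = av.MISSING  # call rate 0.8 < 0.9
        noisy = av.GenotypeMatrix(list(gm.samples), list(gm.loci), G,
                                  list(gm.pop_labels))
        panel = av.PanelDefinition("p", list(gm.loci[:40]))
        with pytest.raises(ValueError, match="filtered profiles"):
            # POP1 drops to 29 profiles after filtering
            av.sample_size_experiment(noisy, est_freqs, panel, sizes=(30,),
                                      n_subsamples=2, seed=74)


class TestSizeErrorCorrelation:
    def _reports(self, errors_by_size):
        return [
            av.ErrorReport(panel=f"p{s}", size=s, errors=e)
            for s, e in errors_by_size.items()
        ]

    def test_decreasing_error_gives_negative_correlation(self):
        reps = self._reports({
            10: {"A": 0.2, "B": 0.25},
            100: {"A": 0.05, "B": 0.06},
            1000: {"A": 0.01, "B": 0.02},
        })
        corr = av.size_error_correlation(reps)
        assert corr["A"] < 0 and corr["B"] < 0 and corr["pooled"] < 0

    def test_constant_errors_flagged_undefined(self):
        reps = self._reports({10: {"A": 0.1}, 20: {"A": 0.1},
                              30: {"A": 0.1}})
        with pytest.warns(UserWarning, match="undefined"):
            corr = av.size_error_correlation(reps)
        assert np.isnan(corr["A"])

    def test_too_few_sizes_rejected(self):
        reps = self._reports({10: {"A": 0.1}, 20: {"A": 0.2}})
        with pytest.raises(ValueError, match="distinct"):
            av.size_error_correlation(reps)


def test_eval_summary_ordering_enforced():
    with pytest.raises(ValueError, match="ordering"):
        av.EvalSummary(group="g", ancestry="a", mean=50.0, sd=1.0,
                       ci_low=60.0, ci_high=70.0, minimum=40.0,
                       maximum=80.0, panel_size=10, n_replicates=5)


def test_admixed_error_exceeds_unadmixed_at_equal_panel_size(
    three_pop_sim, est_freqs
):
    """Admixture penalty: at a fixed small panel size, RMS error about the
    full-data reference tends to be larger for hybrids than for unadmixed
    genomes (pooled over replicates, not per replicate)."""
    _, _, gm = three_pop_sim
    aa = av.make_aa_genomes(gm, 30, seed=80)
    ref_un = av.genome_ancestry_reference(gm, est_freqs)
    ref_aa = av.genome_ancestry_reference(aa, est_freqs)
    rng = np.random.default_rng(81)
    err_un, err_aa = [], []
    for _ in range(10):
        idx = sorted(rng.choice(gm.n_loci, 60, replace=False))
        q_un = av.supervised_ancestry(gm.take_loci(idx), est_freqs).Q
        q_aa = av.supervised_ancestry(aa.take_loci(idx), est_freqs).Q
        err_un.append(np.mean(list(
            av.panel_error(q_un, ref_un).errors.values())))
        err_aa.append(np.mean(list(
            av.panel_error(q_aa, ref_aa).errors.values())))
    assert np.mean(err_aa) > np.mean(err_un)
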