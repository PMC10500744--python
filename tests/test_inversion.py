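"""Monte Carlo inversion: primitives, full per-voxel algorithm, ensembles."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest

import rd5d
from rd5d import (Component, DiscreteDistribution, InversionConfig,
                  SamplingBox, bootstrap_ensemble, invert_voxel,
                  iso_delta_from_eigs, repair_voxel, synthesize_signal,
                  to_iso_delta)
from rd5d.inversion import (merge_and_refit, mutate, nnls_fit, prune_nonzero,
                            seed_components)
from conftest import random_component

BOX = SamplingBox()
FAST = InversionConfig(n_seed=100, n_merge_rounds=8, n_mutation_rounds=8,
                       n_ensemble=4)


class TestSeeding:
    def test_all_inside_box_and_deterministic(self):
        a = seed_components(BOX, 500, np.random.default_rng(7))
        b = seed_components(BOX, 500, np.random.default_rng(7))
        assert BOX.contains(a)
        np.testing.assert_array_equal(a.r2, b.r2)
        np.testing.assert_array_equal(a.phi, b.phi)
        assert np.all(a.weights == 0)

    def test_marginals_uniform_on_each_axis(self):
        d = seed_components(BOX, 1000, np.random.default_rng(1))
        marginals = {
            "log_r2": (np.log10(d.r2) - BOX.log10_r2[0]) / 1.5,
            "log_d_par": (np.log10(d.d_par) + 10.0) / 1.5,
            "log_d_perp": (np.log10(d.d_perp) + 10.0) / 1.5,
            "cos_theta": np.cos(d.theta),
            "phi": d.phi / (2 * np.pi),
        }
        for name, u in marginals.items():
            assert kstest(u, "uniform").pvalue > 0.01, name


class TestNNLS:
    def test_recovers_single_generating_component(self, mini_scheme):
        dic = seed_components(BOX, 40, np.random.default_rng(3))
        weights = np.zeros(40)
        weights[17] = 7.0
        signal = synthesize_signal(mini_scheme, dic.with_weights(weights))
        w, ssr = nnls_fit(mini_scheme, dic, signal)
        assert w[17] == pytest.approx(7.0, rel=1e-6)
        assert ssr == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.delete(w, 17), 0.0, atol=1e-6)

    def test_zero_signal_gives_zero_weights(self, mini_scheme):
        dic = seed_components(BOX, 10, np.random.default_rng(0))
        w, ssr = nnls_fit(mini_scheme, dic, np.zeros(len(mini_scheme)))
        np.testing.assert_array_equal(w, 0.0)
        assert ssr == 0.0

    def test_extra_column_never_raises_ssr(self, mini_scheme):
        rng = np.random.default_rng(5)
        dic = seed_components(BOX, 20, rng)
        signal = np.abs(rng.normal(0.5, 0.1, len(mini_scheme)))
        _, ssr20 = nnls_fit(mini_scheme, dic, signal)
        bigger = dic.concat(seed_components(BOX, 1, rng))
        _, ssr21 = nnls_fit(mini_scheme, bigger, signal)
        assert ssr21 <= ssr20 + 1e-12

    def test_dimension_mismatch_rejected(self, mini_scheme):
        dic = seed_components(BOX, 5, np.random.default_rng(0))
        with pytest.raises(ValueError):
            nnls_fit(mini_scheme, dic, np.zeros(len(mini_scheme) + 1))

    def test_matches_exhaustive_kkt_enumeration(self):
        """Lawson–Hanson agrees with brute-force active-set search on a
        3-point scheme and a 2-component dictionary."""
        sch = rd5d.AcquisitionScheme(
            tau_e=[0.05, 0.10, 0.15], b=[0.1e9, 1e9, 2e9],
            b_delta=[1.0, 0.0, -0.5], Theta=[0.0, 0.3, 1.2],
            Phi=[0.0, 1.0, 2.0])
        dic = seed_components(BOX, 2, np.random.default_rng(11))
        K = rd5d.kernel_matrix(sch, dic)
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.uniform(-0.5, 1.0, 3)  # include infeasible targets
            w, ssr = nnls_fit(sch, dic, s)
            best_w, best_ssr = None, np.inf
            for active in itertools.chain.from_iterable(
                    itertools.combinations([0, 1], k) for k in (0, 1, 2)):
                cand = np.zeros(2)
                if active:
                    sub = K[:, active]
                    sol, *_ = np.linalg.lstsq(sub, s, rcond=None)
                    if np.any(sol < 0):
                        continue
                    cand[list(active)] = sol
                r = s - K @ cand
                if r @ r < best_ssr - 1e-15:
                    best_ssr, best_w = r @ r, cand
            assert ssr == pytest.approx(best_ssr, abs=1e-10)
            np.testing.assert_allclose(w, best_w, atol=1e-6)


class TestPruneMergeMutate:
    def test_prune_keeps_only_nonzero(self):
        dic = seed_components(BOX, 3, np.random.default_rng(0))
        kept = prune_nonzero(dic, np.array([0.0, 1.0, 0.0]))
        assert len(kept) == 1
        assert kept.s0 == 1.0

    def test_prune_conserves_total_weight(self):
        dic = seed_components(BOX, 6, np.random.default_rng(1))
        w = np.array([0.0, 0.5, 0.0, 2.0, 0.0, 0.25])
        assert prune_nonzero(dic, w).s0 == pytest.approx(w.sum())

    def test_prune_all_zero_gives_trivial_solution(self):
        dic = seed_components(BOX, 3, np.random.default_rng(0))
        assert len(prune_nonzero(dic, np.zeros(3))) == 0

    def test_merge_keeps_exact_generators_at_zero_residual(self, mini_scheme):
        rng = np.random.default_rng(8)
        truth = DiscreteDistribution.from_components(
            [random_component(rng, weight=1.0)])
        signal = synthesize_signal(mini_scheme, truth)
        merged, ssr = merge_and_refit(truth, BOX, mini_scheme, signal, rng,
                                      n_seed=50)
        assert ssr == pytest.approx(0.0, abs=1e-10)

    def test_merge_never_raises_ssr(self, mini_scheme):
        rng = np.random.default_rng(9)
        signal = np.abs(rng.normal(0.4, 0.1, len(mini_scheme)))
        current = DiscreteDistribution.empty()
        prev = np.inf
        for _ in range(6):
            current, ssr = merge_and_refit(current, BOX, mini_scheme, signal,
                                           rng, n_seed=60)
            assert ssr <= prev + 1e-12
            prev = ssr

    def test_mutate_stays_in_box_and_small_sigma_is_identity_like(self):
        rng = np.random.default_rng(3)
        dist = seed_components(BOX, 50, rng)
        mut = mutate(dist, 1e-9, 1e-9, rng, BOX)
        assert BOX.contains(mut)
        np.testing.assert_allclose(mut.r2, dist.r2, rtol=1e-6)
        big = mutate(dist, 0.5, 0.5, rng, BOX)
        assert BOX.contains(big)

    def test_mutate_empty_returns_empty(self):
        out = mutate(DiscreteDistribution.empty(), 0.05, 0.1,
                     np.random.default_rng(0), BOX)
        assert len(out) == 0


class TestInvertVoxel:
    def test_noiseless_single_component_recovery(self, mini_scheme):
        rng = np.random.default_rng(21)
        c = random_component(rng, weight=1.0)
        signal = synthesize_signal(
            mini_scheme, DiscreteDistribution.from_components([c]))
        dist, ssr = invert_voxel(signal, mini_scheme, rng=2)
        assert 0 < len(dist) <= 10
        f = dist.weights / dist.s0
        iso = to_iso_delta(dist)
        d_iso_t, d_delta_t = iso_delta_from_eigs(c.d_par, c.d_perp)
        assert abs(np.log10(f @ iso["r2"]) - np.log10(c.r2)) \
            <= 0.05 * abs(np.log10(c.r2)) + 0.02
        assert abs(np.log10(f @ iso["d_iso"]) - np.log10(d_iso_t)) \
            <= 0.05 * abs(np.log10(d_iso_t))
        assert abs(f @ iso["d_delta"] - d_delta_t) <= 0.1
        assert dist.s0 == pytest.approx(1.0, rel=0.02)

    def test_noiseless_two_population_voxel(self, mini_scheme):
        wm = rd5d.preset_component("wm", rng=1, weight=0.5)
        csf = rd5d.preset_component("csf", weight=0.5)
        truth = DiscreteDistribution.from_components([wm, csf])
        signal = synthesize_signal(mini_scheme, truth)
        dist, _ = invert_voxel(signal, mini_scheme, rng=3)
        iso = to_iso_delta(dist)
        fast = iso["d_iso"] > 1.5e-9  # CSF-like cluster
        f_fast = iso["weights"][fast].sum() / dist.s0
        assert f_fast == pytest.approx(0.5, abs=0.1)

    def test_pure_noise_yields_negligible_structure(self, mini_scheme):
        rng = np.random.default_rng(6)
        noise = rng.normal(0.0, 0.01, len(mini_scheme))
        dist, _ = invert_voxel(noise, mini_scheme, rng=4, config=FAST)
        assert dist.s0 < 0.15

    def test_non_finite_signal_rejected(self, mini_scheme):
        bad = np.full(len(mini_scheme), np.nan)
        with pytest.raises(ValueError):
            invert_voxel(bad, mini_scheme)

    def test_ssr_trace_monotone(self, mini_scheme):
        rng = np.random.default_rng(12)
        c = random_component(rng, weight=1.0)
        s = synthesize_signal(mini_scheme,
                              DiscreteDistribution.from_components([c]))
        s = np.abs(s + rng.normal(0, 0.02, len(s)))
        _, _, trace = invert_voxel(s, mini_scheme, rng=5, return_trace=True)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_final_component_budget_and_box(self, mini_scheme):
        rng = np.random.default_rng(13)
        comps = [random_component(rng, weight=0.3) for _ in range(4)]
        s = synthesize_signal(mini_scheme,
                              DiscreteDistribution.from_components(comps))
        dist, _ = invert_voxel(s, mini_scheme, rng=6)
        assert len(dist) <= 10
        assert BOX.contains(dist)
        assert np.all(dist.weights >= 0)


class TestEnsembles:
    def test_reproducible_given_seed(self, mini_scheme):
        rng = np.random.default_rng(30)
        c = random_component(rng, weight=1.0)
        s = synthesize_signal(mini_scheme,
                              DiscreteDistribution.from_components([c]))
        cfg = InversionConfig(n_seed=80, n_merge_rounds=5,
                              n_mutation_rounds=5, n_ensemble=2)
        a = bootstrap_ensemble(s, mini_scheme, cfg, seed=9, voxel_index=3)
        b = bootstrap_ensemble(s, mini_scheme, cfg, seed=9, voxel_index=3)
        assert len(a) == 2
        for sa, sb in zip(a.solutions, b.solutions):
            np.testing.assert_array_equal(sa.r2, sb.r2)
            np.testing.assert_array_equal(sa.weights, sb.weights)

    def test_default_ensemble_size_is_96(self):
        assert InversionConfig().n_ensemble == 96

    def test_noiseless_spread_smaller_than_noisy(self, mini_scheme):
        rng = np.random.default_rng(31)
        c = random_component(rng, weight=1.0)
        clean = synthesize_signal(mini_scheme,
                                  DiscreteDistribution.from_components([c]))
        noisy = np.abs(clean + rng.normal(0, 0.02, len(clean))
                       + 1j * rng.normal(0, 0.02, len(clean)))
        cfg = InversionConfig(n_seed=100, n_merge_rounds=8,
                              n_mutation_rounds=8, n_ensemble=8,
                              bootstrap=False)

        def mad_of_e_diso(signal):
            ens = bootstrap_ensemble(signal, mini_scheme, cfg, seed=2)
            vals = [rd5d.distribution_moments(sol).e["d_iso"]
                    for sol in ens.solutions]
            med = np.median(vals)
            return np.median(np.abs(np.array(vals) - med))

        assert mad_of_e_diso(clean) < mad_of_e_diso(noisy)


class TestRepair:
    def test_recovers_from_neighbor_pool(self, mini_scheme):
        rng = np.random.default_rng(40)
        c = random_component(rng, weight=1.0)
        truth = DiscreteDistribution.from_components([c])
        signal = synthesize_signal(mini_scheme, truth)
        own = DiscreteDistribution.empty()
        fixed = repair_voxel(own, [truth], mini_scheme, signal)
        assert fixed is not None
        f = fixed.weights / fixed.s0
        iso = to_iso_delta(fixed)
        d_iso_t, _ = iso_delta_from_eigs(c.d_par, c.d_perp)
        assert f @ iso["d_iso"] == pytest.approx(d_iso_t, rel=0.05)

    def test_empty_pool_flags_unrecoverable(self, mini_scheme):
        out = repair_voxel(DiscreteDistribution.empty(), [], mini_scheme,
                           np.ones(len(mini_scheme)))
        assert out is None

    def test_pooled_fit_beats_trivial_solution(self, mini_scheme):
        rng = np.random.default_rng(41)
        c = random_component(rng, weight=1.0)
        truth = DiscreteDistribution.from_components([c])
        signal = synthesize_signal(mini_scheme, truth)
        fixed = repair_voxel(DiscreteDistribution.empty(), [truth],
                             mini_scheme, signal)
        _, ssr = nnls_fit(mini_scheme, fixed, signal)
        assert ssr < signal @ signal


class TestIsoDeltaMapping:
    def test_isotropic_maps_to_zero_anisotropy(self):
        d = DiscreteDistribution.from_components(
            [Component(10.0, 1e-9, 1e-9, weight=2.0)])
        iso = to_iso_delta(d)
        assert iso["d_delta"][0] == 0.0
        assert iso["weights"][0] == 2.0

    def test_ratio_four_maps_to_half(self):
        d = DiscreteDistribution.from_components(
            [Component(10.0, 4e-9, 1e-9)])
        assert to_iso_delta(d)["d_delta"][0] == pytest.approx(0.5)

    def test_round_trip_through_eigenvalues(self):
        rng = np.random.default_rng(2)
        d = seed_components(BOX, 20, rng)
        iso = to_iso_delta(d)
        d_par, d_perp = rd5d.eigs_from_iso_delta(iso["d_iso"],
                                                 iso["d_delta"])
        np.testing.assert_allclose(d_par, d.d_par, rtol=1e-12)
        np.testing.assert_allclose(d_perp, d.d_perp, rtol=1e-12)


class TestEstimator:
    def test_fit_produces_per_voxel_ensembles(self, mini_scheme):
        rng = np.random.default_rng(50)
        X = np.stack([synthesize_signal(
            mini_scheme, DiscreteDistribution.from_components(
                [random_component(rng, weight=1.0)])) for _ in range(3)])
        inv = rd5d.MonteCarloInverter(
            mini_scheme, n_seed=80, n_merge_rounds=5, n_mutation_rounds=5,
            n_ensemble=2, random_state=1)
        inv.fit(X)
        assert len(inv.ensembles_) == 3
        assert all(len(e) == 2 for e in inv.ensembles_)

    def test_results_independent_of_worker_count(self, mini_scheme):
        rng = np.random.default_rng(51)
        X = np.stack([synthesize_signal(
            mini_scheme, DiscreteDistribution.from_components(
                [random_component(rng, weight=1.0)])) for _ in range(2)])
        kw = dict(n_seed=60, n_merge_rounds=4, n_mutation_rounds=4,
                  n_ensemble=2, random_state=3)
        a = rd5d.MonteCarloInverter(mini_scheme, n_jobs=1, **kw).fit(X)
        b = rd5d.MonteCarloInverter(mini_scheme, n_jobs=2, **kw).fit(X)
        for ea, eb in zip(a.ensembles_, b.ensembles_):
            for sa, sb in zip(ea.solutions, eb.solutions):
                np.testing.assert_array_equal(sa.weights, sb.weights)

    def test_sklearn_get_set_params(self, mini_scheme):
        inv = rd5d.MonteCarloInverter(mini_scheme)
        params = inv.get_params(deep=False)
        assert params["n_ensemble"] == 96
        inv.set_params(n_ensemble=8)
        assert inv.n_ensemble == 8
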