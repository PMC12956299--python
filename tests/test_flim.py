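import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from mesomux import (
    GAConfig,
    GateGene,
    IRFTrace,
    assemble_decay_stack,
    convolve_model,
    decay_basis,
    fit_lifetime_ls,
    fit_lifetime_poisson,
    four_gate_lifetime,
    ga_optimize_gates,
    lifetime_noise_study,
    phasor_coordinates,
    phasor_lifetime,
    preprocess_four_gate,
    simulate_decay_stack,
    window_means,
)
from mesomux.flim import DT_NS, OMEGA

ALL_BIN_GENE = GateGene((0, 9, 10, 19, 20, 29, 30, 39))


def oracle_convolve(u, A, B, tau, dt=DT_NS):
    """Scalar triple-period convolution reference."""
    un = np.asarray(u, float) / np.sum(u)
    ue = list(un) * 3
    e = [np.exp(-j * dt / tau) for j in range(120)]
    out = []
    for n in range(40, 80):
        s = 0.0
        for j, uj in enumerate(ue):
            if 0 <= n - j < 120:
                s += uj * e[n - j]
        out.append(A * s + B)
    return np.array(out)


class TestAssembleStack:
    def test_identity_placement(self):
        acqs = [(s, np.full((2, 2, 4), s)) for s in range(0, 40, 4)]
        stack = assemble_decay_stack(acqs)
        for s in range(0, 40, 4):
            assert np.all(stack.cube[..., s : s + 4] == s)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        acqs = [(s, rng.random((3, 4))) for s in range(0, 40, 4)]
        a = assemble_decay_stack(acqs)
        b = assemble_decay_stack(acqs[::-1])
        assert np.array_equal(a.cube, b.cube)

    def test_missing_window_rejected(self):
        acqs = [(s, np.zeros((2, 4))) for s in range(0, 36, 4)]
        with pytest.raises(ValueError):
            assemble_decay_stack(acqs)

    def test_overlapping_windows_rejected(self):
        acqs = [(s, np.zeros((2, 4))) for s in range(0, 36, 4)] + [(2, np.zeros((2, 4)))]
        with pytest.raises(ValueError):
            assemble_decay_stack(acqs)


class TestConvolveModel:
    def test_matches_scalar_oracle(self, irf):
        got = convolve_model(irf, 100.0, 2.0, 2.0)
        assert got == pytest.approx(oracle_convolve(irf.u, 100.0, 2.0, 2.0),
                                    abs=1e-12)

    @given(tau=st.floats(0.5, 8.0), A=st.floats(0.0, 500.0), B=st.floats(0.0, 10.0))
    @settings(deadline=None, max_examples=25)
    def test_oracle_property(self, irf, tau, A, B):
        got = convolve_model(irf, A, B, tau)
        assert np.allclose(got, oracle_convolve(irf.u, A, B, tau), atol=1e-10)

    def test_zero_amplitude_gives_offset(self, irf):
        assert convolve_model(irf, 0.0, 3.0, 1.5) == pytest.approx(np.full(40, 3.0))

    def test_delta_irf_gives_wrapped_exponential(self):
        delta = np.zeros(40)
        delta[0] = 1.0
        u = IRFTrace(delta)
        tau = 2.5
        k = np.arange(40) * DT_NS
        expected = np.exp(-k / tau) + np.exp(-(k + 12.5) / tau)
        assert convolve_model(u, 1.0, 0.0, tau) == pytest.approx(expected, rel=1e-12)

    def test_shifting_irf_shifts_model(self):
        delta = np.zeros(40)
        delta[0] = 1.0
        m = 5
        base = convolve_model(IRFTrace(delta), 1.0, 0.0, 1.5)
        shifted = convolve_model(IRFTrace(np.roll(delta, m)), 1.0, 0.0, 1.5)
        assert shifted == pytest.approx(np.roll(base, m), rel=1e-3)

    def test_invalid_tau_rejected(self, irf):
        with pytest.raises(ValueError):
            convolve_model(irf, 1.0, 0.0, -1.0)


class TestLeastSquaresFit:
    def test_noiseless_parameter_recovery(self, irf):
        y = convolve_model(irf, 100.0, 2.0, 2.0)
        fit = fit_lifetime_ls(y, irf)
        assert fit.tau == pytest.approx(2.0, abs=0.02)
        assert fit.A == pytest.approx(100.0, rel=0.01)
        assert fit.B == pytest.approx(2.0, abs=0.05)
        assert fit.corr > 0.9999

    def test_constant_trace_flagged_unidentifiable(self, irf):
        fit = fit_lifetime_ls(np.full(40, 7.0), irf)
        assert fit.A == pytest.approx(0.0, abs=1e-6)
        assert not fit.identifiable

    def test_optimum_beats_dense_grid(self, irf):
        rng = np.random.default_rng(2)
        y = convolve_model(irf, 80.0, 1.0, 1.7) + rng.normal(0, 1.0, 40)
        fit = fit_lifetime_ls(y, irf)

        def rss(tau):
            d = decay_basis(irf, tau)
            from mesomux.flim import _ls_solve_ab

            return _ls_solve_ab(y, d)[2]

        grid_best = min(rss(t) for t in np.geomspace(0.3125, 12.5, 400))
        assert rss(fit.tau) <= grid_best + 1e-9


class TestPoissonFit:
    def test_noiseless_fixed_point(self, irf):
        y = convolve_model(irf, 60.0, 1.0, 2.2)
        fit = fit_lifetime_poisson(y, irf)
        assert fit.tau == pytest.approx(2.2, abs=0.02)
        assert fit.neg_log_lik is not None

    def test_high_count_agreement_with_ls(self, irf):
        rng = np.random.default_rng(3)
        diffs = []
        for tau in np.linspace(1.2, 3.5, 20):
            y = rng.poisson(convolve_model(irf, 2000.0, 5.0, tau)).astype(float)
            ls = fit_lifetime_ls(y, irf)
            po = fit_lifetime_poisson(y, irf, init=ls)
            diffs.append(abs(po.tau - ls.tau) / ls.tau)
        assert np.median(diffs) < 0.01


class TestPhasor:
    def test_self_reference_is_origin(self, irf):
        p = phasor_lifetime(irf.u, irf)
        assert (p.g, p.s) == pytest.approx((1.0, 0.0), abs=1e-12)
        assert p.tau_phasor_ns == pytest.approx(0.0, abs=1e-9)

    def test_matches_discrete_sum_oracle(self, irf):
        y = convolve_model(irf, 50.0, 1.0, 2.0)
        v = (y - y.min()) / (y.max() - y.min())
        g = sum(v[k] * np.cos(2 * np.pi * k / 40) for k in range(40)) / v.sum()
        s = sum(v[k] * np.sin(2 * np.pi * k / 40) for k in range(40)) / v.sum()
        p = phasor_lifetime(y, irf)
        assert (p.g_raw, p.s_raw) == pytest.approx((g, s), rel=1e-12)

    def test_analytic_limit_dense_monoexponential(self):
        """Dense sampling of a pure decay approaches the universal circle."""
        tau = 1.0
        n = 4000
        t = np.arange(n) * (12.5 / n)
        g, s = phasor_coordinates(np.exp(-t / tau))
        wt = OMEGA * tau * 1e-9
        assert g == pytest.approx(1 / (1 + wt**2), abs=2e-3)
        assert s == pytest.approx(wt / (1 + wt**2), abs=2e-3)

    def test_constant_trace_flagged(self, irf):
        p = phasor_lifetime(np.full(40, 2.0), irf)
        assert not p.valid
        assert np.isnan(p.tau_phasor_ns)

    def test_rank_agreement_with_ls_fit(self, irf):
        taus = np.linspace(0.8, 4.0, 25)
        pt, lt = [], []
        for tau in taus:
            y = convolve_model(irf, 100.0, 1.0, tau)
            pt.append(phasor_lifetime(y, irf).tau_phasor_ns)
            lt.append(fit_lifetime_ls(y, irf).tau)
        assert spearmanr(pt, lt).statistic >= 0.99


class TestFourGate:
    def test_gene_ordering_validated(self):
        with pytest.raises(ValueError):
            GateGene((0, 5, 5, 10, 15, 20, 25, 30))  # b2 < b3 violated
        with pytest.raises(ValueError):
            GateGene((0, 1, 2, 3, 4, 5, 6, 41))

    def test_window_means_inclusive_ranges(self):
        tr = np.arange(40.0)
        got = window_means(tr, ALL_BIN_GENE)
        assert got == pytest.approx([4.5, 14.5, 24.5, 34.5])

    def test_gate_times_from_bin_centers(self):
        assert ALL_BIN_GENE.gate_times_ns == pytest.approx(
            [4.5 * DT_NS, 14.5 * DT_NS, 24.5 * DT_NS, 34.5 * DT_NS]
        )

    def test_all_bin_gene_matches_full_fit(self, irf, irf_shifted):
        """Four windows tiling all 40 bins carry the full fit's information."""
        for tau in (1.2, 2.0, 3.5):
            y = convolve_model(irf, 100.0, 1.0, tau)
            full = fit_lifetime_ls(y, irf).tau
            fg = four_gate_lifetime(preprocess_four_gate(y, 19), ALL_BIN_GENE,
                                    irf_shifted)
            assert fg.tau == pytest.approx(full, rel=0.05)

    def test_constant_trace_hits_bound(self, irf_shifted):
        fg = four_gate_lifetime(np.zeros(40), ALL_BIN_GENE, irf_shifted)
        assert fg.at_bound

    def test_offset_invariance(self, irf, irf_shifted):
        y1 = convolve_model(irf, 100.0, 0.0, 2.0)
        y2 = convolve_model(irf, 100.0, 8.0, 2.0)
        f1 = four_gate_lifetime(preprocess_four_gate(y1, 19), ALL_BIN_GENE,
                                irf_shifted)
        f2 = four_gate_lifetime(preprocess_four_gate(y2, 19), ALL_BIN_GENE,
                                irf_shifted)
        assert f1.tau == pytest.approx(f2.tau, rel=1e-6)


@pytest.fixture(scope="module")
def two_lifetime_stack(irf):
    rng = np.random.default_rng(5)
    tau_map = rng.choice([1.5, 3.0], size=(24, 24))
    bright = rng.uniform(0.5, 2.0, size=(24, 24))
    stack = simulate_decay_stack(tau_map, irf.u, 100.0, 20, "poisson", seed=7,
                                 brightness_map=bright)
    return stack, tau_map


class TestGeneticAlgorithm:
    def test_elitism_makes_fitness_monotone(self, two_lifetime_stack, irf):
        stack, _ = two_lifetime_stack
        config = GAConfig(generations=12, seed=3)
        best, hist = ga_optimize_gates(stack, irf, config)
        assert np.all(np.diff(hist) >= -1e-12)
        assert hist[-1] >= hist[0]

    def test_two_lifetime_phantom_reaches_high_fitness(self, two_lifetime_stack,
                                                       irf):
        stack, _ = two_lifetime_stack
        config = GAConfig(generations=25, seed=11)
        best, hist = ga_optimize_gates(stack, irf, config)
        assert hist[-1] >= 0.9
        GateGene(best.bins)  # still a valid gene

    def test_deterministic_under_seed(self, two_lifetime_stack, irf):
        stack, _ = two_lifetime_stack
        config = GAConfig(generations=5, seed=21)
        a = ga_optimize_gates(stack, irf, config)
        b = ga_optimize_gates(stack, irf, config)
        assert a[0].bins == b[0].bins
        assert np.array_equal(a[1], b[1])

    def test_config_consistency_enforced(self):
        with pytest.raises(ValueError):
            GAConfig(population=100, elites=30, offspring=80)

    def test_too_few_bright_pixels_rejected(self, irf):
        stack = simulate_decay_stack(np.full((5, 5), 2.0), irf.u, 50.0, 10,
                                     "poisson", seed=0)
        with pytest.raises(ValueError, match="pixels"):
            ga_optimize_gates(stack, irf, GAConfig(generations=2, seed=0))


class TestNoiseStudy:
    def test_structure_and_ground_truth_zero(self, irf):
        rng = np.random.default_rng(8)
        tau_map = rng.choice([1.5, 3.0], size=(8, 8))
        res = lifetime_noise_study(tau_map, irf, [25, 200], seed=8,
                                   photons_per_pixel=50.0,
                                   models=("gaussian",))
        assert res["mae_all"]["gaussian"][-1] == 0.0
        assert res["mae_all"]["gaussian"][0] >= 0.0
        assert len(res["errors"]["gaussian"][25]) == 64

    def test_missing_reference_n_rejected(self, irf):
        with pytest.raises(ValueError, match="200"):
            lifetime_noise_study(np.full((4, 4), 2.0), irf, [10, 50])
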