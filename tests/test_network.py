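"""LIF network: connectivity, drives, integration, kernel LFP."""

import numpy as np
import pytest
from dataclasses import replace

from neuroei import (
    LFPKernel,
    NetworkConfig,
    NeuronParams,
    OUParams,
    PoissonParams,
    SpikeTrains,
    SynapseParams,
    build_connectivity,
    default_kernels,
    ou_input,
    simulate,
    spikes_to_lfp,
)

# small, fast network used across tests
SMALL = NetworkConfig(n_exc=200, n_inh=50, duration=1.0, seed=3)


class TestConnectivity:
    def test_density_within_binomial_bounds(self):
        cfg = NetworkConfig(n_exc=400, n_inh=100, seed=0)
        adj = build_connectivity(cfg)
        n = cfg.n_total
        pairs = n * (n - 1)
        density = adj.sum() / pairs
        sd = np.sqrt(0.2 * 0.8 / pairs)
        assert abs(density - 0.2) < 3 * sd

    def test_no_autapses(self):
        adj = build_connectivity(SMALL)
        assert not np.any(np.diag(adj))

    def test_seeded_reproducibility(self):
        a = build_connectivity(SMALL)
        b = build_connectivity(SMALL)
        np.testing.assert_array_equal(a, b)


class TestOUInput:
    def test_zero_sigma_is_constant(self):
        x = ou_input(mean=5.0, sigma=0.0, tau=10.0, duration=0.1, dt=0.1, rng=0)
        assert np.all(x == 5.0)

    def test_stationary_mean_within_standard_error(self):
        mean, sigma, tau = 2.0, 1.5, 10.0
        x = ou_input(mean, sigma, tau, duration=20.0, dt=0.1, rng=1)
        # effective number of independent samples ~ T / (2 tau)
        se = sigma / np.sqrt(20_000.0 / (2 * tau))
        assert abs(x.mean() - mean) < 3 * se

    def test_autocorrelation_decays_at_rate_tau(self):
        tau, dt = 10.0, 0.5
        x = ou_input(0.0, 1.0, tau, duration=100.0, dt=dt, rng=2)
        x = x - x.mean()
        k = int(round(tau / dt))
        acf_k = np.dot(x[:-k], x[k:]) / np.dot(x, x)
        assert acf_k == pytest.approx(np.exp(-1.0), abs=0.05)

    def test_dt_not_smaller_than_tau_rejected(self):
        with pytest.raises(ValueError):
            ou_input(0.0, 1.0, tau=1.0, duration=1.0, dt=1.0)


class TestSimulate:
    def test_zero_drive_stays_at_rest(self):
        cfg = replace(
            SMALL,
            thalamic_ou=OUParams(mean=0.0, sigma=0.0),
            cortical_poisson=PoissonParams(rate_hz=0.0, rate_hz_inh=0.0),
        )
        result = simulate(cfg)
        assert result.spikes.times.size == 0
        assert np.all(result.g_exc_mean == 0.0)

    def test_single_neuron_matches_analytic_lif_rate(self):
        # isolated LIF with constant current: closed-form interspike interval
        neuron = NeuronParams(cm=200.0, gl=10.0, t_ref=2.0)
        current = 400.0  # pA, suprathreshold (rheobase = 150 pA)
        cfg = NetworkConfig(
            n_exc=1,
            n_inh=0,
            exc_neuron=neuron,
            thalamic_ou=OUParams(mean=0.0, sigma=0.0),
            cortical_poisson=PoissonParams(rate_hz=0.0, rate_hz_inh=0.0),
            constant_current_pa=current,
            dt=0.01,
            duration=2.0,
            seed=0,
            scale_g_with_size=False,
        )
        result = simulate(cfg)
        v_inf = neuron.el + current / neuron.gl
        t_isi = neuron.t_ref + neuron.tau_m * np.log(
            (v_inf - neuron.v_reset) / (v_inf - neuron.v_th)
        )
        expected = 1000.0 / t_isi  # Hz
        assert result.spikes.population_rate("exc") == pytest.approx(expected, rel=0.02)

    def test_active_network_statistics(self):
        result = simulate(SMALL)
        rate_e = result.spikes.population_rate("exc")
        rate_i = result.spikes.population_rate("inh")
        assert 0.5 < rate_e < 100.0
        assert 0.5 < rate_i < 200.0
        # conductance traces are non-negative throughout
        assert result.g_exc_mean.min() >= 0.0
        assert result.g_inh_mean.min() >= 0.0

    def test_refractory_period_respected(self):
        result = simulate(SMALL)
        spikes = result.spikes
        t_ref_s = SMALL.exc_neuron.t_ref / 1000.0
        for nid in np.unique(spikes.neurons[spikes.neurons < SMALL.n_exc])[:20]:
            isi = np.diff(np.sort(spikes.times[spikes.neurons == nid]))
            if isi.size:
                assert isi.min() >= t_ref_s - 1e-9

    def test_halving_dt_changes_mean_rates_below_5_percent(self):
        cfg = NetworkConfig(n_exc=400, n_inh=100, duration=2.0)
        coarse, fine = [], []
        for seed in range(3):
            r1 = simulate(replace(cfg, seed=seed, dt=0.1))
            r2 = simulate(replace(cfg, seed=seed, dt=0.05))
            coarse.append(
                r1.spikes.population_rate("exc") + r1.spikes.population_rate("inh")
            )
            fine.append(
                r2.spikes.population_rate("exc") + r2.spikes.population_rate("inh")
            )
        assert np.mean(coarse) == pytest.approx(np.mean(fine), rel=0.05)


class TestKernelLFP:
    def test_single_spike_reproduces_kernel(self):
        spikes = SpikeTrains(
            times=np.array([0.1]),
            neurons=np.array([0]),
            n_exc=1,
            n_inh=0,
            duration=0.5,
        )
        kernel = LFPKernel(amplitude=-2.0, latency=1.0, rise=0.5, decay=5.0)
        lfp = spikes_to_lfp(spikes, {"exc": kernel}, fs_out=10_000.0, dt_conv=0.1)
        assert lfp.samples.min() == pytest.approx(-2.0, rel=0.01)
        t_min = lfp.samples.argmin() / lfp.fs
        t_peak_ms = 1.0 + np.log(5.0 / 0.5) * 0.5 * 5.0 / 4.5
        assert t_min == pytest.approx(0.1 + t_peak_ms / 1000.0, abs=5e-4)

    def test_superposition(self):
        rng = np.random.default_rng(0)
        ta = np.sort(rng.uniform(0, 1, 40))
        tb = np.sort(rng.uniform(0, 1, 25))
        mk = lambda t: SpikeTrains(  # noqa: E731
            times=t,
            neurons=np.zeros(t.size, dtype=int),
            n_exc=1,
            n_inh=0,
            duration=1.0,
        )
        kernels = {"exc": default_kernels()["exc"]}
        lfp_a = spikes_to_lfp(mk(ta), kernels)
        lfp_b = spikes_to_lfp(mk(tb), kernels)
        lfp_ab = spikes_to_lfp(mk(np.sort(np.concatenate([ta, tb]))), kernels)
        np.testing.assert_allclose(
            lfp_ab.samples, lfp_a.samples + lfp_b.samples, atol=1e-10
        )

    def test_empty_kernel_set_rejected(self):
        spikes = SpikeTrains(
            times=np.array([0.1]),
            neurons=np.array([0]),
            n_exc=1,
            n_inh=0,
            duration=0.5,
        )
        with pytest.raises(ValueError):
            spikes_to_lfp(spikes, {})
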