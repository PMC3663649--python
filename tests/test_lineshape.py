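"""Exchange-matrix line shapes vs the closed-form McConnell oracle, and fitting."""

import math

import numpy as np
import pytest
from scipy.signal import find_peaks

from nucbind.equilibria import EquilibriumParams, solve_two_site
from nucbind.lineshape import (
    AcquisitionParams,
    ExchangeState,
    assemble_evolution_matrix,
    fit_exchange,
    peak_positions,
    pseudo_first_order_rates,
    simulate_fid,
    spectrum_from_fid,
    titration_lineshapes,
)
from nucbind.simulate import GeneratorSpec, make_lineshape_dataset

from _oracles import mcconnell_spectrum

# long acquisition so the FID decays fully: discretisation error << 0.1%
ACQ = AcquisitionParams(sweep_width_ppm=6.0, n_points=4096)
DW_PPM = 0.35  # ~79 Hz on the 13C axis at a 900 MHz 1H field
DW_RAD = 2 * math.pi * DW_PPM * ACQ.observe_frequency_mhz


def simulate_pair(k_fb, k_bf, r2=(12.0, 12.0), offsets=(-DW_PPM / 2, DW_PPM / 2), pops=None):
    if pops is None:
        ktot = k_fb + k_bf
        pops = (k_bf / ktot, k_fb / ktot) if ktot > 0 else (0.5, 0.5)
    states = (ExchangeState(offsets[0], r2[0]), ExchangeState(offsets[1], r2[1]))
    ev = assemble_evolution_matrix(states, (k_fb, k_bf), ACQ)
    fid = simulate_fid(ev, pops, ACQ.dwell, ACQ.n_points)
    return spectrum_from_fid(fid, ACQ), pops


class TestEvolutionMatrix:
    def test_no_exchange_is_block_diagonal(self):
        states = (ExchangeState(-0.1, 5.0), ExchangeState(0.1, 20.0))
        ev = assemble_evolution_matrix(states, (0.0, 0.0), ACQ)
        assert ev[0, 1] == 0 and ev[1, 0] == 0

    @pytest.mark.parametrize("rates", [(0.0, 0.0), (100.0, 50.0), (5000.0, 5000.0)])
    def test_kinetic_part_conserves_population(self, rates):
        states = (ExchangeState(-0.1, 5.0), ExchangeState(0.1, 20.0))
        ev = assemble_evolution_matrix(states, rates, ACQ)
        kinetic = ev.real + np.diag([s.r2 for s in states])
        assert np.allclose(kinetic.sum(axis=0), 0.0, atol=1e-9)

    def test_symmetric_exchange_eigenvalues_match_closed_form(self):
        # equal populations, equal R2: lambda = i*mean(W) - R2 - k +/- sqrt(k^2 - dW^2/4)
        r2, k = 10.0, 300.0
        states = (ExchangeState(-DW_PPM / 2, r2), ExchangeState(DW_PPM / 2, r2))
        ev = assemble_evolution_matrix(states, (k, k), ACQ)
        eig = np.sort_complex(np.linalg.eigvals(ev))
        root = np.sqrt(complex(k**2 - DW_RAD**2 / 4.0))
        expected = np.sort_complex(np.array([-r2 - k + root, -r2 - k - root]))
        assert np.allclose(eig, expected, rtol=1e-10)


class TestFid:
    def test_single_state_pure_decay(self):
        states = (ExchangeState(0.0, 10.0), ExchangeState(1.0, 10.0))
        ev = assemble_evolution_matrix(states, (0.0, 0.0), ACQ)
        fid = simulate_fid(ev, (1.0, 0.0), ACQ.dwell, 512)
        t = ACQ.dwell * np.arange(512)
        assert np.allclose(fid, np.exp(-10.0 * t), atol=1e-12)

    @pytest.mark.parametrize("k", [0.0, 200.0, 5000.0])
    def test_contraction(self, k):
        states = (ExchangeState(-0.1, 8.0), ExchangeState(0.15, 40.0))
        ev = assemble_evolution_matrix(states, (k, k), ACQ)
        fid = simulate_fid(ev, (0.5, 0.5), ACQ.dwell, 1024)
        assert np.all(np.abs(fid) <= np.abs(fid[0]) + 1e-12)

    def test_fast_limit_is_population_averaged_decay(self):
        # k >> dW: single line at the population-weighted offset and R2
        k = 1000.0 * DW_RAD
        pops = (0.7, 0.3)
        states = (ExchangeState(-DW_PPM / 2, 8.0), ExchangeState(DW_PPM / 2, 40.0))
        ev = assemble_evolution_matrix(states, (k * pops[1], k * pops[0]), ACQ)
        fid = simulate_fid(ev, pops, ACQ.dwell, 1024)
        w_avg = 2 * math.pi * ACQ.observe_frequency_mhz * (
            pops[0] * -DW_PPM / 2 + pops[1] * DW_PPM / 2
        )
        r2_avg = pops[0] * 8.0 + pops[1] * 40.0
        t = ACQ.dwell * np.arange(1024)
        ref = np.exp((1j * w_avg - r2_avg) * t)
        assert np.max(np.abs(fid - ref)) < 0.01

    def test_divergent_evolution_raises(self):
        ev = np.array([[1.0 + 0j, 0], [0, -5.0]])
        with pytest.raises(ValueError, match="divergent"):
            simulate_fid(ev, (0.5, 0.5), 1e-3, 256)


class TestSpectrum:
    def test_lorentzian_width_and_position(self):
        r2 = 25.0
        states = (ExchangeState(0.12, r2), ExchangeState(1.0, r2))
        ev = assemble_evolution_matrix(states, (0.0, 0.0), ACQ)
        fid = simulate_fid(ev, (1.0, 0.0), ACQ.dwell, ACQ.n_points)
        tr = spectrum_from_fid(fid, ACQ)
        dres_ppm = tr.ppm[1] - tr.ppm[0]
        (_, pos), = peak_positions([tr])
        assert abs(pos - 0.12) <= dres_ppm
        half = tr.intensity.max() / 2
        above = np.nonzero(tr.intensity > half)[0]
        fwhm_hz = (tr.ppm[above[-1] + 1] - tr.ppm[above[0]]) * ACQ.observe_frequency_mhz
        assert fwhm_hz == pytest.approx(r2 / math.pi, abs=2 * dres_ppm * ACQ.observe_frequency_mhz)

    def test_integral_equals_initial_magnetization(self):
        tr, _ = simulate_pair(300.0, 300.0)
        dnu = (tr.ppm[1] - tr.ppm[0]) * ACQ.observe_frequency_mhz
        assert tr.intensity.sum() * dnu == pytest.approx(1.0, rel=5e-3)

    def test_integral_conserved_across_exchange_rates(self):
        integrals = []
        for k in [0.0, 10.0, 300.0, 3000.0, 3e4]:
            tr, _ = simulate_pair(k, k)
            dnu = (tr.ppm[1] - tr.ppm[0]) * ACQ.observe_frequency_mhz
            integrals.append(tr.intensity.sum() * dnu)
        assert np.ptp(integrals) / np.mean(integrals) < 5e-3

    def test_slow_exchange_peak_integrals_proportional_to_populations(self):
        pops = (0.7, 0.3)
        k = 0.002 * DW_RAD
        tr, _ = simulate_pair(k * pops[1], k * pops[0], pops=pops)
        mid = np.searchsorted(tr.ppm, 0.0)
        dnu = (tr.ppm[1] - tr.ppm[0]) * ACQ.observe_frequency_mhz
        left = tr.intensity[:mid].sum() * dnu
        right = tr.intensity[mid:].sum() * dnu
        assert left == pytest.approx(pops[0], abs=0.02)
        assert right == pytest.approx(pops[1], abs=0.02)

    @pytest.mark.parametrize(
        "k_scale, pops",
        [
            (0.01, (0.5, 0.5)),  # slow
            (0.2, (0.65, 0.35)),
            (1.0, (0.5, 0.5)),  # intermediate
            (3.0, (0.3, 0.7)),
            (100.0, (0.5, 0.5)),  # fast
        ],
    )
    def test_matches_closed_form_mcconnell_oracle(self, k_scale, pops):
        k = k_scale * DW_RAD
        k_fb, k_bf = k * pops[1], k * pops[0]
        r2 = (12.0, 30.0)
        offsets = (-DW_PPM / 2, DW_PPM / 2)
        tr, _ = simulate_pair(k_fb, k_bf, r2=r2, offsets=offsets, pops=pops)
        oracle = mcconnell_spectrum(tr.ppm, ACQ, offsets, r2, pops, k_fb, k_bf)
        rms = np.sqrt(np.mean((tr.intensity - oracle) ** 2))
        assert rms / oracle.max() < 1e-3

    def test_coalescence_scan(self):
        # two resolved maxima in slow exchange, one in fast exchange
        def n_maxima(k):
            tr, _ = simulate_pair(k / 2, k / 2)
            peaks, _ = find_peaks(tr.intensity, prominence=0.02 * tr.intensity.max())
            return len(peaks)

        assert n_maxima(0.01 * DW_RAD) == 2
        assert n_maxima(10.0 * DW_RAD) == 1


class TestPseudoFirstOrder:
    def test_limits(self):
        assert pseudo_first_order_rates(1e-6, 500.0, 0.0) == (0.0, 500.0)
        k_fb, k_bf = pseudo_first_order_rates(1e-6, 500.0, 1e-6)
        assert k_fb == pytest.approx(k_bf)  # detailed balance: p_bound = 0.5

    def test_population_consistent_with_two_site_mass_balance(self):
        mix = solve_two_site(116e-6, 232e-6, 1.5e-6)
        k_fb, k_bf = pseudo_first_order_rates(1.5e-6, 500.0, mix.free_ligand)
        p_bound = k_fb / (k_fb + k_bf)
        assert p_bound == pytest.approx(mix.site_occupancy, rel=1e-12)
        assert p_bound == pytest.approx(0.92, abs=5e-3)


class TestTitration:
    def make(self, kd=1.5e-6, koff=500.0, ratios=(0.0, 0.5, 1.0, 1.8, 2.7), acq=None):
        acq = acq or AcquisitionParams()
        states = (ExchangeState(0.0, 8.0), ExchangeState(DW_PPM, 40.0))
        return titration_lineshapes(
            EquilibriumParams(kd, 2), koff, states, acq, 116e-6, ratios
        )

    def test_free_reference_at_free_offset(self):
        traces = self.make()
        (_, pos) = peak_positions(traces)[0]
        assert abs(pos) <= 2 * (traces[0].ppm[1] - traces[0].ppm[0])

    def test_saturation_reaches_bound_offset(self):
        traces = self.make(ratios=(0.0, 100.0))
        (_, pos) = peak_positions(traces)[1]
        assert pos == pytest.approx(DW_PPM, rel=0.02)

    def test_peak_position_tracks_occupancy_in_fast_exchange(self):
        ratios = (0.0, 0.5, 1.0, 1.8, 2.7)
        traces = self.make(koff=5e4, ratios=ratios)
        positions = np.array([p for _, p in peak_positions(traces)])
        theta = np.array(
            [solve_two_site(116e-6, r * 116e-6, 1.5e-6).site_occupancy for r in ratios]
        )
        assert np.all(np.diff(positions) > 0)  # monotone in ratio
        assert np.allclose(positions, theta * DW_PPM, atol=0.02 * DW_PPM)
        # near-saturated final point sits within 2% of the bound limit
        assert positions[-1] == pytest.approx(DW_PPM, rel=0.02)

    def test_requires_free_reference(self):
        with pytest.raises(ValueError, match="ratio 0|include 0"):
            self.make(ratios=(0.5, 1.0, 2.0))

    def test_flat_trace_has_no_peak(self):
        from nucbind.lineshape import SpectrumTrace

        with pytest.raises(ValueError, match="flat"):
            peak_positions([SpectrumTrace(np.linspace(-1, 1, 64), np.ones(64))])


class TestFitExchange:
    def test_noiseless_self_consistency(self):
        spec = GeneratorSpec.preset("lineshape_nucleosome", seed=0, noise=0.0)
        traces, man = make_lineshape_dataset(spec)
        fit = fit_exchange(
            traces, man["ratios"], man["receptor_total_M"], spec.acquisition, compute_ci=False
        )
        assert fit.kd == pytest.approx(spec.kd, rel=1e-4)
        assert fit.koff == pytest.approx(spec.koff, rel=1e-4)
        assert fit.delta_omega == pytest.approx(spec.delta_omega_ppm, rel=1e-4)

    def test_noisy_fit_with_intervals(self):
        spec = GeneratorSpec.preset("lineshape_nucleosome", seed=11)
        traces, man = make_lineshape_dataset(spec)
        fit = fit_exchange(traces, man["ratios"], man["receptor_total_M"], spec.acquisition)
        lo, hi = fit.interval95_kd
        assert lo <= fit.kd <= hi
        lo, hi = fit.interval95_koff
        assert lo <= fit.koff <= hi
        assert "K_D" in fit.summary()

    def test_one_sided_interval_when_binding_is_stoichiometric(self):
        # kd far below receptor: every trace is saturated the same way, the
        # chi2 surface is flat toward smaller kd and only an upper bound exists
        spec = GeneratorSpec.preset(
            "lineshape_nucleosome", seed=5, kd=1e-8, noise=0.02
        )
        traces, man = make_lineshape_dataset(spec)
        fit = fit_exchange(traces, man["ratios"], man["receptor_total_M"], spec.acquisition)
        assert fit.interval95_kd[0] == 0.0
        assert any(k.startswith("kd_lower") or k == "kd" for k in fit.flags)

    def test_requires_at_least_four_traces(self):
        spec = GeneratorSpec.preset("lineshape_nucleosome", seed=0, noise=0.0,
                                    schedule=(0.0, 1.0, 2.7))
        traces, man = make_lineshape_dataset(spec)
        with pytest.raises(ValueError, match=">= 4 traces"):
            fit_exchange(traces, man["ratios"], man["receptor_total_M"], spec.acquisition)


def test_acquisition_validation():
    with pytest.raises(ValueError, match="power of two"):
        AcquisitionParams(n_points=1000)
    with pytest.raises(ValueError, match="nucleus"):
        AcquisitionParams(nucleus="31P")
    acq = AcquisitionParams(sweep_width_ppm=0.5)
    with pytest.raises(ValueError, match="outside covered window"):
        acq.validate_states((ExchangeState(0.0, 8.0), ExchangeState(0.4, 40.0)))
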