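"""Generator contracts: determinism, physical limits, closed-form consistency."""

import math

import numpy as np
import pytest

from qbetkit.errors import DiscretizationError, InputError
from qbetkit.kinetics import detect_redox_peaks
from qbetkit.simulate import (
    Band,
    CVSimParams,
    GridSpec,
    MetabolicSimParams,
    SpectrumSimParams,
    simulate_metabolic_dataset,
    simulate_scan_rate_study,
    simulate_spectrum,
    simulate_voltammogram,
)
from qbetkit.spectra import peak_max
from qbetkit.tunneling import charging_rate_from_activity, linker_length_from_mw


class TestVoltammogramSimulator:
    def test_reversible_limit_peak_separation(self):
        """A fast couple (k0 = 1 cm/s) must show the Nernstian ~59 mV split."""
        vg = simulate_voltammogram(CVSimParams(k0_true=1.0, scan_rate=0.1))
        pair = detect_redox_peaks(vg)
        assert abs(pair.delta_Ep - 0.059) <= 0.003
        assert abs(pair.E_formal - 0.5) < 0.005

    def test_peak_separation_grows_with_scan_rate(self, coarse_cv_params):
        """Quasi-reversible kinetics: faster sweeps pull the peaks apart."""
        slow = detect_redox_peaks(
            simulate_voltammogram(coarse_cv_params(k0_true=3.75e-3, scan_rate=0.05))
        )
        fast = detect_redox_peaks(
            simulate_voltammogram(coarse_cv_params(k0_true=3.75e-3, scan_rate=0.5))
        )
        assert fast.delta_Ep > slow.delta_Ep

    def test_single_peak_pair(self, coarse_cv_params):
        """Quasi-reversible parameters give exactly one peak per branch."""
        from scipy.signal import find_peaks

        vg = simulate_voltammogram(coarse_cv_params(k0_true=5e-3, scan_rate=0.5))
        rev = vg.reversal_index
        i_p = np.max(np.abs(vg.current))
        cath, _ = find_peaks(-vg.current[: rev + 1], prominence=0.05 * i_p)
        ano, _ = find_peaks(vg.current[rev:], prominence=0.05 * i_p)
        assert len(cath) == 1 and len(ano) == 1

    def test_seeded_noise_reproducible(self, coarse_cv_params):
        a = simulate_voltammogram(coarse_cv_params(noise_sd_current=1e-6, seed=3))
        b = simulate_voltammogram(coarse_cv_params(noise_sd_current=1e-6, seed=3))
        np.testing.assert_array_equal(a.current, b.current)
        c = simulate_voltammogram(coarse_cv_params(noise_sd_current=1e-6, seed=4))
        assert not np.array_equal(a.current, c.current)

    def test_grid_convergence_under_refinement(self):
        """Halving both grid steps moves each peak potential by < 1 mV."""
        base = CVSimParams(k0_true=3.75e-3, scan_rate=0.5)
        fine = CVSimParams(k0_true=3.75e-3, scan_rate=0.5, grid=base.grid.refined(2))
        p0 = detect_redox_peaks(simulate_voltammogram(base))
        p1 = detect_redox_peaks(simulate_voltammogram(fine))
        assert abs(p0.E_pa - p1.E_pa) < 1e-3
        assert abs(p0.E_pc - p1.E_pc) < 1e-3

    def test_degenerate_sweep_rejected(self):
        with pytest.raises(InputError, match="E_start"):
            CVSimParams(E_start=0.5, E_reverse=0.5)

    def test_unstable_grid_rejected(self):
        params = CVSimParams(grid=GridSpec(n_time=6000, stability=0.6))
        with pytest.raises(DiscretizationError, match="dt/dx\\^2"):
            simulate_voltammogram(params)

    def test_invalid_kinetic_parameters_rejected(self):
        with pytest.raises(InputError):
            CVSimParams(k0_true=-1.0)
        with pytest.raises(InputError):
            CVSimParams(alpha_ct_true=1.2)


class TestScanRateStudy:
    def test_rates_recorded_ascending(self, coarse_cv_params):
        study = simulate_scan_rate_study(coarse_cv_params(), [2.0, 0.05, 0.5, 0.1, 1.0])
        assert study.scan_rates == sorted(study.scan_rates)
        assert len(study.voltammograms) == 5
        assert study.sufficient_for_regression

    def test_single_rate_flagged_insufficient(self, coarse_cv_params):
        study = simulate_scan_rate_study(coarse_cv_params(), [0.1])
        assert not study.sufficient_for_regression

    def test_empty_rates_rejected(self, coarse_cv_params):
        with pytest.raises(InputError, match="non-empty"):
            simulate_scan_rate_study(coarse_cv_params(), [])

    def test_duplicate_rates_rejected(self, coarse_cv_params):
        with pytest.raises(InputError, match="distinct"):
            simulate_scan_rate_study(coarse_cv_params(), [0.1, 0.1, 0.5])


class TestMetabolicGenerator:
    def test_zero_decay_constant_removes_length_dependence(self):
        """With alpha_loc = 0 every cell sees M = exp(-beta t) exactly."""
        ds = simulate_metabolic_dataset(
            MetabolicSimParams(
                beta_true=0.1, alpha_loc_true=0.0, times=(12.0,),
                noise_sd_activity=0.0, replicates=2, seed=1,
            )
        )
        expected = math.exp(-1.2)
        assert np.allclose(ds.table["activity_fraction"], expected, rtol=1e-12)

    def test_activity_is_unity_at_time_zero(self):
        ds = simulate_metabolic_dataset(
            MetabolicSimParams(times=(0.0,), noise_sd_activity=0.0, replicates=3, seed=1)
        )
        assert (ds.table["activity_fraction"] == 1.0).all()

    def test_noisy_cell_means_match_closed_form(self):
        """Per-condition mean activity stays within 3 s.e. of the survival model."""
        params = MetabolicSimParams(noise_sd_activity=0.05, replicates=9, seed=7)
        ds = simulate_metabolic_dataset(params)
        for (_, _, mass), grp in ds.table.groupby(["cell_line", "diameter_nm", "linker_kda"]):
            L = linker_length_from_mw(mass)
            clean = math.exp(-ds.true_rate(L) * 12.0)
            se = clean * 0.05 / math.sqrt(9)
            assert abs(grp["activity_fraction"].mean() - clean) < 3 * se

    def test_noiseless_rows_invert_to_true_rate(self):
        """Generator/extractor consistency: r_d(M, t) == beta exp(-alpha L)."""
        ds = simulate_metabolic_dataset(
            MetabolicSimParams(noise_sd_activity=0.0, replicates=1, seed=0)
        )
        for row in ds.table.itertuples():
            r = charging_rate_from_activity(row.activity_fraction, row.time_h)
            truth = ds.true_rate(row.linker_length_nm)
            assert abs(r - truth) <= 1e-12 * max(truth, 1e-30)

    def test_noise_clipped_into_range(self):
        ds = simulate_metabolic_dataset(
            MetabolicSimParams(noise_sd_activity=2.0, replicates=50, seed=5, times=(1.0,))
        )
        m = ds.table["activity_fraction"]
        assert (m > 0).all() and (m <= 1.5).all()

    def test_seeded_determinism(self):
        a = simulate_metabolic_dataset(MetabolicSimParams(seed=11))
        b = simulate_metabolic_dataset(MetabolicSimParams(seed=11))
        assert a.table.equals(b.table)


class TestSpectrumGenerator:
    def test_single_band_peaks_at_centre(self):
        s = simulate_spectrum(
            SpectrumSimParams(bands=(Band(612.0, 40.0, 1.0),), baseline=0.0, noise_sd=0.0)
        )
        assert abs(s.wavelength[np.argmax(s.intensity)] - 612.0) <= s.step

    def test_no_bands_gives_flat_baseline(self):
        s = simulate_spectrum(SpectrumSimParams(bands=(), baseline=0.2, noise_sd=0.0))
        assert np.allclose(s.intensity, 0.2)

    def test_two_bands_recovered_by_windowed_peak_finder(self):
        s = simulate_spectrum(
            SpectrumSimParams(
                bands=(Band(568.0, 20.0, 0.8), Band(711.0, 25.0, 1.0)),
                baseline=0.05, noise_sd=0.0,
            )
        )
        assert abs(peak_max(s, (520.0, 640.0)) - 568.0) <= s.step
        assert abs(peak_max(s, (650.0, 790.0)) - 711.0) <= s.step

    def test_band_outside_range_warns_but_renders(self):
        with pytest.warns(UserWarning, match="outside"):
            s = simulate_spectrum(
                SpectrumSimParams(
                    bands=(Band(900.0, 80.0, 1.0),), baseline=0.0, noise_sd=0.0
                )
            )
        assert s.intensity[-1] > s.intensity[0]  # the tail enters from the red edge

    def test_seeded_determinism(self):
        a = simulate_spectrum(SpectrumSimParams(noise_sd=0.05, seed=9))
        b = simulate_spectrum(SpectrumSimParams(noise_sd=0.05, seed=9))
        np.testing.assert_array_equal(a.intensity, b.intensity)
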