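"""Decay/recovery fitting against closed forms and grid-search oracles."""

import numpy as np
import pytest
from conftest import decay_grid_search

from barriertrace import simkit
from barriertrace.kinetics import (
    fit_one_phase_decay,
    fit_recovery,
    halftime_dataset,
    interpolated_half_loss_time,
    t50_of,
)
from barriertrace.quant import normalize_to_controls, subtract_background
from barriertrace.simkit import CompartmentModel, NoiseModel, simulate_trace_bundle
from barriertrace.stats import group_compare


class TestOnePhaseDecay:
    def test_pure_exponential_recovered_exactly(self):
        t = np.arange(0.0, 60.0, 1.0)
        y = 100.0 * np.exp(-0.0693 * t)
        fit = fit_one_phase_decay(t, y)
        assert fit.rate == pytest.approx(0.0693, rel=1e-6)
        assert fit.plateau == pytest.approx(0.0, abs=1e-4)
        assert t50_of(fit) == pytest.approx(np.log(2) / 0.0693, rel=1e-6)

    def test_decay_with_plateau_recovered_exactly(self):
        t = np.arange(0.0, 80.0, 1.0)
        y = 20.0 + 80.0 * np.exp(-0.1 * t)
        fit = fit_one_phase_decay(t, y)
        assert fit.rate == pytest.approx(0.1, rel=1e-6)
        assert fit.plateau == pytest.approx(20.0, rel=1e-6)
        # solve 50 = 20 + 80 exp(-0.1 t)
        assert t50_of(fit) == pytest.approx(np.log(80.0 / 30.0) / 0.1, rel=1e-6)

    def test_high_plateau_leaves_t50_undefined(self):
        t = np.arange(0.0, 80.0, 1.0)
        y = 60.0 + 40.0 * np.exp(-0.1 * t)
        fit = fit_one_phase_decay(t, y)
        assert fit.t50 is None
        assert "t50_undefined" in fit.flags
        with pytest.raises(ValueError, match="undefined"):
            t50_of(fit)

    def test_fit_composes_with_raw_half_loss_crossing(self):
        t = np.arange(0.0, 120.0, 1.0)
        y = 10.0 + 90.0 * np.exp(-0.05 * t)
        fit = fit_one_phase_decay(t, y)
        assert t50_of(fit) == pytest.approx(interpolated_half_loss_time(t, y), rel=1e-3)

    def test_constant_trace_rejected(self):
        t = np.arange(20.0)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_one_phase_decay(t, np.full(20, 100.0))

    def test_nonfinite_trace_rejected(self):
        t = np.arange(20.0)
        y = 100.0 * np.exp(-0.1 * t)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_one_phase_decay(t, y)

    def test_matches_dense_grid_search_on_noisy_traces(self):
        rng = np.random.default_rng(77)
        t = np.arange(0.0, 100.0, 2.0)
        for _ in range(10):
            rate = 10 ** rng.uniform(-2.5, -0.7)
            plateau = rng.uniform(0.0, 40.0)
            y = plateau + (100.0 - plateau) * np.exp(-rate * t)
            y = y + rng.normal(0.0, 2.0, t.size)
            fit = fit_one_phase_decay(t, y)
            rate_g, plateau_g, rates, plateaus = decay_grid_search(t, y)

            def ssr(rate, plateau):
                return float(
                    np.sum((plateau + (100.0 - plateau) * np.exp(-rate * t) - y) ** 2)
                )

            # the continuous fit must be at least as good as the grid optimum
            ssr_grid = ssr(rate_g, plateau_g)
            assert ssr(fit.rate, fit.plateau) <= ssr_grid * (1.0 + 1e-9)
            # and must lie within one grid cell of the grid-search optimum set:
            # snapping the fit to the grid loses no more than one grid step of
            # SSR resolution around the optimum
            def neighborhood_ssr(rate, plateau):
                i_rate = int(np.argmin(np.abs(np.log(rates) - np.log(rate))))
                i_plat = int(np.argmin(np.abs(plateaus - plateau)))
                return [
                    ssr(
                        rates[np.clip(i, 0, rates.size - 1)],
                        plateaus[np.clip(j, 0, plateaus.size - 1)],
                    )
                    for i in (i_rate - 1, i_rate, i_rate + 1)
                    for j in (i_plat - 1, i_plat, i_plat + 1)
                ]

            # the grid cannot resolve SSR differences smaller than its own
            # one-step variation around the optimum
            resolution = max(neighborhood_ssr(rate_g, plateau_g)) - ssr_grid
            assert min(neighborhood_ssr(fit.rate, fit.plateau)) <= ssr_grid + resolution

    def test_shallow_trace_flagged_extrapolated(self):
        bundle = simulate_trace_bundle(
            CompartmentModel(exchange_rate=0.002),
            simkit.default_flip_protocol(),
            NoiseModel.none(),
        )
        nb = normalize_to_controls(subtract_background(bundle))
        fit = fit_one_phase_decay(nb, roi="bud")
        assert "extrapolated" in fit.flags
        assert t50_of(fit) > nb.times[-1]


class TestRecovery:
    def test_single_component_closed_form(self):
        t = np.arange(0.0, 60.0, 1.0)
        y = 40.0 + 40.0 * (1.0 - np.exp(-0.0866 * t))
        fit = fit_recovery(t, y, pre_bleach_level=100.0)
        assert fit.t_half == pytest.approx(np.log(2) / 0.0866, rel=1e-6)
        assert fit.mobile_fraction == pytest.approx(40.0 / 60.0, rel=1e-6)
        assert fit.plateau == pytest.approx(80.0, rel=1e-6)

    def test_two_component_amplitude_share(self):
        t = np.arange(0.0, 200.0, 1.0)
        y = 40.0 + 30.0 * (1.0 - np.exp(-0.2 * t)) + 10.0 * (1.0 - np.exp(-0.02 * t))
        fit = fit_recovery(t, y, pre_bleach_level=100.0, components=2)
        assert fit.fast_fraction == pytest.approx(0.75, abs=0.01)
        assert fit.rate == pytest.approx(0.2, rel=0.05)
        assert fit.slow_rate == pytest.approx(0.02, rel=0.05)
        # t_half crosses y0 + span/2 = 60
        target = 40.0 + 20.0
        y_at_thalf = (
            40.0
            + 30.0 * (1.0 - np.exp(-0.2 * fit.t_half))
            + 10.0 * (1.0 - np.exp(-0.02 * fit.t_half))
        )
        assert y_at_thalf == pytest.approx(target, abs=0.05)

    def test_two_component_matches_coarse_grid_oracle(self):
        """Brute-force search over (fast rate, slow rate) amplitude-solved pairs."""
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 150.0, 1.0)
        y = 35.0 + 28.0 * (1.0 - np.exp(-0.15 * t)) + 12.0 * (1.0 - np.exp(-0.015 * t))
        y = y + rng.normal(0.0, 0.5, t.size)
        fit = fit_recovery(t, y, pre_bleach_level=100.0, components=2)

        rates = np.logspace(-3, 0, 60)
        best = None
        for i, rf in enumerate(rates):
            for rs in rates[:i]:
                basis = np.column_stack(
                    [np.ones_like(t), 1.0 - np.exp(-rf * t), 1.0 - np.exp(-rs * t)]
                )
                coef, ssr, *_ = np.linalg.lstsq(basis, y, rcond=None)
                if coef[1] < 0 or coef[2] < 0:
                    continue
                resid = float(np.sum((basis @ coef - y) ** 2))
                if best is None or resid < best[0]:
                    best = (resid, coef[1] / (coef[1] + coef[2]))
        assert fit.fast_fraction == pytest.approx(best[1], abs=0.05)

    def test_flat_trace_flagged_no_recovery(self):
        t = np.arange(0.0, 30.0, 1.0)
        fit = fit_recovery(t, np.full(t.size, 40.0), pre_bleach_level=100.0)
        assert fit.mobile_fraction == 0.0
        assert fit.t_half is None
        assert "no_recovery" in fit.flags

    def test_close_rates_flagged_unidentifiable(self):
        t = np.arange(0.0, 100.0, 1.0)
        y = 40.0 + 40.0 * (1.0 - np.exp(-0.05 * t))
        fit = fit_recovery(t, y, pre_bleach_level=100.0, components=2)
        assert ("unidentifiable_components" in fit.flags) or fit.fast_fraction in (0.0, 1.0) \
            or fit.rate / fit.slow_rate >= 3.0

    @pytest.mark.parametrize("scale", [0.1, 3.0, 42.0])
    def test_thalf_and_mobile_fraction_scale_invariant(self, scale):
        t = np.arange(0.0, 60.0, 1.0)
        y = 40.0 + 35.0 * (1.0 - np.exp(-0.09 * t))
        base = fit_recovery(t, y, pre_bleach_level=100.0)
        scaled = fit_recovery(t, y * scale, pre_bleach_level=100.0 * scale)
        assert scaled.t_half == pytest.approx(base.t_half, rel=1e-6)
        assert scaled.mobile_fraction == pytest.approx(base.mobile_fraction, rel=1e-6)


def frap_percent_trace(model, seed):
    """Simulate a FRAP cell and return the post-bleach percent trace."""
    protocol = simkit.default_frap_protocol()
    noise = NoiseModel(seed=seed) if seed is not None else NoiseModel.none()
    bundle = simulate_trace_bundle(model, protocol, noise)
    nb = normalize_to_controls(subtract_background(bundle))
    n_pre = protocol.pulse_frames[0] + 1
    pre = nb.mother[:n_pre].mean()
    return nb.times[n_pre:], 100.0 * nb.mother[n_pre:] / pre


class TestHalftimeDataset:
    def test_single_noiseless_cell(self):
        model = CompartmentModel(intra_mixing_rate=simkit.KAR2_LIKE_INTRA_MIXING)
        t, y = frap_percent_trace(model, None)
        table, summary = halftime_dataset([("cell0", t, y)])
        assert len(table) == 1
        assert summary["t_half_mean_s"] == pytest.approx(8.5, rel=0.05)

    def test_noisy_population_recovers_mean(self):
        model = CompartmentModel(intra_mixing_rate=simkit.KAR2_LIKE_INTRA_MIXING)
        _, y_ref = frap_percent_trace(model, None)
        t_ref = frap_percent_trace(model, None)[0]
        ref = halftime_dataset([("ref", t_ref, y_ref)])[1]["t_half_mean_s"]
        traces = [
            ("cell%d" % i, *frap_percent_trace(model, seed=100 + i)) for i in range(30)
        ]
        table, summary = halftime_dataset(traces)
        assert summary["n_fit"] >= 28
        assert summary["t_half_mean_s"] == pytest.approx(ref, rel=0.05)
        assert summary["t_half_sd_s"] > 0

    def test_mobility_contrast_detected_by_t_test(self):
        """2.5-fold slower exchange gives a strongly significant t_half shift."""
        fast = CompartmentModel(intra_mixing_rate=simkit.KAR2_LIKE_INTRA_MIXING)
        slow = CompartmentModel(intra_mixing_rate=simkit.KAR2_LIKE_INTRA_MIXING / 2.5)
        t_fast = [("f%d" % i, *frap_percent_trace(fast, seed=200 + i)) for i in range(25)]
        t_slow = [("s%d" % i, *frap_percent_trace(slow, seed=300 + i)) for i in range(25)]
        tab_f = halftime_dataset(t_fast)[0]["t_half_s"].dropna()
        tab_s = halftime_dataset(t_slow)[0]["t_half_s"].dropna()
        _, p = group_compare(tab_f, tab_s)
        assert p < 0.001

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            halftime_dataset([])
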