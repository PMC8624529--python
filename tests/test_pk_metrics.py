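import numpy as np
import pytest

from acatpk.compound import PKParameters, metformin_profile
from acatpk.physiology import default_fasted_physiology
from acatpk.permeability import uniform_permeability
from acatpk.pk_metrics import (
    MetricsError,
    PKMetrics,
    auc_trapezoid,
    compute_metrics,
    terminal_slope,
)
from acatpk.simulator import SimulationSettings, simulate

PK = PKParameters(body_weight=114.6, renal_clearance=0.18, volume_of_distribution=1.0)


@pytest.fixture(scope="module")
def oral_result():
    return simulate(
        default_fasted_physiology(),
        uniform_permeability(1e-5),
        metformin_profile(),
        PK,
        SimulationSettings(t_end=96.0, output_step=0.05),
    )


class TestAucTrapezoid:
    def test_constant_profile(self):
        t = np.linspace(0.0, 30.0, 301)
        assert auc_trapezoid(t, np.full_like(t, 7.0), 24.0) == pytest.approx(24.0 * 7.0)

    def test_triangle_area(self):
        t = np.array([0.0, 1.0, 2.0])
        c = np.array([0.0, 1000.0, 0.0])
        assert auc_trapezoid(t, c, 2.0) == pytest.approx(1000.0)

    def test_endpoint_interpolation(self):
        t = np.array([0.0, 2.0])
        c = np.array([0.0, 10.0])
        # integrating half the interval of a linear ramp: area 0.5*1*5
        assert auc_trapezoid(t, c, 1.0) == pytest.approx(2.5)

    def test_exponential_within_trapezoid_error_bound(self):
        h = 0.05
        t = np.arange(0.0, 24.0 + h / 2, h)
        c = np.exp(-0.3 * t)
        exact = (1.0 - np.exp(-0.3 * 24.0)) / 0.3
        bound = h * h / 12.0 * 0.3 * 0.3 * exact  # |f''| = k^2 f, integrated
        assert abs(auc_trapezoid(t, c, 24.0) - exact) <= bound * 1.01

    def test_upper_beyond_grid_rejected(self):
        t = np.linspace(0.0, 10.0, 11)
        with pytest.raises(MetricsError, match="outside"):
            auc_trapezoid(t, t, 12.0)

    def test_refining_grid_converges(self):
        k = 0.25
        aucs = []
        for h in (0.4, 0.2, 0.1):
            t = np.arange(0.0, 24.0 + h / 2, h)
            aucs.append(auc_trapezoid(t, 100 * np.exp(-k * t), 24.0))
        exact = 100 * (1 - np.exp(-k * 24)) / k
        errs = [abs(a - exact) for a in aucs]
        assert errs[0] > errs[1] > errs[2]  # second-order shrinkage


class TestComputeMetrics:
    def test_flat_zero_profile_gives_zero_metrics(self, fasted_physiology):
        result = simulate(
            fasted_physiology,
            uniform_permeability(0.0, colon_factor=0.0),
            metformin_profile(),
            PK,
            SimulationSettings(t_end=48.0, output_step=0.1),
        )
        m = compute_metrics(result, 1000.0, PK)
        assert (m.cmax, m.auc_0_24, m.auc_0_inf, m.bioavailability) == (0.0, 0.0, 0.0, 0.0)

    def test_iv_limit_closed_form_auc(self, fasted_physiology):
        result = simulate(
            fasted_physiology,
            uniform_permeability(1e-5),
            metformin_profile(),
            PK,
            SimulationSettings(t_end=96.0, output_step=0.05),
            iv_bolus=True,
        )
        m = compute_metrics(result, 1000.0, PK)
        assert m.auc_0_inf == pytest.approx(1000.0 / PK.clearance_total * 1000.0, rel=5e-3)

    def test_short_profile_rejected(self, fasted_physiology):
        result = simulate(
            fasted_physiology,
            uniform_permeability(1e-5),
            metformin_profile(),
            PK,
            SimulationSettings(t_end=12.0, output_step=0.1),
        )
        with pytest.raises(MetricsError, match="24"):
            compute_metrics(result, 1000.0, PK)

    def test_peak_refinement_close_to_grid_peak(self, oral_result):
        m = compute_metrics(oral_result, 1000.0, PK)
        i = int(np.argmax(oral_result.plasma_conc))
        assert m.cmax >= oral_result.plasma_conc[i]
        assert abs(m.tmax - oral_result.time[i]) <= oral_result.time[1]

    def test_auc24_below_auc_inf(self, oral_result):
        m = compute_metrics(oral_result, 1000.0, PK)
        assert m.auc_0_24 < m.auc_0_inf

    def test_terminal_slope_recovers_elimination_rate_without_colonic_input(self):
        # with no colonic absorption the gut input ends early and the late
        # profile decays at the disposition rate CL/Vd = 0.18 1/h
        result = simulate(
            default_fasted_physiology(),
            uniform_permeability(1e-5, colon_factor=0.0),
            metformin_profile(),
            PK,
            SimulationSettings(t_end=96.0, output_step=0.05),
        )
        lam = terminal_slope(result.time, result.plasma_conc)
        assert lam == pytest.approx(PK.elimination_rate, rel=0.05)

    def test_terminal_slope_is_absorption_limited_with_colonic_trickle(self, oral_result):
        # flip-flop kinetics: the slow colonic trickle (exit rate 1/13.5 h
        # plus a small ka) is slower than elimination, so it sets the
        # terminal slope
        lam = terminal_slope(oral_result.time, oral_result.plasma_conc)
        assert lam < PK.elimination_rate
        assert lam == pytest.approx(1.0 / 13.5, rel=0.15)

    def test_auc_identity_links_absorption_and_disposition(self, oral_result):
        m = compute_metrics(oral_result, 1000.0, PK)
        identity = m.bioavailability / 100.0 * 1000.0 / PK.clearance_total * 1000.0
        assert m.auc_0_inf == pytest.approx(identity, rel=0.01)

    def test_metric_convergence_under_grid_refinement(self, fasted_physiology):
        metrics = []
        for step in (0.2, 0.05):
            result = simulate(
                fasted_physiology,
                uniform_permeability(1e-5),
                metformin_profile(),
                PK,
                SimulationSettings(t_end=96.0, output_step=step),
            )
            metrics.append(compute_metrics(result, 1000.0, PK))
        assert metrics[0].cmax == pytest.approx(metrics[1].cmax, rel=1e-3)
        assert metrics[0].auc_0_24 == pytest.approx(metrics[1].auc_0_24, rel=1e-3)
        assert metrics[0].auc_0_inf == pytest.approx(metrics[1].auc_0_inf, rel=1e-3)


class TestPKMetricsInvariants:
    def test_auc24_cannot_exceed_auc_inf(self):
        with pytest.raises(MetricsError):
            PKMetrics(cmax=1.0, tmax=1.0, auc_0_24=10.0, auc_0_inf=5.0, bioavailability=10.0)

    def test_bioavailability_bounded(self):
        with pytest.raises(MetricsError):
            PKMetrics(cmax=1.0, tmax=1.0, auc_0_24=1.0, auc_0_inf=2.0, bioavailability=120.0)
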