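import pytest
from hypothesis import given
from hypothesis import strategies as st

from acatpk.permeability import (
    DEFAULT_SEGMENT_MAP,
    ParacellularModel,
    PermeabilityError,
    Provenance,
    SegmentalPermeability,
    assign_segments,
    fit_molecular_radius,
    paracellular_peff,
    rat_to_human,
    renkin_factor,
    uniform_permeability,
)
from acatpk.physiology import GUT_COMPARTMENTS, CompartmentName
from acatpk.spip import Segment


class TestRatToHuman:
    @pytest.mark.parametrize(
        "rat,expected",
        [
            (0.0, 3.0e-6),  # the correlation's intercept
            (2.795e-5, 3.6 * 2.795e-5 + 3.0e-6),  # ~1.036e-4
            (1.0e-4, 3.63e-4),
        ],
    )
    def test_affine_correlation(self, rat, expected):
        assert rat_to_human(rat) == pytest.approx(expected, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(PermeabilityError):
            rat_to_human(-1e-6)

    @given(
        a=st.floats(min_value=0.0, max_value=1e-3),
        b=st.floats(min_value=0.0, max_value=1e-3),
    )
    def test_affinity(self, a, b):
        lhs = rat_to_human(a) + rat_to_human(b) - rat_to_human(0.0)
        assert lhs == pytest.approx(rat_to_human(a + b), rel=1e-12, abs=1e-18)


class TestRenkinFactor:
    @pytest.mark.parametrize(
        "lam,expected",
        [
            (0.0, 1.0),
            (1.0, 0.0),
            (1.5, 0.0),  # beyond size exclusion
            (0.5, 0.25 * (1.0 - 1.052 + 2.09 * 0.125 - 0.95 * 0.03125)),  # 0.04489...
        ],
    )
    def test_sieving_factor(self, lam, expected):
        assert renkin_factor(lam) == pytest.approx(expected, rel=1e-12)

    @given(
        lam=st.floats(min_value=0.0, max_value=0.99),
        step=st.floats(min_value=1e-4, max_value=0.01),
    )
    def test_monotone_nonincreasing(self, lam, step):
        assert renkin_factor(lam + step) <= renkin_factor(lam) + 1e-15

    @given(lam=st.floats(min_value=0.0, max_value=5.0))
    def test_bounded_in_unit_interval(self, lam):
        assert 0.0 <= renkin_factor(lam) <= 1.0


class TestParacellularPeff:
    def test_sieved_out_above_pore_size(self):
        m = ParacellularModel(pore_radius=6.0, pore_capacity=1e-4, molecular_radius=6.0)
        assert paracellular_peff(m) == 0.0

    def test_point_solute_gets_full_capacity(self):
        m = ParacellularModel(pore_radius=6.0, pore_capacity=1e-4, molecular_radius=0.0)
        assert paracellular_peff(m) == pytest.approx(1e-4)

    def test_half_pore_radius(self):
        m = ParacellularModel(pore_radius=6.0, pore_capacity=1e-4, molecular_radius=3.0)
        assert paracellular_peff(m) == pytest.approx(1e-4 * renkin_factor(0.5), rel=1e-12)


class TestFitMolecularRadius:
    def test_round_trip_recovers_target_fraction(self):
        trans = 1e-5
        capacity = 100.0 * trans
        r = fit_molecular_radius(0.90, trans, pore_radius=6.0, pore_capacity=capacity)
        para = paracellular_peff(
            ParacellularModel(pore_radius=6.0, pore_capacity=capacity, molecular_radius=r)
        )
        assert para / (para + trans) == pytest.approx(0.90, abs=1e-6)
        # the 90:10 split with 100x capacity needs a sieving factor of 0.09
        assert renkin_factor(r / 6.0) == pytest.approx(0.09, abs=1e-4)

    def test_bisection_agrees_with_dense_grid_scan(self):
        import numpy as np

        trans, capacity, pore = 2e-5, 5e-3, 6.0
        target = 0.90
        r_fit = fit_molecular_radius(target, trans, pore_radius=pore, pore_capacity=capacity)
        grid = np.linspace(0.0, pore, 200001)
        fracs = np.array(
            [
                capacity * renkin_factor(g / pore) / (capacity * renkin_factor(g / pore) + trans)
                for g in grid
            ]
        )
        r_grid = grid[np.argmin(np.abs(fracs - target))]
        assert r_fit == pytest.approx(r_grid, abs=2 * pore / 200000)

    def test_vanishing_target_approaches_pore_radius(self):
        r = fit_molecular_radius(1e-9, 1e-5, pore_radius=6.0, pore_capacity=1e-3, tol=1e-12)
        assert r == pytest.approx(6.0, abs=0.05)

    def test_unreachable_target_rejected(self):
        # capacity == trans caps the fraction at 0.5
        with pytest.raises(PermeabilityError, match="unreachable"):
            fit_molecular_radius(0.90, 1e-5, pore_radius=6.0, pore_capacity=1e-5)

    @given(target=st.floats(min_value=0.05, max_value=0.95))
    def test_round_trip_property(self, target):
        trans, capacity, pore = 1e-5, 1e-3, 6.0
        r = fit_molecular_radius(target, trans, pore_radius=pore, pore_capacity=capacity)
        para = capacity * renkin_factor(r / pore)
        assert para / (para + trans) == pytest.approx(target, abs=1e-5)


class TestAssignSegments:
    MEASURED = {Segment.jejunum: 1e-4, Segment.mid_SI: 8e-5, Segment.ileum: 6e-5}

    def test_default_mapping(self, fasted_physiology):
        sp = assign_segments(self.MEASURED, 1.2e-4, fasted_physiology, colon_factor=0.1)
        v = sp.values
        assert v[CompartmentName.duodenum] == pytest.approx(1.2e-4)
        assert v[CompartmentName.jejunum1] == v[CompartmentName.jejunum2] == pytest.approx(1e-4)
        assert v[CompartmentName.ileum1] == pytest.approx(8e-5)
        assert v[CompartmentName.ileum2] == v[CompartmentName.ileum3] == pytest.approx(6e-5)
        assert v[CompartmentName.caecum] == pytest.approx(6e-6)
        assert v[CompartmentName.asc_colon] == pytest.approx(6e-6)
        assert sp.provenance is Provenance.segmental_measured

    def test_zero_colon_factor_zeroes_colonic_absorption(self, fasted_physiology):
        sp = assign_segments(self.MEASURED, 1.2e-4, fasted_physiology, colon_factor=0.0)
        assert sp.values[CompartmentName.caecum] == 0.0
        assert sp.values[CompartmentName.asc_colon] == 0.0

    def test_uniform_inputs_give_uniform_map(self, fasted_physiology):
        v = 5e-5
        sp = assign_segments(
            {s: v for s in Segment}, v, fasted_physiology, colon_factor=1.0
        )
        assert all(x == pytest.approx(v) for x in sp.values.values())

    def test_missing_segment_rejected(self, fasted_physiology):
        with pytest.raises(PermeabilityError, match="missing"):
            assign_segments({Segment.jejunum: 1e-4}, 1e-4, fasted_physiology)

    def test_ordered_inputs_stay_ordered(self, fasted_physiology):
        # distally decreasing measured values stay decreasing across compartments
        sp = assign_segments(self.MEASURED, 1.2e-4, fasted_physiology)
        values = [sp.values[n] for n in GUT_COMPARTMENTS[:6]]
        assert values == sorted(values, reverse=True)

    def test_segment_map_covers_distal_small_intestine(self):
        covered = {c for comps in DEFAULT_SEGMENT_MAP.values() for c in comps}
        assert covered == {
            CompartmentName.jejunum1,
            CompartmentName.jejunum2,
            CompartmentName.ileum1,
            CompartmentName.ileum2,
            CompartmentName.ileum3,
        }


class TestSegmentalPermeability:
    def test_scaling_preserves_ratios(self):
        sp = uniform_permeability(1e-4, colon_factor=0.1)
        scaled = sp.scaled(2.5)
        for name in GUT_COMPARTMENTS:
            assert scaled.values[name] == pytest.approx(2.5 * sp.values[name])

    def test_incomplete_map_rejected(self):
        with pytest.raises(PermeabilityError, match="eight"):
            SegmentalPermeability(
                values={CompartmentName.jejunum1: 1e-4}, provenance=Provenance.single_value
            )

    def test_negative_value_rejected(self):
        values = {n: 1e-4 for n in GUT_COMPARTMENTS}
        values[CompartmentName.ileum2] = -1e-5
        with pytest.raises(PermeabilityError, match="negative"):
            SegmentalPermeability(values=values, provenance=Provenance.single_value)
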