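"""Displacement generation: random-walk vector, component arithmetic,
repulsion, gradients, constraints and the assembled motion step."""

import math

import numpy as np
import pytest

from platesim.core import CellState, Constraint, PlateState, ScalarField
from platesim.motility import (
    MotionContext,
    apply_constraints,
    compose_displacement,
    effective_components,
    gradient_bias,
    random_walk_vector,
    repulsion_bias,
    step_motion,
)

from conftest import make_cell


class TestRandomWalkVector:
    def test_zero_module_gives_zero_vector(self, rng):
        assert random_walk_vector(0.0, rng) == (0.0, 0.0)

    def test_negative_module_rejected(self, rng):
        with pytest.raises(ValueError):
            random_walk_vector(-1.0, rng)

    def test_deterministic_for_fixed_seed(self):
        a = random_walk_vector(8.7, np.random.default_rng(42))
        b = random_walk_vector(8.7, np.random.default_rng(42))
        assert a == b

    def test_mean_resultant_matches_requested_module(self):
        """Monte-Carlo check of the ten-step walk calibration at module 8.7."""
        rng = np.random.default_rng(99)
        n = 100_000
        ang = rng.uniform(0, 2 * math.pi, (n, 10))
        step = 8.7 / 2.820439
        mods = step * np.hypot(np.cos(ang).sum(axis=1), np.sin(ang).sum(axis=1))
        assert mods.mean() == pytest.approx(8.7, abs=0.05)

    def test_direction_is_isotropic(self):
        rng = np.random.default_rng(3)
        vecs = np.array([random_walk_vector(5.0, rng) for _ in range(4000)])
        mean = vecs.mean(axis=0)
        assert np.hypot(*mean) < 0.25  # population mean vanishes


def test_compose_displacement_is_vector_sum():
    assert compose_displacement((1, 0), (1, 0), (1, 0)) == (3, 0)
    assert compose_displacement((0, 0), (0, 0), (0, 0)) == (0, 0)
    assert compose_displacement((1, 2), (-1, -2), (0.5, 0)) == (0.5, 0)


class TestEffectiveComponents:
    def test_immobile_when_coefficient_zero(self, nih3t3):
        cell = make_cell()
        out = effective_components(cell, nih3t3, MotionContext(k_total=0.0))
        assert out == (0.0, 0.0, (0.0, 0.0))

    def test_plain_fractions_without_bias(self, nih3t3):
        nih3t3.r_frac, nih3t3.p_frac, nih3t3.b_frac = 0.6, 0.4, 0.0
        rand, pers, bias = effective_components(make_cell(), nih3t3, MotionContext(k_total=0.5))
        d_tot = 0.5 * nih3t3.d_ref
        assert rand == pytest.approx(0.6 * d_tot)
        assert pers == pytest.approx(0.4 * d_tot)
        assert bias == (0.0, 0.0)

    def test_extra_bias_rescales_fractions_to_unit_sum(self, nih3t3):
        nih3t3.r_frac, nih3t3.p_frac, nih3t3.b_frac = 0.5, 0.3, 0.2
        ctx = MotionContext(k_total=1.0, extra_bias=[((0.2 * nih3t3.d_ref, 0.0), "x")])
        rand, pers, bias = effective_components(make_cell(), nih3t3, ctx)
        d_tot = nih3t3.d_ref
        b_new = math.hypot(*bias) / d_tot
        assert b_new == pytest.approx(0.4)
        assert (rand + pers) / d_tot + b_new == pytest.approx(1.0)
        # r and p shrink proportionally
        assert rand / pers == pytest.approx(0.5 / 0.3)

    def test_overwhelming_bias_is_capped_at_d_tot(self, nih3t3):
        ctx = MotionContext(k_total=1.0, extra_bias=[((100.0 * nih3t3.d_ref, 0.0), "x")])
        rand, pers, bias = effective_components(make_cell(), nih3t3, ctx)
        assert rand == 0.0 and pers == 0.0
        assert math.hypot(*bias) == pytest.approx(nih3t3.d_ref)


class TestRepulsionBias:
    def _plate(self, positions):
        plate = PlateState(width=1000, height=1000)
        for i, p in enumerate(positions, start=1):
            plate.cells.append(make_cell(cid=i, pos=p))
        plate.rebuild_grid(50.0)
        return plate

    def test_no_neighbours_no_push(self, nih3t3):
        plate = self._plate([(500, 500), (900, 900)])
        assert repulsion_bias(plate.cells[0], plate, nih3t3) == (0.0, 0.0)

    def test_single_neighbour_at_half_radius(self, nih3t3):
        R = nih3t3.repulsion_radius
        plate = self._plate([(500, 500), (500 + R / 2, 500)])
        vx, vy = repulsion_bias(plate.cells[0], plate, nih3t3)
        assert vy == pytest.approx(0.0)
        assert vx == pytest.approx(-nih3t3.repulsion_sensitivity * nih3t3.d_ref / 2)

    def test_symmetric_pair_pushes_along_the_bisector(self, nih3t3):
        R = nih3t3.repulsion_radius
        plate = self._plate([(500, 500), (500 + R / 2, 500), (500, 500 + R / 2)])
        vx, vy = repulsion_bias(plate.cells[0], plate, nih3t3)
        assert vx == pytest.approx(vy)
        assert vx < 0 and vy < 0

    def test_coincident_neighbour_uses_random_direction(self, nih3t3):
        plate = self._plate([(500, 500), (500, 500)])
        v1 = repulsion_bias(plate.cells[0], plate, nih3t3, np.random.default_rng(1))
        v2 = repulsion_bias(plate.cells[0], plate, nih3t3, np.random.default_rng(2))
        assert np.hypot(*v1) == pytest.approx(np.hypot(*v2))
        assert v1 != v2


class TestGradientBias:
    def test_uniform_field_gives_no_bias(self, nih3t3):
        f = ScalarField(lattice=np.full((20, 20), 3.0), cell_size=10.0)
        assert gradient_bias(make_cell(pos=(90, 90)), f, nih3t3) == (0.0, 0.0)

    def test_linear_field_points_uphill(self, nih3t3):
        lat = np.tile(np.arange(30, dtype=float), (30, 1))
        f = ScalarField(lattice=lat, cell_size=10.0, gain=2.0)
        vx, vy = gradient_bias(make_cell(pos=(150, 150)), f, nih3t3)
        assert vx > 0 and vy == pytest.approx(0.0)

    def test_cap_is_respected_exactly(self, nih3t3):
        lat = np.tile(np.arange(30, dtype=float) * 50, (30, 1))
        f = ScalarField(lattice=lat, cell_size=10.0, gain=10.0)
        v = gradient_bias(make_cell(pos=(150, 150)), f, nih3t3, cap=4.0)
        assert math.hypot(*v) == pytest.approx(4.0)

    def test_outside_field_feels_nothing(self, nih3t3):
        f = ScalarField(lattice=np.ones((5, 5)), cell_size=10.0)
        assert gradient_bias(make_cell(pos=(400, 400)), f, nih3t3) == (0.0, 0.0)


class TestApplyConstraints:
    def test_free_displacement_adds(self, empty_plate):
        assert apply_constraints((10, 10), (5, -3), empty_plate) == (15, 7)

    def test_stops_at_plate_edge(self, empty_plate):
        x, y = apply_constraints((995, 500), (20, 0), empty_plate)
        assert x == empty_plate.width and y == 500

    def test_blocking_region_is_never_entered(self, empty_plate):
        empty_plate.constraints.append(Constraint(300, 0, 400, 1000, factor=0.0))
        x, y = apply_constraints((250, 500), (100, 0), empty_plate)
        assert x == pytest.approx(300, abs=1e-6)
        assert x <= 300

    def test_slowing_region_scales_displacement(self, empty_plate):
        empty_plate.constraints.append(Constraint(0, 0, 1000, 1000, factor=0.5, name="gel"))
        assert apply_constraints((100, 100), (40, 20), empty_plate) == (120, 110)


class TestStepMotion:
    def test_quiescent_cells_move_less_than_cycling_ones(self, nih3t3):
        """Same random stream: the G0 displacement is strictly shorter."""
        plate = PlateState(width=2000, height=2000)
        disps = {}
        for phase in ("G1", "G0"):
            cell = make_cell(pos=(1000, 1000), phase=phase)
            plate.cells = [cell]
            plate.rebuild_grid(50.0)
            step_motion(cell, plate, nih3t3, 20.0, np.random.default_rng(77))
            disps[phase] = math.hypot(*cell.prev_disp)
        assert 0 < disps["G0"] < disps["G1"]

    def test_prev_disp_tracks_actual_displacement(self, nih3t3):
        plate = PlateState(width=2000, height=2000)
        cell = make_cell(pos=(1000, 1000))
        plate.cells = [cell]
        plate.rebuild_grid(50.0)
        start = cell.pos
        step_motion(cell, plate, nih3t3, 20.0, np.random.default_rng(5))
        assert cell.prev_disp == (cell.pos[0] - start[0], cell.pos[1] - start[1])
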