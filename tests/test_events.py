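"""Field dynamics, local confluence and the event system."""

import math

import numpy as np
import pytest

from platesim.attachment import projected_surface
from platesim.core import PlateState, ScalarField
from platesim.events import (
    EventSpec,
    apply_event,
    decay_field,
    degrade_locally,
    local_confluence,
)

from conftest import make_cell


class TestDecayField:
    def test_one_half_life_halves_everything(self):
        f = ScalarField(lattice=np.full((4, 4), 8.0), cell_size=10.0, half_life=120.0)
        decay_field(f, 120.0)
        assert np.allclose(f.lattice, 4.0)

    def test_infinite_half_life_is_identity(self):
        f = ScalarField(lattice=np.full((4, 4), 8.0), cell_size=10.0, half_life=math.inf)
        decay_field(f, 1e6)
        assert np.allclose(f.lattice, 8.0)

    def test_semigroup_property(self):
        a = ScalarField(lattice=np.full((3, 3), 5.0), cell_size=10.0, half_life=77.0)
        b = ScalarField(lattice=np.full((3, 3), 5.0), cell_size=10.0, half_life=77.0)
        decay_field(a, 60.0)
        decay_field(b, 30.0)
        decay_field(b, 30.0)
        assert np.allclose(a.lattice, b.lattice)


class TestDegradeLocally:
    def _field(self, value=10.0):
        return ScalarField(lattice=np.full((21, 21), value), cell_size=10.0,
                           degradable_by_cells=True)

    def test_no_cells_is_identity(self):
        f = self._field()
        degrade_locally(f, [], rate=1.0, dt=20.0, radius=20.0)
        assert np.allclose(f.lattice, 10.0)

    def test_cell_digs_a_local_pit_that_repels_gradient(self, nih3t3):
        from platesim.motility import gradient_bias

        f = self._field(50.0)
        digger = make_cell(cid=1, pos=(100.0, 100.0))
        for _ in range(3):
            degrade_locally(f, [digger], rate=0.5, dt=20.0, radius=20.0)
        assert f.lattice[10, 10] < 50.0  # pit centred on the cell
        assert f.lattice[10, 18] == 50.0  # far nodes untouched
        neighbour = make_cell(cid=2, pos=(125.0, 100.0))
        vx, vy = gradient_bias(neighbour, f, nih3t3)
        assert vx > 0  # pushed away from the pit, towards intact attractant

    def test_concentration_never_negative(self):
        f = self._field(1.0)
        cells = [make_cell(cid=i, pos=(100.0 + i, 100.0)) for i in range(3)]
        for _ in range(50):
            degrade_locally(f, cells, rate=5.0, dt=20.0, radius=25.0)
        assert (f.lattice >= 0.0).all()

    def test_requires_degradable_flag(self):
        f = ScalarField(lattice=np.ones((3, 3)), cell_size=10.0)
        with pytest.raises(ValueError):
            degrade_locally(f, [], 1.0, 20.0, 20.0)


class TestLocalConfluence:
    def test_empty_neighbourhood_is_zero(self, nih3t3):
        plate = PlateState(width=500, height=500)
        cell = make_cell(pos=(250, 250))
        plate.cells = [cell]
        plate.rebuild_grid(50.0)
        assert local_confluence(cell, plate, nih3t3) == 0.0

    def test_matches_brute_force_on_random_population(self, nih3t3):
        rng = np.random.default_rng(11)
        plate = PlateState(width=600, height=600)
        for i in range(300):
            plate.cells.append(make_cell(
                cid=i, pos=tuple(rng.uniform(0, 600, 2)),
                volume=float(rng.uniform(900, 2000)),
                spread_fraction=float(rng.uniform(0, 1))))
        plate.rebuild_grid(50.0)
        r = nih3t3.confluence_radius
        for idx in (0, 120, 299):
            cell = plate.cells[idx]
            covered = sum(
                projected_surface(o, nih3t3) for o in plate.cells
                if o.id != cell.id
                and math.hypot(o.pos[0] - cell.pos[0], o.pos[1] - cell.pos[1]) <= r)
            expected = min(1.0, covered / (math.pi * r * r))
            assert local_confluence(cell, plate, nih3t3) == pytest.approx(expected)

    def test_tiled_neighbourhood_clamps_to_one(self, nih3t3):
        plate = PlateState(width=300, height=300)
        cid = 1
        for x in range(30, 300, 25):
            for y in range(30, 300, 25):
                plate.cells.append(make_cell(cid=cid, pos=(x, y), volume=2000.0,
                                             spread_fraction=1.0))
                cid += 1
        plate.rebuild_grid(50.0)
        assert local_confluence(plate.cells[60], plate, nih3t3) == 1.0


class TestApplyEvent:
    def _plate(self, n=0):
        plate = PlateState(width=400, height=400)
        rng = np.random.default_rng(2)
        for i in range(1, n + 1):
            plate.cells.append(make_cell(cid=i, pos=tuple(rng.uniform(0, 400, 2))))
        return plate

    def test_unknown_kind_rejected_at_construction(self):
        with pytest.raises(ValueError):
            EventSpec(0.0, "teleportation", {})

    def test_medium_change_replaces_serum_and_molecules(self, rng):
        plate = self._plate()
        plate.medium.molecules["old"] = 3.0
        apply_event(plate, EventSpec(0, "mediumChange", {
            "serum_type": "cs", "serum_level": 2.5, "molecules": {"glc": 1.0}}), rng)
        assert plate.medium.serum_type == "cs"
        assert plate.medium.serum_level == 2.5
        assert plate.medium.molecules == {"glc": 1.0}

    def test_molecule_addition_accumulates(self, rng):
        plate = self._plate()
        for _ in range(2):
            apply_event(plate, EventSpec(0, "moleculeAddition",
                                         {"name": "drug", "concentration": 0.5}), rng)
        assert plate.medium.molecules["drug"] == pytest.approx(1.0)

    def test_gradient_addition_installs_a_field(self, rng):
        plate = self._plate()
        apply_event(plate, EventSpec(0, "gradientAddition", {
            "name": "att", "amplitude": 7.0, "half_life": 120.0,
            "degradable_by_cells": True, "node_size": 20.0}), rng)
        f = plate.fields["att"]
        assert f.degradable_by_cells and f.half_life == 120.0
        assert f.sample((200.0, 200.0)) == pytest.approx(7.0)

    def test_constraints_can_be_added_and_removed(self, rng):
        plate = self._plate()
        apply_event(plate, EventSpec(0, "constraintAddition",
                                     {"x0": 0, "x1": 50, "y0": 0, "y1": 400,
                                      "name": "fence"}), rng)
        assert len(plate.constraints) == 1
        apply_event(plate, EventSpec(0, "constraintRemoval", {"name": "fence"}), rng)
        assert plate.constraints == []

    def test_scratch_damages_exactly_the_cells_in_the_band(self, rng):
        plate = self._plate()
        inside = [make_cell(cid=100 + i, pos=(150.0 + i, 200.0)) for i in range(5)]
        outside = [make_cell(cid=200 + i, pos=(350.0, 50.0 + 40 * i)) for i in range(4)]
        plate.cells = inside + outside
        ev = EventSpec(0, "scratchOnPlate",
                       {"x0": 140.0, "x1": 260.0, "debris_amplitude": 30.0})
        apply_event(plate, ev, rng)
        assert all(c.cycle_phase == "DAMAGED" and c.damage_level == 1.0 for c in inside)
        assert all(c.cycle_phase != "DAMAGED" for c in outside)
        assert ev.payload["cells_damaged"] == 5
        debris = plate.fields["debris"]
        assert debris.sample((200.0, 200.0)) > 0.0
        assert debris.sample((350.0, 200.0)) == 0.0

    def test_transfection_fraction_tracks_efficiency(self):
        plate = self._plate(500)
        apply_event(plate, EventSpec(0, "transfection",
                                     {"gene": "gfp", "efficiency": 0.0}),
                    np.random.default_rng(1))
        assert sum("gfp" in c.genes for c in plate.cells) == 0
        eff = 0.3
        apply_event(plate, EventSpec(0, "transfection",
                                     {"gene": "gfp", "efficiency": eff}),
                    np.random.default_rng(1))
        n = sum("gfp" in c.genes for c in plate.cells)
        sigma = math.sqrt(500 * eff * (1 - eff))
        assert abs(n - 500 * eff) < 4 * sigma

    def test_viral_infection_arms_timers_in_the_region(self, rng):
        plate = self._plate(50)
        apply_event(plate, EventSpec(0, "viralInfection", {
            "region": {"x0": 0, "x1": 200, "y0": 0, "y1": 400},
            "lysis_minutes": 540.0}), rng)
        for c in plate.cells:
            if c.pos[0] <= 200:
                assert c.infection_timer == 540.0
            else:
                assert c.infection_timer is None
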