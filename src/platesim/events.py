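"""Environment dynamics and scheduled plate events.

Scalar attractant fields decay with their half-life and can be locally
consumed by cells (the self-generated-gradient mechanism: a shallow or flat
field develops steep local gradients where cells sit, because the cells
themselves degrade the attractant in their vicinity).

Eight event kinds perturb a running plate: ``update`` (bookkeeping no-op),
``mediumChange``, ``moleculeAddition``, ``gradientAddition``,
``constraintAddition``, ``constraintRemoval``, ``scratchOnPlate``,
``transfection`` and ``viralInfection``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np

from .attachment import projected_surface
from .core import CellState, CellTypeParams, Constraint, PlateState, ScalarField

__all__ = [
    "EVENT_KINDS",
    "EventSpec",
    "decay_field",
    "degrade_locally",
    "local_confluence",
    "apply_event",
]

EVENT_KINDS = (
    "update",
    "mediumChange",
    "moleculeAddition",
    "gradientAddition",
    "constraintAddition",
    "constraintRemoval",
    "scratchOnPlate",
    "transfection",
    "viralInfection",
)


@dataclass
class EventSpec:
    """A scheduled perturbation of the plate or its cells."""

    time: float
    kind: str
    payload: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; choices: {EVENT_KINDS}")


def decay_field(fld: ScalarField, dt: float) -> None:
    """First-order decay: every node times ``2**(-dt / half_life)`` in place."""
    if math.isinf(fld.half_life):
        return
    if fld.half_life <= 0:
        raise ValueError("half_life must be positive or infinite")
    fld.lattice *= 2.0 ** (-dt / fld.half_life)


def degrade_locally(fld: ScalarField, cells: Iterable[CellState],
                    rate: float, dt: float, radius: float) -> None:
    """Consume attractant around live cells (self-generated gradients).

    Every lattice node within ``radius`` µm of a live cell loses
    ``rate * dt`` concentration, floored at zero.  Overlapping cells stack,
    so dense regions dig deeper pits and steeper local gradients than
    sparse ones.
    """
    if not fld.degradable_by_cells:
        raise ValueError("field is not degradable by cells")
    ny, nx = fld.lattice.shape
    cs = fld.cell_size
    amount = rate * dt
    r_nodes = radius / cs
    for c in cells:
        if not c.alive:
            continue
        gx, gy = c.pos[0] / cs, c.pos[1] / cs
        i0 = max(0, int(math.ceil(gx - r_nodes)))
        i1 = min(nx - 1, int(math.floor(gx + r_nodes)))
        j0 = max(0, int(math.ceil(gy - r_nodes)))
        j1 = min(ny - 1, int(math.floor(gy + r_nodes)))
        if i1 < i0 or j1 < j0:
            continue
        ii = np.arange(i0, i1 + 1)
        jj = np.arange(j0, j1 + 1)
        mask = ((ii[None, :] - gx) ** 2 + (jj[:, None] - gy) ** 2) <= r_nodes ** 2
        block = fld.lattice[j0:j1 + 1, i0:i1 + 1]
        block[mask] = np.maximum(0.0, block[mask] - amount)


def local_confluence(cell: CellState, plate: PlateState, params: CellTypeParams,
                     radius: Optional[float] = None) -> float:
    """Fraction of the disc of given radius covered by neighbours' footprints.

    Sum of the projected surfaces of all *other* live cells within the
    radius, divided by the disc area, clamped to 1.  Requires the plate's
    neighbour grid to be built.
    """
    r = radius if radius is not None else params.confluence_radius
    if r <= 0:
        raise ValueError("radius must be positive")
    if plate.grid is None:
        return 0.0
    by_id = getattr(plate, "_by_id", None)
    if by_id is None:
        by_id = {c.id: c for c in plate.cells}
    covered = 0.0
    for nid, _dist in plate.grid.query(cell.pos, r, exclude=cell.id):
        covered += projected_surface(by_id[nid], params)
    return min(1.0, covered / (math.pi * r * r))


def _band(payload: Dict, plate: PlateState) -> Constraint:
    return Constraint(
        x0=payload.get("x0", 0.0),
        y0=payload.get("y0", 0.0),
        x1=payload.get("x1", plate.width),
        y1=payload.get("y1", plate.height),
        factor=payload.get("factor", 0.0),
        name=payload.get("name", "region"),
    )


def _uniform_field(plate: PlateState, amplitude: float, node: float,
                   half_life: float, degradable: bool, gain: float) -> ScalarField:
    nx = int(plate.width / node) + 1
    ny = int(plate.height / node) + 1
    return ScalarField(
        lattice=np.full((ny, nx), amplitude, dtype=float),
        cell_size=node, half_life=half_life,
        degradable_by_cells=degradable, gain=gain,
    )


def apply_event(plate: PlateState, event: EventSpec,
                rng: np.random.Generator) -> None:
    """Apply one event to the plate in place."""
    p = event.payload
    kind = event.kind
    if kind == "update":
        return
    if kind == "mediumChange":
        if "serum_type" in p:
            plate.medium.serum_type = p["serum_type"]
        if "serum_level" in p:
            plate.medium.serum_level = float(p["serum_level"])
        if "molecules" in p:
            plate.medium.molecules = dict(p["molecules"])
        return
    if kind == "moleculeAddition":
        name = p["name"]
        plate.medium.molecules[name] = plate.medium.molecules.get(name, 0.0) + float(p["concentration"])
        return
    if kind == "gradientAddition":
        name = p.get("name", "attractant")
        node = float(p.get("node_size", 10.0))
        half_life = float(p.get("half_life", math.inf)) if p.get("half_life") is not None else math.inf
        fld = _uniform_field(
            plate, float(p.get("amplitude", 1.0)), node, half_life,
            bool(p.get("degradable_by_cells", False)), float(p.get("gain", 1.0)),
        )
        if p.get("slope_x"):
            ny, nx = fld.lattice.shape
            fld.lattice += float(p["slope_x"]) * np.arange(nx)[None, :] * node
        if "region" in p:
            reg = _band(p["region"], plate)
            ny, nx = fld.lattice.shape
            xs = np.arange(nx) * node
            ys = np.arange(ny) * node
            inside = ((xs[None, :] >= reg.x0) & (xs[None, :] <= reg.x1)
                      & (ys[:, None] >= reg.y0) & (ys[:, None] <= reg.y1))
            fld.lattice = np.where(inside, fld.lattice, 0.0)
        plate.fields[name] = fld
        return
    if kind == "constraintAddition":
        plate.constraints.append(_band(p, plate))
        return
    if kind == "constraintRemoval":
        name = p.get("name")
        plate.constraints = [c for c in plate.constraints if c.name != name]
        return
    if kind == "scratchOnPlate":
        band = _band(p, plate)
        n_hit = 0
        for c in plate.cells:
            if c.alive and band.contains(c.pos):
                c.cycle_phase = "DAMAGED"
                c.damage_level = float(p.get("damage_level", 1.0))
                c.attach_phase = "DESPREADING"
                n_hit += 1
        if p.get("debris_amplitude", 0.0) > 0.0:
            apply_event(plate, EventSpec(event.time, "gradientAddition", {
                "name": p.get("debris_name", "debris"),
                "amplitude": float(p["debris_amplitude"]),
                "half_life": float(p.get("debris_half_life", 240.0)),
                "degradable_by_cells": True,
                "gain": float(p.get("debris_gain", 1.0)),
                "node_size": float(p.get("node_size", 10.0)),
                "region": {"x0": band.x0, "x1": band.x1, "y0": band.y0, "y1": band.y1},
            }), rng)
        p["cells_damaged"] = n_hit
        return
    if kind == "transfection":
        gene = p["gene"]
        eff = float(p.get("efficiency", 0.1))
        for c in plate.cells:
            if c.alive and rng.random() < eff:
                c.genes.add(gene)
        return
    if kind == "viralInfection":
        lysis = float(p.get("lysis_minutes", 540.0))
        targets: List[CellState] = []
        live = [c for c in plate.cells if c.alive]
        if "region" in p:
            band = _band(p["region"], plate)
            targets = [c for c in live if band.contains(c.pos)]
        elif "count" in p:
            n = min(int(p["count"]), len(live))
            idx = rng.choice(len(live), size=n, replace=False) if n else []
            targets = [live[i] for i in np.atleast_1d(idx)]
        for c in targets:
            c.infection_timer = lysis
        p.setdefault("spread_radius", 40.0)
        p.setdefault("spread_prob", 0.7)
        p["lysis_minutes"] = lysis
        return
    raise ValueError(f"unhandled event kind {kind!r}")  # pragma: no cover
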