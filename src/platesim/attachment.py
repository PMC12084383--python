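"""Attachment/spreading state machine and the volume -> footprint relation.

Freshly plated or newborn cells run DETACHED -> ATTACHED -> SPREADING ->
SPREAD; entry into mitosis or apoptosis forces DESPREADING (cells round up),
and after division daughters re-enter SPREADING from the mitotic minimum.
While SPREADING/DESPREADING a continuous ``spread_fraction`` in [0, 1]
advances/retreats at a constant rate, so the projected footprint

    surface = c * V**(2/3) * (1 + (s_max - 1) * spread_fraction)

interpolates between a sphere-like cross-section when round and an
``s_max``-fold larger footprint when fully spread.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import CellState, CellTypeParams, PlateState, transition_probability

__all__ = ["projected_surface", "step_attachment"]


def projected_surface(cell: CellState, params: CellTypeParams) -> float:
    """Projected substrate footprint (µm²) of a cell."""
    if cell.volume <= 0:
        raise ValueError("volume must be positive")
    base = params.surface_coeff * cell.volume ** (2.0 / 3.0)
    return base * (1.0 + (params.spread_gain - 1.0) * cell.spread_fraction)


def step_attachment(cell: CellState, plate: PlateState, params: CellTypeParams,
                    dt: float, rng: np.random.Generator) -> None:
    """Advance the attachment machine by one interval.

    Stochastic edges (DETACHED -> ATTACHED -> SPREADING) come from the
    cell-type's attachment transition table; the continuous spreading /
    de-spreading ramps are deterministic.  M and APO keep the cell pinned in
    DESPREADING until the phase resolves.
    """
    if not cell.alive:
        return
    phase = cell.attach_phase

    if cell.cycle_phase in ("M", "APO"):
        cell.attach_phase = "DESPREADING"
        phase = "DESPREADING"

    if phase == "SPREADING":
        cell.spread_fraction = min(1.0, cell.spread_fraction + dt / params.spread_minutes)
        if cell.spread_fraction >= 1.0:
            cell.attach_phase = "SPREAD"
        return
    if phase == "DESPREADING":
        cell.spread_fraction = max(
            params.min_spread_fraction, cell.spread_fraction - dt / params.despread_minutes
        )
        if cell.cycle_phase not in ("M", "APO") and cell.spread_fraction <= params.min_spread_fraction:
            # injury resolved or mis-entered: resume spreading
            cell.attach_phase = "SPREADING"
        return
    if phase == "SPREAD":
        cell.spread_fraction = 1.0
        return

    # stochastic edges out of DETACHED / ATTACHED
    for tr in params.attach_transitions:
        if tr.from_state != phase:
            continue
        p = transition_probability(tr, cell, plate, dt)
        if rng.random() < p:
            cell.attach_phase = tr.to_state
            return
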