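"""Cell-cycle state machine: growth, phase transitions, division, vitality
and the cdt1/p27 reporter pair.

Phases form a Markov chain G1 -> G1c -> S -> G2 -> M -> division, with a
reversible quiescence branch G1 <-> G0, apoptosis from G1/G0, and a DAMAGED
state fed by physical injury.  Each edge carries a base probability over a
reference time plus logistic factors (serum, volume, crowding, ...), and two
hard gates ride on top of the stochastic draws: S entry requires the DNA to
be flagged ready for duplication, and G2 entry requires replication to have
completed (``dna_fraction == 1``).  DNA progress advances deterministically
at ``1 / s_phase_minutes`` per minute while a cell sits in S.

Volume grows exponentially, ``V(t + dt) = V * exp(alpha * dt)``, where
``alpha`` is the phase-specific rate scaled by a fixed per-cell modifier
(log-normal around 1, giving the between-cell growth variability of real
cultures) and by optional serum/confluence logistic factors.
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import numpy as np

from .core import (
    CellState,
    CellTypeParams,
    PlateState,
    TransitionSpec,
    adapt_probability,
    logistic_effect,
    transition_probability,
)

__all__ = [
    "grow_volume",
    "effective_alpha",
    "step_cycle",
    "divide",
    "update_vitality",
    "update_reporters",
]


def grow_volume(volume: float, alpha: float, dt: float) -> float:
    """Exponential volumetric growth ``V * exp(alpha * dt)``."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return volume * math.exp(alpha * dt)


def effective_alpha(cell: CellState, plate: PlateState, params: CellTypeParams,
                    local_confluence: Optional[float] = None) -> float:
    """Phase- and condition-scaled growth rate for one cell."""
    alpha = params.alpha_growth.get(cell.cycle_phase, 0.0) * cell.growth_rate_modifier
    if alpha == 0.0:
        return 0.0
    if params.growth_serum_factor is not None:
        alpha *= params.growth_serum_factor.effect(plate.medium.serum_level)
    if params.growth_confluence_factor is not None and local_confluence is not None:
        alpha *= params.growth_confluence_factor.effect(local_confluence)
    # growth requires attachment: cells in suspension barely grow
    if cell.attach_phase == "DETACHED":
        alpha *= 0.2
    return alpha


def _gated(tr: TransitionSpec, cell: CellState) -> bool:
    """Hard gates that override the stochastic draw."""
    if tr.from_state == "G1c" and tr.to_state == "S" and not cell.rfd_dna:
        return False
    if tr.from_state == "S" and tr.to_state == "G2" and cell.dna_fraction < 1.0:
        return False
    return True


def step_cycle(cell: CellState, plate: PlateState, params: CellTypeParams,
               dt: float, rng: np.random.Generator,
               local_confluence: Optional[float] = None) -> Optional[str]:
    """Advance one cell through one time interval of the cycle machine.

    Grows the volume, advances DNA replication and age, then draws at most
    one phase transition among the edges leaving the current phase.  Returns
    ``"divide"`` when the mitosis-completion edge fires (the caller performs
    the division), otherwise ``None``.  DEAD cells are absorbing and
    untouched.
    """
    if cell.cycle_phase == "DEAD":
        return None

    cell.volume = grow_volume(
        cell.volume, effective_alpha(cell, plate, params, local_confluence), dt
    )
    if cell.cycle_phase == "S" and cell.dna_fraction < 1.0:
        cell.dna_fraction = min(1.0, cell.dna_fraction + dt / params.s_phase_minutes)
    cell.age += dt

    edges = [tr for tr in params.transitions
             if tr.from_state == cell.cycle_phase and _gated(tr, cell)]
    if not edges:
        return None
    probs = [transition_probability(tr, cell, plate, dt, local_confluence) for tr in edges]
    total = sum(probs)
    if total > 1.0:  # defensive: normalise rather than overflow the unit interval
        probs = [p / total for p in probs]
    u = rng.random()
    acc = 0.0
    chosen: Optional[TransitionSpec] = None
    for tr, p in zip(edges, probs):
        acc += p
        if u < acc:
            chosen = tr
            break
    if chosen is None:
        return None

    if chosen.to_state == "DIVIDE":
        return "divide"
    _enter_phase(cell, chosen.to_state)
    return None


def _enter_phase(cell: CellState, phase: str) -> None:
    cell.cycle_phase = phase
    if phase == "G1c":
        cell.rfd_dna = True  # licensing: DNA flagged ready on cycle commitment
    elif phase == "S":
        cell.dna_fraction = 0.0
    elif phase in ("M", "APO"):
        cell.attach_phase = "DESPREADING"


def divide(cell: CellState, params: CellTypeParams, rng: np.random.Generator,
           next_id: int) -> Tuple[CellState, CellState]:
    """Split an M-phase cell into two G1 daughters.

    Daughter volumes sum to the parent volume (near-symmetric split with a
    small configurable Gaussian asymmetry), ages restart at 0, positions are
    offset by one cell radius in a random direction, and each daughter draws
    a fresh growth-rate modifier.  Both inherit the parent's genes.
    """
    frac = 0.5
    if params.division_asymmetry > 0:
        frac = min(0.75, max(0.25, rng.normal(0.5, params.division_asymmetry)))
    v1 = cell.volume * frac
    v2 = cell.volume - v1
    r = cell.radius()
    theta = rng.uniform(0.0, 2.0 * math.pi)
    off = (r * math.cos(theta), r * math.sin(theta))

    def _daughter(cid: int, vol: float, sign: float) -> CellState:
        d = CellState(
            id=cid,
            pos=(cell.pos[0] + sign * off[0], cell.pos[1] + sign * off[1]),
            volume=vol,
            cycle_phase="G1",
            attach_phase="SPREADING",
            age=0.0,
            vitality=cell.vitality,
            genes=set(cell.genes),
            growth_rate_modifier=float(rng.lognormal(0.0, params.growth_sigma)),
            spread_fraction=params.min_spread_fraction,
            parent=cell.id,
            origin="newborn",
            cdt1=cell.cdt1 * 0.5,
            p27=cell.p27 * 0.5,
        )
        return d

    return _daughter(next_id, v1, 1.0), _daughter(next_id + 1, v2, -1.0)


def update_vitality(cell: CellState, plate: PlateState, params: CellTypeParams,
                    dt: float, rng: np.random.Generator) -> None:
    """Vitality bookkeeping: apoptosis progression, damage resolution, drugs.

    Apoptotic cells lose vitality at a fixed rate and die at vitality 0.
    Damaged cells either recover or die, with the two probabilities shaped
    oppositely by the damage level through the logistic curve.  Dissolved
    drug molecules drain vitality according to the per-molecule sensitivity
    unless the cell carries the protective gene for that molecule.
    """
    if cell.cycle_phase == "DEAD":
        return

    if cell.cycle_phase == "APO":
        cell.vitality = max(0.0, cell.vitality - params.apo_vitality_rate * dt)

    if cell.cycle_phase == "DAMAGED":
        rec_eff = logistic_effect(cell.damage_level, params.damage_x_ref, params.damage_k)
        die_eff = logistic_effect(cell.damage_level, params.damage_x_ref, -params.damage_k)
        p_rec = adapt_probability(params.damage_recover_prob, params.damage_prob_time, dt) * rec_eff
        p_die = adapt_probability(params.damage_death_prob, params.damage_prob_time, dt) * die_eff
        u = rng.random()
        if u < p_rec:
            cell.cycle_phase = "G1"
            cell.damage_level = 0.0
        elif u < p_rec + p_die:
            _kill(cell, plate.time)
            return

    for molecule, sensitivity in params.drug_sensitivity.items():
        conc = plate.medium.molecules.get(molecule, 0.0)
        if conc <= 0.0:
            continue
        gene = params.protective_genes.get(molecule)
        if gene is not None and gene in cell.genes:
            continue
        cell.vitality = max(0.0, cell.vitality - sensitivity * conc * dt)

    if cell.vitality <= 0.0:
        _kill(cell, plate.time)


def _kill(cell: CellState, time: float) -> None:
    cell.cycle_phase = "DEAD"
    cell.vitality = 0.0
    cell.destiny = "dead"
    cell.death_time = time


#: Default reporter kinetics (synthesis in au/min, decay in 1/min) giving a
#: high-(cdt1, p27) fixed point in G0 and a low-p27 band in cycling phases,
#: with cdt1 actively degraded through S.
_CDT1_SYNTH = {"G1": 1.0, "G1c": 1.0, "G0": 1.0, "S": 0.0, "G2": 0.1, "M": 0.1}
_CDT1_DECAY = {"S": 0.05}
_P27_SYNTH = {"G0": 0.5}
_P27_DECAY: dict = {}
_BASE_CDT1_DECAY = 0.01
_BASE_P27_SYNTH = 0.02
_BASE_P27_DECAY = 0.005


def update_reporters(cell: CellState, params: CellTypeParams, dt: float) -> None:
    """First-order synthesis/decay of the cdt1 and p27 reporters.

    Each reporter relaxes toward its phase-dependent steady state s/delta:
    p27 accumulates only in G0; cdt1 accumulates in G1/G0 and is degraded in
    S, so the (cdt1, p27) plane separates cycling from quiescent cells.
    """
    if cell.cycle_phase == "DEAD":
        return
    phase = cell.cycle_phase
    s_c = params.cdt1_synthesis.get(phase, _CDT1_SYNTH.get(phase, 0.0))
    d_c = params.cdt1_decay.get(phase, _CDT1_DECAY.get(phase, _BASE_CDT1_DECAY))
    s_p = params.p27_synthesis.get(phase, _P27_SYNTH.get(phase, _BASE_P27_SYNTH))
    d_p = params.p27_decay.get(phase, _P27_DECAY.get(phase, _BASE_P27_DECAY))
    # exact relaxation of dc/dt = s - d*c over the interval
    for attr, s, d in (("cdt1", s_c, d_c), ("p27", s_p, d_p)):
        c = getattr(cell, attr)
        if d > 0:
            ss = s / d
            c = ss + (c - ss) * math.exp(-d * dt)
        else:
            c = c + s * dt
        setattr(cell, attr, c)
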