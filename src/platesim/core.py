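"""Shared domain types and the two elementary stochastic primitives.

Every probabilistic transition in the simulator is specified as a *base
probability over a reference time* (``base_prob`` per ``prob_time`` minutes)
together with a list of logistic factors that enhance or limit it.  Two
primitives implement this scheme:

``adapt_probability``
    rescales a probability stated for one time span to the simulation
    interval, treating the event as a memoryless hazard, so the same
    parameter set works at any update interval between a few minutes and a
    few hours.

``logistic_effect``
    maps a physiological quantity (serum level, volume, local confluence,
    ...) onto a (0, 1) multiplier through a logistic curve centred on the
    half-effect value ``x_ref`` with steepness ``k``.

Coordinates are Cartesian micrometres, origin at the bottom-left plate
corner, y pointing up.  Times are minutes.  Volumes are µm³, surfaces µm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "PHASES",
    "ATTACH_PHASES",
    "FactorSpec",
    "TransitionSpec",
    "CellTypeParams",
    "CellState",
    "ScalarField",
    "NeighborGrid",
    "Constraint",
    "Medium",
    "PlateState",
    "adapt_probability",
    "logistic_effect",
    "combine_factor_effects",
]

#: Cell-cycle phases.  DIVIDE is a pseudo-target used in transition tables to
#: mark the mitosis-completion edge; cells never persist in it.
PHASES = ("G1", "G1c", "S", "G2", "M", "G0", "APO", "DAMAGED", "DEAD")

ATTACH_PHASES = ("DETACHED", "ATTACHED", "SPREADING", "SPREAD", "DESPREADING")

#: Quantities a logistic factor may read off a cell/plate pair.
FACTOR_QUANTITIES = (
    "serum_level",
    "volume",
    "local_confluence",
    "vitality",
    "drug_level",
    "attachment_state",
    "gene_presence",
)


def adapt_probability(prob: float, prob_time: float, time_int: float) -> float:
    """Rescale a transition probability to the simulation time interval.

    ``prob`` is the probability that the event happens at least once within
    ``prob_time`` minutes.  The returned value is the probability over
    ``time_int`` minutes under the memoryless assumption::

        p(dt) = 1 - (1 - p)**(dt / prob_time)

    which makes survival probabilities multiply exactly across interval
    splits: applying the result twice with ``dt`` equals applying once with
    ``2*dt``.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob must be in [0, 1], got {prob!r}")
    if prob_time <= 0 or time_int <= 0:
        raise ValueError("prob_time and time_int must be positive")
    return 1.0 - (1.0 - prob) ** (time_int / prob_time)


def logistic_effect(x_c: float, x_ref: float, k_steep: float) -> float:
    """Logistic multiplier ``1 / (1 + exp(k*(x_c - x_ref)))`` in (0, 1).

    Decreasing in ``x_c`` for ``k_steep > 0`` (a *limiting* factor: high
    values of the quantity suppress the transition); pass a negative
    ``k_steep`` for an *enhancing* factor.  Equals 0.5 at ``x_c == x_ref``
    and saturates smoothly without overflow for extreme arguments.
    """
    z = k_steep * (x_c - x_ref)
    if z > 700.0:
        return 0.0
    if z < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def combine_factor_effects(base_prob: float, effects: Iterable[float]) -> float:
    """Multiply a base probability by a set of (0, 1) factor effects.

    The combination is multiplicative: every factor can only attenuate the
    base, and the result stays a probability.  Clamped to [0, 1] for safety
    against rounding.
    """
    p = base_prob
    for e in effects:
        p *= e
    return min(1.0, max(0.0, p))


@dataclass(frozen=True)
class FactorSpec:
    """One logistic factor modulating a stochastic transition.

    ``x_ref`` is the quantity value at which the factor contributes 0.5;
    ``k_steep`` (inverse quantity units, positive) sets the slope, and
    ``direction`` chooses whether high quantity values enhance or limit the
    transition.  ``target`` names a molecule (for ``drug_level``) or a gene
    (for ``gene_presence``) where the quantity alone is ambiguous.
    """

    quantity: str
    x_ref: float
    k_steep: float
    direction: str = "enhancing"  # or "limiting"
    target: Optional[str] = None

    def __post_init__(self):
        if self.quantity not in FACTOR_QUANTITIES:
            raise ValueError(f"unknown factor quantity {self.quantity!r}")
        if self.direction not in ("enhancing", "limiting"):
            raise ValueError(f"direction must be enhancing/limiting, got {self.direction!r}")
        if not math.isfinite(self.k_steep):
            raise ValueError("k_steep must be finite")

    def effect(self, x_c: float) -> float:
        """Evaluate the factor at the current quantity value."""
        k = self.k_steep if self.direction == "limiting" else -self.k_steep
        return logistic_effect(x_c, self.x_ref, k)


@dataclass(frozen=True)
class TransitionSpec:
    """One edge of a stochastic state machine (cycle or attachment).

    Parallel edges between the same pair of states are allowed, which gives
    OR semantics between independent causes (e.g. quiescence entry driven by
    starvation or by crowding) that a single multiplicative factor list
    cannot express.
    """

    from_state: str
    to_state: str
    base_prob: float
    prob_time: float
    factors: Tuple[FactorSpec, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.base_prob <= 1.0:
            raise ValueError("base_prob must be in [0, 1]")
        if self.prob_time <= 0:
            raise ValueError("prob_time must be positive")


@dataclass
class CellTypeParams:
    """Per-cell-type constants.

    Motion: ``d_ref`` is the maximum potential displacement (µm) per
    reference interval under optimal conditions; ``r_frac``, ``p_frac``,
    ``b_frac`` (summing to 1) are the fractions of the condition-scaled
    displacement assigned to the random, persistence and bias components;
    ``bias_angle`` orients the global bias.

    Growth: ``alpha_growth`` maps cycle phase to a per-minute exponential
    volume growth rate; ``v_birth`` is the typical post-division volume.

    ``transitions`` holds the cycle edges, ``attach_transitions`` the
    attachment-machine edges; both use :class:`TransitionSpec`.
    """

    name: str = "generic"
    d_ref: float = 10.0
    r_frac: float = 1.0
    p_frac: float = 0.0
    b_frac: float = 0.0
    bias_angle: float = 0.0
    ref_interval: float = 20.0  # minutes the motion moduli refer to
    alpha_growth: Dict[str, float] = field(default_factory=dict)
    v_birth: float = 1000.0
    transitions: List[TransitionSpec] = field(default_factory=list)
    attach_transitions: List[TransitionSpec] = field(default_factory=list)
    s_phase_minutes: float = 420.0
    repulsion_radius: float = 40.0
    repulsion_sensitivity: float = 0.15
    sensing_distance: float = 20.0
    attractant_degradation_rate: float = 0.5  # amount / min / cell
    confluence_radius: float = 50.0
    # motility condition multipliers (cumulative coefficient k)
    phase_motility: Dict[str, float] = field(default_factory=dict)
    attach_motility: Dict[str, float] = field(default_factory=dict)
    confluence_motility: Optional[FactorSpec] = None
    serum_motility: Optional[FactorSpec] = None
    gradient_gain: float = 1.0  # µm of bias per unit concentration difference
    # attachment / spreading geometry
    surface_coeff: float = 1.21  # sphere cross-section: pi*(3V/4pi)^(2/3) ~ 1.21 V^(2/3)
    spread_gain: float = 4.0  # fully spread footprint / detached footprint
    spread_minutes: float = 120.0
    despread_minutes: float = 30.0
    min_spread_fraction: float = 0.1
    #: cumulative cycle-position edges used when seeding cells mid-cycle,
    #: matching the realized phase durations of the calibrated table
    seed_phase_edges: Tuple[Tuple[str, float], ...] = (
        ("G1", 0.55), ("G1c", 0.58), ("S", 0.87), ("G2", 0.98), ("M", 1.0))
    # growth modifiers
    growth_sigma: float = 0.1  # lognormal sd of the per-cell growth-rate modifier
    division_asymmetry: float = 0.05  # sd of the daughter volume split around 0.5
    growth_serum_factor: Optional[FactorSpec] = None
    growth_confluence_factor: Optional[FactorSpec] = None
    # vitality
    apo_vitality_rate: float = 1.0 / 180.0  # vitality lost per minute in apoptosis
    damage_recover_prob: float = 0.3
    damage_death_prob: float = 0.5
    damage_prob_time: float = 60.0
    damage_x_ref: float = 0.5
    damage_k: float = 8.0
    drug_sensitivity: Dict[str, float] = field(default_factory=dict)  # molecule -> vitality/min per unit
    protective_genes: Dict[str, str] = field(default_factory=dict)  # molecule -> gene conferring resistance
    # reporters: phase -> synthesis rate; decay per minute
    cdt1_synthesis: Dict[str, float] = field(default_factory=dict)
    cdt1_decay: Dict[str, float] = field(default_factory=dict)
    p27_synthesis: Dict[str, float] = field(default_factory=dict)
    p27_decay: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if abs(self.r_frac + self.p_frac + self.b_frac - 1.0) > 1e-9:
            raise ValueError("r_frac + p_frac + b_frac must equal 1")
        if self.d_ref <= 0:
            raise ValueError("d_ref must be positive")
        for tr in list(self.transitions) + list(self.attach_transitions):
            if tr.from_state == "DEAD":
                raise ValueError("no transitions out of DEAD")
        for rate in self.alpha_growth.values():
            if not math.isfinite(rate):
                raise ValueError("growth rates must be finite")


@dataclass
class CellState:
    """Full dynamic state of one cell agent."""

    id: int
    pos: Tuple[float, float]
    volume: float
    cycle_phase: str = "G1"
    attach_phase: str = "SPREADING"
    age: float = 0.0
    vitality: float = 1.0
    dna_fraction: float = 0.0
    rfd_dna: bool = False
    prev_disp: Tuple[float, float] = (0.0, 0.0)
    genes: Set[str] = field(default_factory=set)
    cdt1: float = 0.0
    p27: float = 0.0
    infection_timer: Optional[float] = None
    damage_level: float = 0.0
    growth_rate_modifier: float = 1.0
    spread_fraction: float = 0.0
    cell_type: str = "cell"
    parent: Optional[int] = None
    origin: str = "start"
    destiny: Optional[str] = None
    birth_time: float = 0.0
    death_time: Optional[float] = None

    @property
    def alive(self) -> bool:
        """Live means neither dead nor already split into daughters."""
        return self.cycle_phase != "DEAD" and self.destiny != "split"

    def radius(self) -> float:
        """Equivalent spherical radius (µm) from the volume."""
        return (3.0 * self.volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class ScalarField:
    """A static concentration lattice over the plate.

    Nodes are spaced ``cell_size`` µm apart, node (0, 0) at the plate
    origin.  Continuous positions are sampled by bilinear interpolation.
    Decay follows the half-life; fields flagged ``degradable_by_cells`` are
    additionally consumed around live cells (self-generated gradients).
    """

    lattice: np.ndarray  # shape (ny, nx), concentrations >= 0
    cell_size: float
    half_life: float = math.inf
    degradable_by_cells: bool = False
    gain: float = 1.0  # chemotactic gain: µm of bias per unit concentration difference

    def __post_init__(self):
        self.lattice = np.asarray(self.lattice, dtype=float)
        if (self.lattice < 0).any():
            raise ValueError("concentrations must be non-negative")

    def covers(self, pos: Tuple[float, float]) -> bool:
        x, y = pos
        ny, nx = self.lattice.shape
        return 0.0 <= x <= (nx - 1) * self.cell_size and 0.0 <= y <= (ny - 1) * self.cell_size

    def sample(self, pos: Tuple[float, float]) -> float:
        """Bilinear interpolation, clamped to the lattice edge."""
        ny, nx = self.lattice.shape
        gx = min(max(pos[0] / self.cell_size, 0.0), nx - 1.0)
        gy = min(max(pos[1] / self.cell_size, 0.0), ny - 1.0)
        i0 = min(int(gx), nx - 2) if nx > 1 else 0
        j0 = min(int(gy), ny - 2) if ny > 1 else 0
        fx = gx - i0
        fy = gy - j0
        lat = self.lattice
        if nx == 1 and ny == 1:
            return float(lat[0, 0])
        if nx == 1:
            return float(lat[j0, 0] * (1 - fy) + lat[j0 + 1, 0] * fy)
        if ny == 1:
            return float(lat[0, i0] * (1 - fx) + lat[0, i0 + 1] * fx)
        return float(
            lat[j0, i0] * (1 - fx) * (1 - fy)
            + lat[j0, i0 + 1] * fx * (1 - fy)
            + lat[j0 + 1, i0] * (1 - fx) * fy
            + lat[j0 + 1, i0 + 1] * fx * fy
        )


class NeighborGrid:
    """Bucket spatial index over cell positions for radius queries."""

    def __init__(self, bucket_size: float):
        if bucket_size <= 0:
            raise ValueError("bucket_size must be positive")
        self.bucket_size = bucket_size
        self._buckets: Dict[Tuple[int, int], List[int]] = {}
        self._pos: Dict[int, Tuple[float, float]] = {}

    def _key(self, pos: Tuple[float, float]) -> Tuple[int, int]:
        return (int(pos[0] // self.bucket_size), int(pos[1] // self.bucket_size))

    def insert(self, cell_id: int, pos: Tuple[float, float]) -> None:
        if cell_id in self._pos:
            raise ValueError(f"cell {cell_id} already indexed")
        self._pos[cell_id] = pos
        self._buckets.setdefault(self._key(pos), []).append(cell_id)

    def build(self, cells: Iterable[CellState]) -> "NeighborGrid":
        for c in cells:
            if c.alive:
                self.insert(c.id, c.pos)
        return self

    def position(self, cell_id: int) -> Tuple[float, float]:
        return self._pos[cell_id]

    def query(self, pos: Tuple[float, float], radius: float,
              exclude: Optional[int] = None) -> List[Tuple[int, float]]:
        """All indexed cells within ``radius`` of ``pos`` as (id, distance)."""
        bs = self.bucket_size
        x, y = pos
        i0 = int((x - radius) // bs)
        i1 = int((x + radius) // bs)
        j0 = int((y - radius) // bs)
        j1 = int((y + radius) // bs)
        out: List[Tuple[int, float]] = []
        r2 = radius * radius
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                for cid in self._buckets.get((i, j), ()):
                    if cid == exclude:
                        continue
                    px, py = self._pos[cid]
                    d2 = (px - x) ** 2 + (py - y) ** 2
                    if d2 <= r2:
                        out.append((cid, math.sqrt(d2)))
        return out

    def __len__(self) -> int:
        return len(self._pos)


@dataclass
class Constraint:
    """Axis-aligned rectangular region blocking or slowing movement.

    ``factor`` 0 blocks entry entirely; 0 < factor < 1 scales displacements
    of cells inside the region.
    """

    x0: float
    y0: float
    x1: float
    y1: float
    factor: float = 0.0
    name: str = "constraint"

    def contains(self, pos: Tuple[float, float]) -> bool:
        return self.x0 <= pos[0] <= self.x1 and self.y0 <= pos[1] <= self.y1


@dataclass
class Medium:
    serum_type: str = "FBS"
    serum_level: float = 10.0  # percent
    molecules: Dict[str, float] = field(default_factory=dict)


@dataclass
class PlateState:
    """The culture plate: geometry, medium, fields, constraints and cells."""

    width: float
    height: float
    cells: List[CellState] = field(default_factory=list)
    medium: Medium = field(default_factory=Medium)
    fields: Dict[str, ScalarField] = field(default_factory=dict)
    constraints: List[Constraint] = field(default_factory=list)
    grid: Optional[NeighborGrid] = None
    time: float = 0.0

    def live_cells(self) -> List[CellState]:
        return [c for c in self.cells if c.alive]

    def rebuild_grid(self, bucket_size: float) -> NeighborGrid:
        self.grid = NeighborGrid(bucket_size).build(self.cells)
        return self.grid

    def clamp(self, pos: Tuple[float, float]) -> Tuple[float, float]:
        return (min(max(pos[0], 0.0), self.width), min(max(pos[1], 0.0), self.height))


def factor_value(factor: FactorSpec, cell: CellState, plate: PlateState,
                 local_confluence: Optional[float] = None) -> float:
    """Read the current value of the quantity a factor responds to."""
    q = factor.quantity
    if q == "serum_level":
        return plate.medium.serum_level
    if q == "volume":
        return cell.volume
    if q == "vitality":
        return cell.vitality
    if q == "local_confluence":
        if local_confluence is None:
            raise ValueError("local_confluence required but not supplied")
        return local_confluence
    if q == "drug_level":
        return plate.medium.molecules.get(factor.target or "", 0.0)
    if q == "attachment_state":
        return cell.spread_fraction
    if q == "gene_presence":
        return 1.0 if (factor.target or "") in cell.genes else 0.0
    raise ValueError(f"unknown quantity {q!r}")  # pragma: no cover


def transition_probability(tr: TransitionSpec, cell: CellState, plate: PlateState,
                           dt: float, local_confluence: Optional[float] = None) -> float:
    """Combined, interval-adapted probability of one transition edge."""
    effects = [f.effect(factor_value(f, cell, plate, local_confluence)) for f in tr.factors]
    p = combine_factor_effects(tr.base_prob, effects)
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    return adapt_probability(p, tr.prob_time, dt)
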