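"""Displacement generation: the three-component motion model and its
condition-aware extension.

Per interval, a cell's displacement is the vector sum of

* a **random** vector — the resultant of a ten-step walk with i.i.d.
  uniform directions, whose step length is calibrated so the *mean*
  resultant length equals the requested module;
* a **persistence** vector along the direction of the previous actual
  displacement;
* a **bias** vector — the cell type's global bias plus any extra bias
  contributed by cell-cell repulsion and attractant gradients.

The moduli derive from the base parameters (r, p, b, d_ref): the maximum
potential displacement d_ref is scaled by a cumulative coefficient k (cycle
phase, attachment state, vitality, local confluence) into d_tot, extra
biases are folded into the bias fraction, and the three fractions are
rescaled to keep their sum at 1 before being multiplied by d_tot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import CellState, CellTypeParams, Constraint, PlateState, ScalarField

__all__ = [
    "RW10_MEAN_RESULTANT",
    "MotionContext",
    "random_walk_vector",
    "compose_displacement",
    "effective_components",
    "repulsion_bias",
    "gradient_bias",
    "apply_constraints",
    "motility_coefficient",
    "step_motion",
]

#: Mean resultant length of a ten-step unit-length uniform-direction walk,
#: computed once by high-precision Monte Carlo.  The step length of the
#: generator is module / RW10_MEAN_RESULTANT so that the *mean* displacement
#: module equals the requested one (the matching convention is used by the
#: component estimator, making round trips consistent in expectation).
RW10_MEAN_RESULTANT = 2.820439

Vec = Tuple[float, float]


@dataclass
class MotionContext:
    """Condition summary consumed by :func:`effective_components`.

    ``k_total`` is the cumulative displacement coefficient (>= 0);
    ``extra_bias`` lists additional bias vectors (µm) with a source label.
    """

    k_total: float = 1.0
    extra_bias: List[Tuple[Vec, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.k_total < 0:
            raise ValueError("k_total must be non-negative")


def random_walk_vector(module: float, rng: np.random.Generator) -> Vec:
    """Resultant of a ten-step uniform-direction walk with mean length ``module``."""
    if module < 0:
        raise ValueError("module must be non-negative")
    if module == 0.0:
        return (0.0, 0.0)
    step = module / RW10_MEAN_RESULTANT
    angles = rng.uniform(0.0, 2.0 * math.pi, 10)
    return (step * float(np.cos(angles).sum()), step * float(np.sin(angles).sum()))


def compose_displacement(rand_vec: Vec, pers_vec: Vec, bias_vec: Vec) -> Vec:
    """Vector sum of the three motion components."""
    return (
        rand_vec[0] + pers_vec[0] + bias_vec[0],
        rand_vec[1] + pers_vec[1] + bias_vec[1],
    )


def effective_components(cell: CellState, params: CellTypeParams,
                         ctx: MotionContext) -> Tuple[float, float, Vec]:
    """Condition-scaled (random, persistence) moduli and the final bias vector.

    ``d_tot = k_total * d_ref``.  The global bias (``b_frac * d_tot`` along
    ``bias_angle``) is vector-summed with every extra bias; the resulting
    module defines a new bias fraction b' = |bias| / d_tot, and r, p are
    rescaled so r' + p' + b' = 1.  If the combined bias exceeds d_tot it is
    capped at module d_tot and the other two components vanish.
    """
    d_tot = ctx.k_total * params.d_ref
    if d_tot <= 0.0:
        return 0.0, 0.0, (0.0, 0.0)
    bx = params.b_frac * d_tot * math.cos(params.bias_angle)
    by = params.b_frac * d_tot * math.sin(params.bias_angle)
    for (vx, vy), _src in ctx.extra_bias:
        bx += vx
        by += vy
    b_mod = math.hypot(bx, by)
    b_new = b_mod / d_tot
    if b_new >= 1.0:
        scale = d_tot / b_mod
        return 0.0, 0.0, (bx * scale, by * scale)
    rp = params.r_frac + params.p_frac
    if rp <= 0.0:
        return 0.0, 0.0, (bx, by)
    r_new = params.r_frac * (1.0 - b_new) / rp
    p_new = params.p_frac * (1.0 - b_new) / rp
    return r_new * d_tot, p_new * d_tot, (bx, by)


def repulsion_bias(cell: CellState, plate: PlateState, params: CellTypeParams,
                   rng: Optional[np.random.Generator] = None) -> Vec:
    """Short-range cell-cell repulsion as an extra bias vector.

    Each neighbour within ``repulsion_radius`` contributes a vector pointing
    away from it with module ``sensitivity * d_ref * (1 - dist / radius)``
    (linear falloff, zero at the radius).  Coincident neighbours push in a
    uniformly random direction (documented tie-break; requires ``rng``).
    """
    if plate.grid is None:
        return (0.0, 0.0)
    radius = params.repulsion_radius
    x, y = cell.pos
    vx = vy = 0.0
    for nid, dist in plate.grid.query(cell.pos, radius, exclude=cell.id):
        amp = params.repulsion_sensitivity * params.d_ref * (1.0 - dist / radius)
        if dist <= 1e-12:
            theta = rng.uniform(0.0, 2.0 * math.pi) if rng is not None else 0.0
            ux, uy = math.cos(theta), math.sin(theta)
        else:
            nx, ny = plate.grid.position(nid)
            ux, uy = (x - nx) / dist, (y - ny) / dist
        vx += amp * ux
        vy += amp * uy
    return (vx, vy)


def gradient_bias(cell: CellState, fld: ScalarField, params: CellTypeParams,
                  cap: Optional[float] = None) -> Vec:
    """Bias from the attractant difference across the cell body.

    Samples the field half a sensing distance ahead and behind the cell
    along each axis; the bias is the finite-difference gradient times the
    field's chemotactic gain, capped at ``cap`` µm (if given) so sharp
    fields cannot teleport a cell in one step.  Cells outside the field feel
    nothing.
    """
    if not fld.covers(cell.pos):
        return (0.0, 0.0)
    h = params.sensing_distance / 2.0
    x, y = cell.pos
    dx = fld.sample((x + h, y)) - fld.sample((x - h, y))
    dy = fld.sample((x, y + h)) - fld.sample((x, y - h))
    vx, vy = fld.gain * dx, fld.gain * dy
    if cap is not None:
        mod = math.hypot(vx, vy)
        if mod > cap > 0.0:
            s = cap / mod
            vx, vy = vx * s, vy * s
    return (vx, vy)


def _segment_entry_t(pos: Vec, disp: Vec, rect: Constraint) -> Optional[float]:
    """Earliest t in (0, 1] at which pos + t*disp enters the rectangle."""
    t0, t1 = 0.0, 1.0
    for p, d, lo, hi in (
        (pos[0], disp[0], rect.x0, rect.x1),
        (pos[1], disp[1], rect.y0, rect.y1),
    ):
        if abs(d) < 1e-15:
            if p < lo or p > hi:
                return None
            continue
        ta, tb = (lo - p) / d, (hi - p) / d
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return None
    return t0 if t0 > 0.0 else (0.0 if rect.contains(pos) else None)


def apply_constraints(pos: Vec, disp: Vec, plate: PlateState) -> Vec:
    """Truncate a displacement at plate edges and blocking regions.

    Movement stops at the first wall hit (no reflection); slowing regions
    scale the displacement of cells currently inside them by their factor.
    """
    dx, dy = disp
    for c in plate.constraints:
        if 0.0 < c.factor < 1.0 and c.contains(pos):
            dx, dy = dx * c.factor, dy * c.factor

    t_stop = 1.0
    for c in plate.constraints:
        if c.factor != 0.0 or c.contains(pos):
            continue
        t = _segment_entry_t(pos, (dx, dy), c)
        if t is not None and t < t_stop:
            t_stop = max(0.0, t - 1e-9)
    x = pos[0] + t_stop * dx
    y = pos[1] + t_stop * dy
    # plate edges: stop at the wall
    x = min(max(x, 0.0), plate.width)
    y = min(max(y, 0.0), plate.height)
    return (x, y)


def motility_coefficient(cell: CellState, params: CellTypeParams, plate: PlateState,
                         local_confluence: Optional[float] = None) -> float:
    """Cumulative displacement coefficient k for one cell.

    Product of per-phase and per-attachment multipliers, the vitality, and
    optional logistic effects of local confluence and serum level.
    """
    k = params.phase_motility.get(cell.cycle_phase, 1.0)
    k *= params.attach_motility.get(cell.attach_phase, 1.0)
    k *= cell.vitality
    if params.confluence_motility is not None and local_confluence is not None:
        k *= params.confluence_motility.effect(local_confluence)
    if params.serum_motility is not None:
        k *= params.serum_motility.effect(plate.medium.serum_level)
    return k


def step_motion(cell: CellState, plate: PlateState, params: CellTypeParams,
                dt: float, rng: np.random.Generator,
                local_confluence: Optional[float] = None) -> None:
    """Generate and apply one displacement for one cell.

    Builds the motion context (k from conditions, extra bias from repulsion
    and every attractant field), computes the effective components, draws
    the random-walk vector, composes, applies constraints, and updates
    position and previous displacement (the *actual*, post-constraint one).
    """
    if not cell.alive or cell.cycle_phase == "DAMAGED" and cell.damage_level >= 1.0:
        return
    k = motility_coefficient(cell, params, plate, local_confluence)
    k *= dt / params.ref_interval  # moduli are stated per reference interval
    ctx = MotionContext(k_total=k)
    rep = repulsion_bias(cell, plate, params, rng)
    if rep != (0.0, 0.0):
        ctx.extra_bias.append((rep, "repulsion"))
    d_tot_cap = k * params.d_ref
    for name, fld in plate.fields.items():
        g = gradient_bias(cell, fld, params, cap=d_tot_cap if d_tot_cap > 0 else None)
        if g != (0.0, 0.0):
            ctx.extra_bias.append((g, name))

    rand_mod, pers_mod, bias_vec = effective_components(cell, params, ctx)
    rand_vec = random_walk_vector(rand_mod, rng)
    px, py = cell.prev_disp
    pmod = math.hypot(px, py)
    if pers_mod > 0.0 and pmod > 1e-12:
        pers_vec = (pers_mod * px / pmod, pers_mod * py / pmod)
    else:
        pers_vec = (0.0, 0.0)
    disp = compose_displacement(rand_vec, pers_vec, bias_vec)
    new_pos = apply_constraints(cell.pos, disp, plate)
    cell.prev_disp = (new_pos[0] - cell.pos[0], new_pos[1] - cell.pos[1])
    cell.pos = new_pos
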