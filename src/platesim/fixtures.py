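"""Synthetic fixtures with known ground truth, plus the standalone
three-component track generator.

``simulate_tracks`` produces displacement sequences exactly as the motion
model defines them (ten-step random walk resultant + persistence along the
previous displacement + a fixed bias vector) without any plate machinery,
which makes it the reference input for estimator round-trip checks.

``make_fixture`` provides analytic path families (straight lines, Brownian
walks, integrated Ornstein-Uhlenbeck persistent walks with closed-form
persistent-random-walk MSD) and two plate layouts (confluent layer, sparse
seeding).
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np

from .analysis import TrackSet
from .core import CellState, PlateState
from .motility import RW10_MEAN_RESULTANT

__all__ = ["simulate_tracks", "make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("straight_paths", "brownian_paths", "ou_persistent_paths",
                 "confluent_layer", "sparse_seeding")


def simulate_tracks(n_cells: int, n_frames: int, rand: float, pers: float,
                    bias: float, bias_angle: float = 0.0, interval: float = 20.0,
                    seed: int = 0) -> TrackSet:
    """Generate paths from the three-component model with fixed moduli.

    Each displacement is ``r_t + pers * unit(d_{t-1}) + bias_vec`` where
    ``r_t`` is a ten-step random-walk resultant with mean length ``rand``;
    the first displacement of every path has zero persistence.
    """
    rng = np.random.default_rng(seed)
    bias_vec = np.array([bias * math.cos(bias_angle), bias * math.sin(bias_angle)])
    step = rand / RW10_MEAN_RESULTANT if rand > 0 else 0.0
    cells = {}
    times = np.arange(n_frames, dtype=float) * interval
    for cid in range(1, n_cells + 1):
        xy = np.zeros((n_frames, 2))
        prev = np.zeros(2)
        for i in range(1, n_frames):
            if step > 0:
                ang = rng.uniform(0.0, 2.0 * math.pi, 10)
                r_vec = step * np.array([np.cos(ang).sum(), np.sin(ang).sum()])
            else:
                r_vec = np.zeros(2)
            pmod = math.hypot(*prev)
            p_vec = pers * prev / pmod if (pers > 0 and pmod > 1e-12) else np.zeros(2)
            d = r_vec + p_vec + bias_vec
            xy[i] = xy[i - 1] + d
            prev = d
        cells[cid] = (times, xy, "start", None)
    return TrackSet(cells=cells, interval=interval)


def _straight_paths(params: Dict, rng: np.random.Generator) -> TrackSet:
    n_cells = params.get("n_cells", 10)
    n_frames = params.get("n_frames", 20)
    speed = params.get("speed", 0.5)  # µm/min
    interval = params.get("interval", 20.0)
    times = np.arange(n_frames, dtype=float) * interval
    cells = {}
    for cid in range(1, n_cells + 1):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        step = speed * interval * np.array([math.cos(theta), math.sin(theta)])
        xy = np.outer(np.arange(n_frames), step)
        cells[cid] = (times, xy, "start", None)
    return TrackSet(cells=cells, interval=interval)


def _brownian_paths(params: Dict, rng: np.random.Generator) -> TrackSet:
    n_cells = params.get("n_cells", 50)
    n_frames = params.get("n_frames", 72)
    sigma = params.get("sigma", 5.0)  # per-axis step sd, µm
    interval = params.get("interval", 20.0)
    times = np.arange(n_frames, dtype=float) * interval
    cells = {}
    for cid in range(1, n_cells + 1):
        steps = rng.normal(0.0, sigma, (n_frames - 1, 2))
        xy = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        cells[cid] = (times, xy, "start", None)
    return TrackSet(cells=cells, interval=interval)


def _ou_persistent_paths(params: Dict, rng: np.random.Generator) -> TrackSet:
    """Integrated Ornstein-Uhlenbeck paths with exact discretization.

    The velocity is a stationary OU process with correlation time P and
    root-mean-squared speed S, so the ensemble MSD follows the
    persistent-random-walk law MSD(t) = 2 S^2 P [t - P (1 - exp(-t/P))]
    exactly at all lags.
    """
    n_cells = params.get("n_cells", 100)
    n_frames = params.get("n_frames", 60)
    speed = params.get("speed", 1.0)  # S, µm/min (rms over both axes)
    P = params.get("persistence_time", 30.0)  # minutes
    interval = params.get("interval", 5.0)
    sigma_v2 = speed ** 2 / 2.0  # per-axis stationary velocity variance
    lam = 1.0 / P
    a = math.exp(-lam * interval)
    # exact joint covariance of (position increment, velocity innovation)
    var_x = sigma_v2 / lam ** 2 * (2 * lam * interval - 3.0 + 4.0 * a - a * a)
    var_v = sigma_v2 * (1.0 - a * a)
    cov_xv = sigma_v2 / lam * (1.0 - a) ** 2
    cov = np.array([[var_x, cov_xv], [cov_xv, var_v]])
    L = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
    times = np.arange(n_frames, dtype=float) * interval
    cells = {}
    for cid in range(1, n_cells + 1):
        v = rng.normal(0.0, math.sqrt(sigma_v2), 2)  # stationary start
        xy = np.zeros((n_frames, 2))
        for i in range(1, n_frames):
            z = rng.standard_normal((2, 2))  # one (dx, dv) pair per axis
            noise = z @ L.T
            dx = v / lam * (1.0 - a) + noise[:, 0]
            v = a * v + noise[:, 1]
            xy[i] = xy[i - 1] + dx
        cells[cid] = (times, xy, "start", None)
    return TrackSet(cells=cells, interval=interval)


def _layer_positions(width: float, height: float, spacing: float):
    out = []
    x = spacing / 2.0
    while x < width:
        y = spacing / 2.0
        while y < height:
            out.append((x, y))
            y += spacing
        x += spacing
    return out


def _confluent_layer(params: Dict, rng: np.random.Generator) -> PlateState:
    width = params.get("width", 600.0)
    height = params.get("height", 600.0)
    spacing = params.get("spacing", 30.0)
    plate = PlateState(width=width, height=height)
    for i, pos in enumerate(_layer_positions(width, height, spacing), start=1):
        plate.cells.append(CellState(
            id=i, pos=pos, volume=params.get("volume", 1400.0),
            attach_phase="SPREAD", spread_fraction=1.0,
        ))
    return plate


def _sparse_seeding(params: Dict, rng: np.random.Generator) -> PlateState:
    width = params.get("width", 1000.0)
    height = params.get("height", 1000.0)
    n = params.get("n_cells", 20)
    plate = PlateState(width=width, height=height)
    for i in range(1, n + 1):
        plate.cells.append(CellState(
            id=i, pos=(rng.uniform(0, width), rng.uniform(0, height)),
            volume=params.get("volume", 1400.0),
            attach_phase="SPREAD", spread_fraction=1.0,
        ))
    return plate


def make_fixture(kind: str, params: Optional[Dict] = None, seed: int = 0):
    """Analytic fixtures with known ground truth for estimator/fit tests."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choices: {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    params = dict(params or {})
    return {
        "straight_paths": _straight_paths,
        "brownian_paths": _brownian_paths,
        "ou_persistent_paths": _ou_persistent_paths,
        "confluent_layer": _confluent_layer,
        "sparse_seeding": _sparse_seeding,
    }[kind](params, rng)
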