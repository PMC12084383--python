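"""Movement statistics for simulated or experimental track sets.

The suite covers the standard descriptors used to validate simulated
populations against time-lapse experiments: the three-component
decomposition (random / persistence / bias moduli), MSD curves with
power-law (anomalous diffusion exponent) and Fürth (persistence time) fits,
linearity, coherence, circular statistics, per-window component
contributions, and 2-D displacement kernel densities.

Component estimation
--------------------
Displacements are modelled as ``d_t = b + p * u_{t-1} + r_t`` where ``b``
is the bias vector, ``u_{t-1}`` the unit vector of the previous
displacement, ``p`` the persistence module and ``r_t`` an isotropic random
vector.  Because ``r_t`` is independent of the regressors, ordinary least
squares on ``(1, u_{t-1})`` recovers ``b`` and ``p`` consistently; the
random module is the mean residual length, matching the generator's
mean-resultant calibration so that generation -> estimation round trips are
consistent in expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .motility import RW10_MEAN_RESULTANT

__all__ = [
    "TrackSet",
    "ComponentEstimate",
    "PowerLawFit",
    "FurthFit",
    "MotionSummary",
    "estimate_components",
    "msd_curve",
    "fit_alpha",
    "fit_persistence",
    "linearity",
    "coherence",
    "circular_R",
    "component_contributions",
    "displacement_density",
    "summarize",
]

ORIGIN_LABELS = ("start", "newborn", "found", "gone in")
DESTINY_LABELS = ("split", "dead", "lost", "gone out")


@dataclass
class TrackSet:
    """Per-cell time-stamped paths.

    ``cells`` maps cell id to ``(times, xy, origin, destiny)`` where
    ``times`` is a strictly increasing 1-D array (minutes) and ``xy`` an
    ``(n, 2)`` array in µm.  ``destiny`` may be None for paths censored at
    the end of the observation.
    """

    cells: Dict[int, Tuple[np.ndarray, np.ndarray, str, Optional[str]]]
    interval: float

    def __post_init__(self):
        for cid, (t, xy, origin, destiny) in self.cells.items():
            t = np.asarray(t, dtype=float)
            xy = np.asarray(xy, dtype=float)
            if t.ndim != 1 or xy.shape != (t.size, 2):
                raise ValueError(f"track {cid}: shapes inconsistent")
            if t.size >= 2 and not (np.diff(t) > 0).all():
                raise ValueError(f"track {cid}: times must be strictly increasing")
            if origin not in ORIGIN_LABELS:
                raise ValueError(f"track {cid}: unknown origin {origin!r}")
            if destiny is not None and destiny not in DESTINY_LABELS:
                raise ValueError(f"track {cid}: unknown destiny {destiny!r}")
            self.cells[cid] = (t, xy, origin, destiny)

    def __len__(self) -> int:
        return len(self.cells)

    def displacements(self) -> List[np.ndarray]:
        """Per-cell arrays of consecutive frame-to-frame displacement vectors."""
        return [np.diff(xy, axis=0) for _t, xy, _o, _d in self.cells.values()
                if xy.shape[0] >= 2]

    def window(self, t0: float, t1: float) -> "TrackSet":
        """Sub-trackset restricted to frames with t0 <= time <= t1."""
        out = {}
        for cid, (t, xy, origin, destiny) in self.cells.items():
            m = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
            if m.sum() >= 2:
                out[cid] = (t[m], xy[m], origin, destiny)
        return TrackSet(cells=out, interval=self.interval)


@dataclass
class ComponentEstimate:
    """Three-component decomposition of a population's displacements."""

    rand_module: float
    pers_module: float
    bias_module: float
    bias_angle: float
    n_displacements: int = 0

    def __iter__(self):
        return iter((self.rand_module, self.pers_module, self.bias_module, self.bias_angle))


def _pairs(tracks: TrackSet) -> Tuple[np.ndarray, np.ndarray]:
    """All displacements with the unit vector of their predecessor.

    The first displacement of each path carries zero persistence, encoded
    as a zero predecessor direction.
    """
    ds: List[np.ndarray] = []
    us: List[np.ndarray] = []
    for d in tracks.displacements():
        n = d.shape[0]
        u = np.zeros_like(d)
        if n >= 2:
            mod = np.hypot(d[:-1, 0], d[:-1, 1])
            nz = mod > 1e-12
            u[1:][nz] = d[:-1][nz] / mod[nz, None]
        ds.append(d)
        us.append(u)
    if not ds:
        raise ValueError("track set contains no displacements")
    return np.concatenate(ds), np.concatenate(us)


def estimate_components(tracks: TrackSet) -> ComponentEstimate:
    """Estimate random, persistence and bias moduli from a track set."""
    d, u = _pairs(tracks)
    n = d.shape[0]
    # stacked regression: [d_x; d_y] on [1,0,u_x; 0,1,u_y]
    X = np.zeros((2 * n, 3))
    X[0::2, 0] = 1.0
    X[1::2, 1] = 1.0
    X[0::2, 2] = u[:, 0]
    X[1::2, 2] = u[:, 1]
    y = d.reshape(-1)
    beta, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        # degenerate design (e.g. identical directions throughout):
        # attribute everything to bias, persistence unidentifiable -> 0
        b = d.mean(axis=0)
        p = 0.0
    else:
        b = beta[:2]
        p = max(0.0, float(beta[2]))
    resid = d - b[None, :] - p * u
    rand = float(np.hypot(resid[:, 0], resid[:, 1]).mean())
    return ComponentEstimate(
        rand_module=rand,
        pers_module=p,
        bias_module=float(np.hypot(*b)),
        bias_angle=float(math.atan2(b[1], b[0])),
        n_displacements=n,
    )


def msd_curve(tracks: TrackSet) -> pd.DataFrame:
    """Mean squared displacement vs lag, averaged over all start frames.

    Overlapping windows: for every cell and every lag of ``j`` frames, all
    ``n - j`` squared displacements enter the average.  Returns columns
    ``lag`` (minutes), ``msd`` (µm²) and ``n_pairs``.
    """
    sums: Dict[int, float] = {}
    counts: Dict[int, int] = {}
    for _t, xy, _o, _dst in tracks.cells.values():
        n = xy.shape[0]
        for j in range(1, n):
            diff = xy[j:] - xy[:-j]
            sq = (diff ** 2).sum(axis=1)
            sums[j] = sums.get(j, 0.0) + float(sq.sum())
            counts[j] = counts.get(j, 0) + sq.size
    if not sums:
        raise ValueError("need at least one track with two points")
    lags = sorted(sums)
    return pd.DataFrame({
        "lag": [j * tracks.interval for j in lags],
        "msd": [sums[j] / counts[j] for j in lags],
        "n_pairs": [counts[j] for j in lags],
    })


@dataclass
class PowerLawFit:
    """Result of the anomalous-diffusion fit MSD = k * t**alpha."""

    k: float
    alpha: float
    cov: Optional[np.ndarray] = None

    def __iter__(self):
        return iter((self.k, self.alpha))


def fit_alpha(msd_series: pd.DataFrame) -> PowerLawFit:
    """Weighted nonlinear fit of MSD = k * t**alpha (weights = pair counts)."""
    t = msd_series["lag"].to_numpy(float)
    m = msd_series["msd"].to_numpy(float)
    w = msd_series["n_pairs"].to_numpy(float)
    if t.size < 3:
        raise ValueError("need at least 3 lags to fit the power law")
    pos = m > 0
    if pos.sum() >= 2:
        a0, logk0 = np.polyfit(np.log(t[pos]), np.log(m[pos]), 1)
        p0 = (math.exp(logk0), float(np.clip(a0, 0.1, 2.5)))
    else:
        p0 = (1.0, 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            lambda tt, k, a: k * tt ** a, t, m, p0=p0,
            sigma=1.0 / np.sqrt(w), absolute_sigma=False, maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"power-law fit did not converge: {exc}") from exc
    return PowerLawFit(k=float(popt[0]), alpha=float(popt[1]), cov=pcov)


@dataclass
class FurthFit:
    """Result of the persistent-random-walk MSD fit.

    ``speed`` is the root-mean-squared speed S (µm/min) and
    ``persistence_time`` the directional persistence time P (minutes) of
    MSD(t) = 2 S² P [t - P (1 - exp(-t/P))].  ``at_bound`` flags fits that
    ended on the parameter bounds.
    """

    speed: float
    persistence_time: float
    cov: Optional[np.ndarray] = None
    at_bound: bool = False

    def __iter__(self):
        return iter((self.speed, self.persistence_time))


def furth_msd(t: np.ndarray, speed: float, persistence_time: float) -> np.ndarray:
    """Fürth persistent-random-walk MSD model."""
    t = np.asarray(t, dtype=float)
    P = persistence_time
    return 2.0 * speed ** 2 * P * (t - P * (1.0 - np.exp(-t / P)))


def fit_persistence(msd_series: pd.DataFrame) -> FurthFit:
    """Weighted Fürth fit returning (S, P)."""
    t = msd_series["lag"].to_numpy(float)
    m = msd_series["msd"].to_numpy(float)
    w = msd_series["n_pairs"].to_numpy(float)
    if t.size < 4:
        raise ValueError("need at least 4 lags to fit the Fürth model")
    # initial guesses: diffusive slope for 2 S^2 P, persistence ~ one frame
    slope = max(m[-1] / t[-1], 1e-12)
    P0 = max(t[0] / 2.0, 1.0)
    S0 = math.sqrt(slope / (2.0 * P0))
    lo, hi = [1e-9, 1e-3], [np.inf, 1e7]
    try:
        popt, pcov = optimize.curve_fit(
            furth_msd, t, m, p0=(S0, P0), sigma=1.0 / np.sqrt(w),
            bounds=(lo, hi), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Fürth fit did not converge: {exc}") from exc
    at_bound = bool(popt[1] <= lo[1] * 1.01 or popt[1] >= hi[1] * 0.99)
    return FurthFit(speed=float(popt[0]), persistence_time=float(popt[1]),
                    cov=pcov, at_bound=at_bound)


def linearity(tracks: TrackSet) -> float:
    """Population mean of per-cell net-displacement / path-length ratios."""
    vals = []
    for _t, xy, _o, _d in tracks.cells.values():
        if xy.shape[0] < 2:
            continue
        steps = np.diff(xy, axis=0)
        length = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
        if length <= 0:
            warnings.warn("zero-length path excluded from linearity")
            continue
        net = float(np.hypot(*(xy[-1] - xy[0])))
        vals.append(net / length)
    if not vals:
        raise ValueError("no usable paths for linearity")
    return float(np.mean(vals))


def coherence(tracks: TrackSet) -> float:
    """|sum of net displacement vectors| / sum of their lengths."""
    nets = []
    for _t, xy, _o, _d in tracks.cells.values():
        if xy.shape[0] >= 2:
            nets.append(xy[-1] - xy[0])
    if not nets:
        raise ValueError("no paths with net displacement")
    nets_arr = np.asarray(nets)
    denom = float(np.hypot(nets_arr[:, 0], nets_arr[:, 1]).sum())
    if denom <= 0:
        raise ValueError("all net displacements are zero; coherence undefined")
    num = float(np.hypot(*nets_arr.sum(axis=0)))
    return num / denom


def circular_R(displacements: Iterable[Sequence[float]]) -> Tuple[float, float]:
    """Mean angle and linear dispersion coefficient R of displacement directions.

    Directions enter as unit vectors (moduli are ignored); R is the length
    of their mean, 0 for uniform angles and 1 when all angles coincide.
    """
    d = np.asarray(list(displacements), dtype=float)
    if d.ndim != 2 or d.shape[1] != 2:
        raise ValueError("expected an iterable of 2-D vectors")
    mod = np.hypot(d[:, 0], d[:, 1])
    nz = mod > 1e-12
    if not nz.any():
        raise ValueError("need at least one nonzero displacement")
    u = d[nz] / mod[nz, None]
    mean = u.mean(axis=0)
    return float(math.atan2(mean[1], mean[0])), float(np.hypot(*mean))


def component_contributions(tracks: TrackSet, window: float,
                            stride: Optional[float] = None) -> pd.DataFrame:
    """Scalar contributions of the three components over sliding windows.

    For each overlapping window the components are re-estimated, every
    realized component vector is projected onto its displacement direction,
    and the projections are averaged; the three contributions sum to the
    mean displacement module within the window.  Columns: ``t_mid``,
    ``random``, ``persistence``, ``bias``, ``displacement``.
    """
    if window < 2 * tracks.interval:
        raise ValueError("window must span at least two intervals")
    if stride is None:
        stride = tracks.interval
    t_min = min(t[0] for t, *_ in tracks.cells.values())
    t_max = max(t[-1] for t, *_ in tracks.cells.values())
    rows = []
    t0 = t_min
    while t0 + window <= t_max + 1e-9:
        sub = tracks.window(t0, t0 + window)
        if len(sub) > 0:
            est = estimate_components(sub)
            d, u = _pairs(sub)
            mod = np.hypot(d[:, 0], d[:, 1])
            nz = mod > 1e-12
            dn = d[nz] / mod[nz, None]
            b = est.bias_module * np.array([math.cos(est.bias_angle), math.sin(est.bias_angle)])
            pers_vec = est.pers_module * u[nz]
            rand_vec = d[nz] - b[None, :] - pers_vec
            rows.append({
                "t_mid": t0 + window / 2.0,
                "random": float((rand_vec * dn).sum(axis=1).mean()),
                "persistence": float((pers_vec * dn).sum(axis=1).mean()),
                "bias": float((dn @ b).mean()),
                "displacement": float(mod[nz].mean()),
            })
        t0 += stride
    return pd.DataFrame(rows, columns=["t_mid", "random", "persistence", "bias", "displacement"])


@dataclass
class DensityMap:
    """2-D kernel density of displacement endpoints relative to the origin."""

    x: np.ndarray  # grid x coordinates
    y: np.ndarray  # grid y coordinates
    density: np.ndarray  # shape (ny, nx), integrates to ~1 over the grid

    def mode(self) -> Tuple[float, float]:
        j, i = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.x[i]), float(self.y[j])

    def integral(self) -> float:
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.density.sum() * dx * dy)


def displacement_density(tracks: TrackSet, lag: float, grid: int = 25,
                         pad: float = 0.15) -> DensityMap:
    """Gaussian-kernel density of shifts over the given lag (minutes)."""
    j = max(1, int(round(lag / tracks.interval)))
    shifts = []
    for _t, xy, _o, _d in tracks.cells.values():
        if xy.shape[0] > j:
            shifts.append(xy[j:] - xy[:-j])
    if not shifts:
        raise ValueError("no shifts available at this lag")
    s = np.concatenate(shifts)
    if s.shape[0] < 10:
        raise ValueError("need at least 10 shifts for a density estimate")
    kde = stats.gaussian_kde(s.T)  # normal-reference (Scott) bandwidth
    lo = s.min(axis=0)
    hi = s.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    lo -= pad * span
    hi += pad * span
    gx = np.linspace(lo[0], hi[0], grid)
    gy = np.linspace(lo[1], hi[1], grid)
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid, grid)
    return DensityMap(x=gx, y=gy, density=dens)


@dataclass
class MotionSummary:
    """The standard per-population movement statistics table."""

    rand_module: float
    pers_module: float
    bias_module: float
    bias_angle: float
    mean_displacement: float
    msd_final: float
    rmsd_final: float
    alpha: float
    k_msd: float
    persistence_time: float
    rms_speed: float
    linearity: float
    coherence: float
    R: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def rmsd_at(rand_module: float, lag: float, interval: float) -> float:
    """MSD a pure random walker with the given module would show at ``lag``.

    The random component is the resultant of a ten-step walk with mean
    length ``rand_module``; its per-step second moment is
    ``10 * (rand_module / c)**2`` with ``c`` the ten-step mean resultant
    constant, and MSD grows linearly with the number of steps.
    """
    steps = lag / interval
    return steps * 10.0 * (rand_module / RW10_MEAN_RESULTANT) ** 2


def summarize(tracks: TrackSet, msd_report_lag: Optional[float] = None,
              normalise: bool = False) -> MotionSummary:
    """Compute the full movement-statistics summary for a track set.

    ``msd_report_lag`` is the lag (minutes) at which MSD and rMSD are
    reported (default: two frame intervals, i.e. 40 min at a 20-min frame
    rate).  With ``normalise=True`` the persistence and bias moduli are
    reported relative to the random module.
    """
    est = estimate_components(tracks)
    msd = msd_curve(tracks)
    power = fit_alpha(msd)
    furth = fit_persistence(msd)
    disp = np.concatenate(tracks.displacements())
    mods = np.hypot(disp[:, 0], disp[:, 1])
    lag = msd_report_lag if msd_report_lag is not None else 2.0 * tracks.interval
    idx = int(np.argmin(np.abs(msd["lag"].to_numpy() - lag)))
    pers, bias = est.pers_module, est.bias_module
    if normalise and est.rand_module > 0:
        pers, bias = pers / est.rand_module, bias / est.rand_module
    return MotionSummary(
        rand_module=est.rand_module,
        pers_module=pers,
        bias_module=bias,
        bias_angle=est.bias_angle,
        mean_displacement=float(mods.mean()),
        msd_final=float(msd["msd"].iloc[idx]),
        rmsd_final=rmsd_at(est.rand_module, float(msd["lag"].iloc[idx]), tracks.interval),
        alpha=power.alpha,
        k_msd=power.k,
        persistence_time=furth.persistence_time,
        rms_speed=float(np.sqrt((mods ** 2).mean()) / tracks.interval),
        linearity=linearity(tracks),
        coherence=coherence(tracks),
        R=circular_R(disp)[1],
    )
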