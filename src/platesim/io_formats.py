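"""Readers and writers: track files, setup configs, and the symbolic SVG
frame renderer.

Track file dialect (plain text, one file per population)::

    # platesim tracks v1
    interval_min 20
    pixel_scale none
    cell 1 origin=start destiny=split
    0 12.500 30.500
    20 14.100 29.000
    end
    cell 2 origin=newborn
    ...

Header lines give the frame interval (minutes) and an optional pixel scale
(pixel/µm); when a scale is present the coordinate rows are in pixels and
are divided by the scale on import.  Cell blocks hold ``time x y`` rows in
strictly increasing time order, with origin in {start, newborn, found,
gone in} and destiny (optional: censored paths omit it) in {split, dead,
lost, gone out}.  Comment lines start with ``#``.  Malformed input is
rejected with the offending line number, never silently repaired.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from .analysis import DESTINY_LABELS, ORIGIN_LABELS, TrackSet
from .attachment import projected_surface
from .core import CellTypeParams, PlateState
from .events import EVENT_KINDS

__all__ = ["read_tracks", "write_tracks", "load_config", "validate_config",
           "render_frame"]


class TrackFormatError(ValueError):
    pass


def read_tracks(path) -> TrackSet:
    """Parse a track file into a :class:`TrackSet`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    interval: Optional[float] = None
    scale: Optional[float] = None
    cells: Dict[int, tuple] = {}
    cur_id: Optional[int] = None
    cur_origin = cur_destiny = None
    cur_rows: List[tuple] = []

    def fail(lineno: int, msg: str):
        raise TrackFormatError(f"{path.name}:{lineno}: {msg}")

    def close_cell(lineno: int):
        nonlocal cur_id, cur_rows
        if cur_id is None:
            return
        if len(cur_rows) < 1:
            fail(lineno, f"cell {cur_id} has no coordinate rows")
        t = np.array([r[0] for r in cur_rows], dtype=float)
        xy = np.array([[r[1], r[2]] for r in cur_rows], dtype=float)
        if t.size >= 2 and not (np.diff(t) > 0).all():
            fail(lineno, f"cell {cur_id}: times must be strictly increasing")
        if scale is not None:
            xy = xy / scale
        cells[cur_id] = (t, xy, cur_origin, cur_destiny)
        cur_id, cur_rows = None, []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "interval_min":
            try:
                interval = float(parts[1])
            except (IndexError, ValueError):
                fail(lineno, "malformed interval_min line")
        elif parts[0] == "pixel_scale":
            if len(parts) < 2:
                fail(lineno, "malformed pixel_scale line")
            if parts[1] != "none":
                try:
                    scale = float(parts[1])
                except ValueError:
                    fail(lineno, "malformed pixel_scale value")
                if scale <= 0:
                    fail(lineno, "pixel_scale must be positive")
        elif parts[0] == "cell":
            if cur_id is not None:
                fail(lineno, "new cell block before 'end'")
            try:
                cur_id = int(parts[1])
            except (IndexError, ValueError):
                fail(lineno, "malformed cell header")
            cur_origin, cur_destiny = "start", None
            for kv in parts[2:]:
                if "=" not in kv:
                    fail(lineno, f"malformed cell attribute {kv!r}")
                k, v = kv.split("=", 1)
                v = v.replace("_", " ")
                if k == "origin":
                    if v not in ORIGIN_LABELS:
                        fail(lineno, f"unknown origin {v!r}")
                    cur_origin = v
                elif k == "destiny":
                    if v not in DESTINY_LABELS:
                        fail(lineno, f"unknown destiny {v!r}")
                    cur_destiny = v
                else:
                    fail(lineno, f"unknown cell attribute {k!r}")
            cur_rows = []
        elif parts[0] == "end":
            close_cell(lineno)
        else:
            if cur_id is None:
                fail(lineno, f"unexpected line outside a cell block: {line!r}")
            if len(parts) != 3:
                fail(lineno, f"expected 'time x y', got {line!r}")
            try:
                cur_rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError:
                fail(lineno, f"non-numeric coordinate row: {line!r}")
    if cur_id is not None:
        raise TrackFormatError(f"{path.name}: unterminated cell block {cur_id}")
    if interval is None:
        raise TrackFormatError(f"{path.name}: missing interval_min header")
    if not cells:
        raise TrackFormatError(f"{path.name}: no cell tracks found")
    return TrackSet(cells=cells, interval=interval)


def write_tracks(tracks: TrackSet, path) -> None:
    """Serialize a track set deterministically (sorted ids, fixed precision)."""
    path = Path(path)
    out = ["# platesim tracks v1", f"interval_min {tracks.interval:g}", "pixel_scale none"]
    for cid in sorted(tracks.cells):
        t, xy, origin, destiny = tracks.cells[cid]
        header = f"cell {cid} origin={origin.replace(' ', '_')}"
        if destiny is not None:
            header += f" destiny={destiny.replace(' ', '_')}"
        out.append(header)
        for ti, (x, y) in zip(t, xy):
            out.append(f"{ti:g} {x:.3f} {y:.3f}")
        out.append("end")
    path.write_text("\n".join(out) + "\n")


def load_config(path) -> Dict:
    """Load a setup config from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def validate_config(config: Dict) -> List[str]:
    """Validate a setup config; returns a list of problems (empty if valid)."""
    problems: List[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    plate = config.get("plate", {})
    for dim in ("width", "height"):
        v = plate.get(dim)
        if v is not None and (not isinstance(v, (int, float)) or v <= 0):
            problems.append(f"plate.{dim} must be a positive number")
    run = config.get("run", {})
    duration = run.get("duration_min", 1440.0)
    interval = run.get("interval_min", 20.0)
    if not isinstance(duration, (int, float)) or duration <= 0:
        problems.append("run.duration_min must be positive")
    if not isinstance(interval, (int, float)) or interval <= 0:
        problems.append("run.interval_min must be positive")
    for i, seeding in enumerate(config.get("seeding", [])):
        if "count" not in seeding and "positions" not in seeding:
            problems.append(f"seeding[{i}] needs 'count' or 'positions'")
    for i, ev in enumerate(config.get("events", [])):
        kind = ev.get("kind")
        if kind not in EVENT_KINDS:
            problems.append(f"events[{i}]: unknown kind {kind!r}")
        t = ev.get("time")
        if not isinstance(t, (int, float)) or t < 0:
            problems.append(f"events[{i}]: time must be a non-negative number")
        elif isinstance(duration, (int, float)) and t > duration:
            problems.append(f"events[{i}]: time {t} outside run duration {duration}")
    try:
        from .scenarios import params_from_config

        params_from_config(config)
    except Exception as exc:  # surface parameter errors as validation problems
        problems.append(f"cell_types: {exc}")
    return problems


# grey-level styling per attachment/cycle condition, phase-contrast inspired
_STYLES = {
    "SPREAD": ("#d9d9d9", "#9a9a9a", 1.0),
    "SPREADING": ("#cfcfcf", "#8a8a8a", 1.5),
    "ATTACHED": ("#c4c4c4", "#7a7a7a", 2.0),
    "DETACHED": ("#bbbbbb", "#6a6a6a", 2.5),
    "DESPREADING": ("#eeeeee", "#fafafa", 3.0),
}


def render_frame(plate: PlateState, params_by_type: Dict[str, CellTypeParams],
                 scale: float = 1.0) -> str:
    """Render live cells as an SVG string.

    One ellipse per live cell: size follows the projected surface,
    elongation follows the previous displacement when the cell is
    polarized, and grey-level styling distinguishes attachment states;
    rounded mitotic/apoptotic cells get the thick bright border seen in
    phase contrast.
    """
    w, h = plate.width * scale, plate.height * scale
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}" '
        f'viewBox="0 0 {w:.3f} {h:.3f}">',
        f'<rect width="{w:.3f}" height="{h:.3f}" fill="#4a4a4a"/>',
    ]
    for c in plate.cells:
        if not c.alive:
            continue
        params = params_by_type.get(c.cell_type) or next(iter(params_by_type.values()))
        area = projected_surface(c, params)
        r = math.sqrt(area / math.pi) * scale
        px, py = c.prev_disp
        pmod = math.hypot(px, py)
        elong = min(1.8, 1.0 + pmod / max(params.d_ref, 1e-9)) if pmod > 1e-9 else 1.0
        rx, ry = r * elong, r / elong
        angle = math.degrees(math.atan2(py, px)) if pmod > 1e-9 else 0.0
        fill, stroke, width = _STYLES.get(c.attach_phase, _STYLES["SPREAD"])
        klass = c.attach_phase
        if c.cycle_phase in ("M", "APO"):
            stroke, width = "#ffffff", 3.0
            klass = c.cycle_phase
        x = c.pos[0] * scale
        y = (plate.height - c.pos[1]) * scale  # SVG y axis points down
        parts.append(
            f'<ellipse class="{klass}" cx="{x:.2f}" cy="{y:.2f}" rx="{rx:.2f}" '
            f'ry="{ry:.2f}" transform="rotate({-angle:.1f} {x:.2f} {y:.2f})" '
            f'fill="{fill}" stroke="{stroke}" stroke-width="{width}"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)
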