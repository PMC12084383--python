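"""Experiment runner: scheduling, the per-interval update loop, and the
History / Path / Frame output tables.

Per interval the engine fires due events, rebuilds the neighbour grid,
updates every cell (cycle, vitality, reporters, attachment, motion — all
cells read the *previous* interval's grid and fields, so the update is
synchronous and iteration-order independent), advances attractant fields
(decay plus cell-driven degradation), and records one frame.

Reproducibility: one master seed; every cell derives an independent RNG
substream keyed by its id, so a run is bit-identical for a fixed seed
regardless of how the population evolves.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import attachment as _attach
from . import cycle as _cycle
from . import motility as _motility
from .core import (
    CellState,
    CellTypeParams,
    Medium,
    PlateState,
    PHASES,
    ATTACH_PHASES,
)
from .events import EventSpec, apply_event, decay_field, degrade_locally, local_confluence

__all__ = ["RunRecord", "run_experiment", "replication_time", "build_plate"]


@dataclass
class RunRecord:
    """Outputs of one simulation run.

    ``history``: one row per time point (live count, per-phase and
    per-attachment counts, mean volume/surface, divisions, deaths, events).
    ``paths``: one row per cell (lineage, origin/destiny, birth/death time).
    ``frames``: one row per live cell per recorded interval.
    """

    history: pd.DataFrame
    paths: pd.DataFrame
    frames: pd.DataFrame
    setup: Dict
    performance: Dict
    interval: float

    def to_tracks(self):
        """Convert the frame table into a TrackSet for the analysis suite."""
        from .analysis import TrackSet

        cells = {}
        meta = {}
        for row in self.paths.itertuples():
            meta[row.id] = (row.origin, row.destiny if isinstance(row.destiny, str) else None)
        for cid, grp in self.frames.groupby("id"):
            t = grp["time"].to_numpy(float)
            xy = grp[["x", "y"]].to_numpy(float)
            origin, destiny = meta.get(cid, ("start", None))
            cells[int(cid)] = (t, xy, origin, destiny)
        return TrackSet(cells=cells, interval=self.interval)

    def export(self, out_dir) -> None:
        """Write history.csv, paths.csv, frames.csv and setup.json."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.history.to_csv(out / "history.csv", index=False)
        self.paths.to_csv(out / "paths.csv", index=False)
        self.frames.to_csv(out / "frames.csv", index=False)
        with open(out / "setup.json", "w") as fh:
            json.dump(self.setup, fh, indent=2, default=str)


def _cell_rng(master_seed: int, cell_id: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_id,)))
    )


def _seed_cell(cid: int, pos: Tuple[float, float], params: CellTypeParams,
               rng: np.random.Generator, randomize_cycle: bool,
               attach: str, nominal_cycle: float) -> CellState:
    cell = CellState(
        id=cid, pos=pos, volume=params.v_birth,
        growth_rate_modifier=float(rng.lognormal(0.0, params.growth_sigma)),
        cell_type=params.name, origin="start",
    )
    if attach == "spread":
        cell.attach_phase = "SPREAD"
        cell.spread_fraction = 1.0
    else:
        cell.attach_phase = "DETACHED"
        cell.spread_fraction = 0.0
    if randomize_cycle:
        u = float(rng.random())
        cell.volume = params.v_birth * 2.0 ** u
        cell.age = u * nominal_cycle
        prev = 0.0
        for phase, edge in params.seed_phase_edges:
            if u < edge:
                cell.cycle_phase = phase
                if phase == "S":
                    cell.dna_fraction = (u - prev) / (edge - prev)
                break
            prev = edge
        if cell.cycle_phase in ("G1c", "S", "G2", "M"):
            cell.rfd_dna = True
        if cell.cycle_phase in ("S", "G2", "M") and cell.cycle_phase != "S":
            cell.dna_fraction = 1.0
    return cell


def build_plate(config: Dict, params_by_type: Dict[str, CellTypeParams],
                master_seed: int) -> Tuple[PlateState, Dict[int, np.random.Generator]]:
    """Create the plate and its seeded cells from a validated config."""
    pc = config.get("plate", {})
    plate = PlateState(
        width=float(pc.get("width", 1000.0)),
        height=float(pc.get("height", 1000.0)),
        medium=Medium(
            serum_type=pc.get("serum_type", "FBS"),
            serum_level=float(pc.get("serum_level", 10.0)),
            molecules=dict(pc.get("molecules", {})),
        ),
    )
    seed_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=master_seed, spawn_key=(0,)))
    )
    rngs: Dict[int, np.random.Generator] = {}
    cid = 1
    nominal = float(config.get("run", {}).get("nominal_cycle_minutes", 1440.0))
    for seeding in config.get("seeding", [{"count": 1}]):
        tname = seeding.get("type", next(iter(params_by_type)))
        params = params_by_type[tname]
        randomize = bool(seeding.get("randomize_cycle", True))
        attach = seeding.get("attach", "spread")
        positions = seeding.get("positions")
        if positions is None:
            n = int(seeding.get("count", 1))
            positions = [
                (seed_rng.uniform(0.0, plate.width), seed_rng.uniform(0.0, plate.height))
                for _ in range(n)
            ]
        for pos in positions:
            cell = _seed_cell(cid, (float(pos[0]), float(pos[1])), params,
                              seed_rng, randomize, attach, nominal)
            plate.cells.append(cell)
            rngs[cid] = _cell_rng(master_seed, cid)
            cid += 1
    return plate, rngs


def run_experiment(config: Dict, seed: Optional[int] = None,
                   params_by_type: Optional[Dict[str, CellTypeParams]] = None,
                   record_frames: bool = True, record_every: int = 1) -> RunRecord:
    """Run one simulated experiment and return its record.

    ``config`` is the (validated) setup dictionary; ``params_by_type`` maps
    cell-type names to parameter sets (defaults to the packaged library via
    :mod:`platesim.scenarios`).  ``seed`` overrides ``config['run']['seed']``.
    """
    from .scenarios import params_from_config

    t_wall = _time.perf_counter()
    if params_by_type is None:
        params_by_type = params_from_config(config)
    run_cfg = config.get("run", {})
    master_seed = int(seed if seed is not None else run_cfg.get("seed", 0))
    dt = float(run_cfg.get("interval_min", 20.0))
    duration = float(run_cfg.get("duration_min", 1440.0))
    n_steps = int(round(duration / dt))

    plate, rngs = build_plate(config, params_by_type, master_seed)
    events = sorted(
        (EventSpec(float(e["time"]), e["kind"], dict(e.get("payload", {})))
         for e in config.get("events", [])),
        key=lambda e: e.time,
    )
    event_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=master_seed, spawn_key=(1,)))
    )
    virus: Dict = {}
    next_id = max((c.id for c in plate.cells), default=0) + 1
    bucket = max(p.repulsion_radius for p in params_by_type.values())
    bucket = max(bucket, max(p.confluence_radius for p in params_by_type.values()))

    hist_rows: List[Dict] = []
    frame_rows: List[Tuple] = []
    n_updates = 0
    ev_idx = 0

    def record(time: float, divisions: int, deaths: int, fired: List[str]) -> None:
        live = [c for c in plate.cells if c.alive]
        phase_counts = {ph: 0 for ph in PHASES if ph != "DEAD"}
        attach_counts = {ap: 0 for ap in ATTACH_PHASES}
        vol = surf = 0.0
        for c in live:
            phase_counts[c.cycle_phase] += 1
            attach_counts[c.attach_phase] += 1
            vol += c.volume
            surf += _attach.projected_surface(c, params_by_type[c.cell_type])
        n = len(live)
        row = {
            "time": time, "live": n,
            "divisions": divisions, "deaths": deaths,
            "mean_volume": vol / n if n else math.nan,
            "mean_surface": surf / n if n else math.nan,
            "events": ";".join(fired),
        }
        for ph, cnt in phase_counts.items():
            row[f"n_{ph}"] = cnt
        for ap, cnt in attach_counts.items():
            row[f"n_{ap}"] = cnt
        hist_rows.append(row)
        if record_frames:
            step_no = len(hist_rows) - 1
            if step_no % record_every == 0:
                for c in live:
                    frame_rows.append((
                        time, c.id, c.pos[0], c.pos[1], c.cycle_phase,
                        c.attach_phase, c.volume, c.cdt1, c.p27,
                    ))

    record(plate.time, 0, 0, [])

    for _step in range(n_steps):
        fired: List[str] = []
        while ev_idx < len(events) and events[ev_idx].time <= plate.time + 1e-9:
            ev = events[ev_idx]
            apply_event(plate, ev, event_rng)
            if ev.kind == "viralInfection":
                virus = dict(ev.payload)
            fired.append(ev.kind)
            ev_idx += 1

        plate.rebuild_grid(bucket)
        plate._by_id = {c.id: c for c in plate.cells}

        divisions = 0
        deaths_before = sum(1 for c in plate.cells if c.cycle_phase == "DEAD")
        newborns: List[CellState] = []
        live_now = [c for c in plate.cells if c.alive]
        for cell in live_now:
            params = params_by_type[cell.cell_type]
            rng = rngs[cell.id]
            conf = local_confluence(cell, plate, params)
            action = _cycle.step_cycle(cell, plate, params, dt, rng, conf)
            _cycle.update_vitality(cell, plate, params, dt, rng)
            if cell.cycle_phase == "DEAD":
                continue
            _cycle.update_reporters(cell, params, dt)
            _attach.step_attachment(cell, plate, params, dt, rng)
            _motility.step_motion(cell, plate, params, dt, rng, conf)
            cell.pos = plate.clamp(cell.pos)
            if cell.infection_timer is not None:
                cell.infection_timer -= dt
                if cell.infection_timer <= 0.0:
                    _burst(cell, plate, virus, rngs, event_rng)
            if action == "divide":
                d1, d2 = _cycle.divide(cell, params, rng, next_id)
                for d in (d1, d2):
                    d.cell_type = cell.cell_type
                    d.pos = plate.clamp(d.pos)
                    d.birth_time = plate.time + dt
                    rngs[d.id] = _cell_rng(master_seed, d.id)
                    newborns.append(d)
                next_id += 2
                cell.destiny = "split"
                cell.death_time = plate.time + dt
                divisions += 1

        plate.cells.extend(newborns)
        plate.time += dt

        for fld in plate.fields.values():
            decay_field(fld, dt)
            if fld.degradable_by_cells:
                any_params = next(iter(params_by_type.values()))
                # dying cells have shut down metabolism and no longer consume
                degrade_locally(
                    fld, (c for c in plate.cells
                          if c.alive and c.cycle_phase not in ("DAMAGED", "APO")),
                    any_params.attractant_degradation_rate, dt,
                    any_params.sensing_distance,
                )

        deaths = sum(1 for c in plate.cells if c.cycle_phase == "DEAD") - deaths_before
        n_updates += len(live_now)
        record(plate.time, divisions, deaths, fired)

    path_rows = []
    for c in plate.cells:
        path_rows.append({
            "id": c.id, "parent": c.parent, "type": c.cell_type,
            "origin": c.origin, "destiny": c.destiny,
            "birth_time": c.birth_time, "death_time": c.death_time,
            "age": c.age,
        })
    frames = pd.DataFrame(
        frame_rows,
        columns=["time", "id", "x", "y", "phase", "attach", "volume", "cdt1", "p27"],
    )
    perf = {
        "wall_seconds": _time.perf_counter() - t_wall,
        "cell_updates": n_updates,
        "steps": n_steps,
    }
    return RunRecord(
        history=pd.DataFrame(hist_rows),
        paths=pd.DataFrame(path_rows),
        frames=frames,
        setup=config,
        performance=perf,
        interval=dt,
    )


def _burst(cell: CellState, plate: PlateState, virus: Dict,
           rngs: Dict[int, np.random.Generator], rng: np.random.Generator) -> None:
    """Lysis: the cell dies and sheds virus onto its neighbours."""
    cell.infection_timer = None
    cell.cycle_phase = "DEAD"
    cell.vitality = 0.0
    cell.destiny = "dead"
    cell.death_time = plate.time
    if plate.grid is None or not virus:
        return
    radius = float(virus.get("spread_radius", 40.0))
    prob = float(virus.get("spread_prob", 0.7))
    lysis = float(virus.get("lysis_minutes", 540.0))
    by_id = getattr(plate, "_by_id", {})
    for nid, _d in plate.grid.query(cell.pos, radius, exclude=cell.id):
        nb = by_id.get(nid)
        if nb is None or not nb.alive or nb.infection_timer is not None:
            continue
        if rng.random() < prob:
            nb.infection_timer = lysis


def replication_time(record: RunRecord) -> float:
    """Mean cell age at mitosis (minutes) over all division events.

    Uses the cell's accumulated age (which, for cells seeded mid-cycle,
    includes the age assigned at seeding), so the value estimates the full
    birth-to-division time.
    """
    split = record.paths[record.paths["destiny"] == "split"]
    if split.empty:
        raise ValueError("no divisions recorded; replication time undefined")
    return float(split["age"].mean())
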