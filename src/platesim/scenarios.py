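"""Packaged cell-type parameter library and named experiment scenarios.

The NIH3T3-like parameter set is the reference configuration used by the
documentation examples and the acceptance runs.  Its cycle is organised
around volumetric growth: cells double their volume over the nominal
replication time, commitment (G1 -> G1c) and mitosis entry (G2 -> M) are
gated by volume thresholds, and quiescence (G0) exchanges with G1 under
serum and crowding control while volume keeps growing at the same rate —
so quiescence detours do not distort the requested replication time.
Transition-rate values were calibrated by simulation against
population-level reference behaviour (a 24 h mean age at mitosis, day-3
quiescent fractions across serum levels, and a ~70% quiescent plateau at
confluence); they are not measured molecular rates.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

from .core import CellTypeParams, FactorSpec, TransitionSpec

__all__ = ["cell_type_library", "default_cell_type", "params_from_config",
           "scenario", "SCENARIO_NAMES"]

_LN2 = math.log(2.0)


def _nih3t3(nominal_cycle: float = 1440.0) -> CellTypeParams:
    """The packaged NIH3T3-like fibroblast parameter set."""
    # the volume-doubling clock runs slightly slower than the nominal cycle:
    # the factor compensates stochastic gate lags and the bias of measuring
    # mean age at mitosis over a finite run, so a standard 3-day experiment
    # reports a mean replication time matching the nominal one (calibrated
    # by simulation)
    alpha = _LN2 / (nominal_cycle * 1.095)
    v_birth = 925.0
    v_commit = 1500.0
    v_mitosis = 1500.0

    serum_commit = FactorSpec("serum_level", x_ref=2.5, k_steep=2.5, direction="enhancing")
    vol_commit = FactorSpec("volume", x_ref=v_commit, k_steep=0.015, direction="enhancing")
    conf_commit = FactorSpec("local_confluence", x_ref=0.72, k_steep=10.0, direction="limiting")
    vol_mitosis = FactorSpec("volume", x_ref=v_mitosis, k_steep=0.008, direction="enhancing")
    serum_mitosis = FactorSpec("serum_level", x_ref=0.4, k_steep=2.0, direction="enhancing")

    transitions = [
        TransitionSpec("G1", "G1c", 0.95, 20.0, (vol_commit, serum_commit, conf_commit)),
        TransitionSpec("G1c", "S", 0.95, 20.0),
        TransitionSpec("S", "G2", 0.95, 20.0),
        TransitionSpec("G2", "M", 0.95, 20.0, (vol_mitosis, serum_mitosis)),
        TransitionSpec("M", "DIVIDE", 0.90, 20.0),
        # quiescence entry: starvation arm and crowding arm (parallel edges,
        # OR semantics)
        TransitionSpec("G1", "G0", 0.08, 20.0,
                       (FactorSpec("serum_level", 6.0, 0.35, "limiting"),)),
        TransitionSpec("G1", "G0", 0.30, 20.0,
                       (FactorSpec("serum_level", 1.2, 2.5, "limiting"),)),
        TransitionSpec("G1", "G0", 0.05, 20.0,
                       (FactorSpec("local_confluence", 0.68, 12.0, "enhancing"),)),
        # quiescence exit: needs serum, room and enough volume to re-commit
        TransitionSpec("G0", "G1c", 0.70, 20.0,
                       (FactorSpec("serum_level", 4.5, 0.7, "enhancing"),
                        FactorSpec("local_confluence", 0.90, 6.0, "limiting"),
                        FactorSpec("volume", 1300.0, 0.010, "enhancing"))),
        # apoptosis: small baseline, raised by crowding and starvation
        TransitionSpec("G1", "APO", 0.02, 1440.0),
        TransitionSpec("G0", "APO", 0.03, 1440.0),
        TransitionSpec("G1", "APO", 0.30, 1440.0,
                       (FactorSpec("serum_level", 1.0, 1.0, "limiting"),)),
        TransitionSpec("G0", "APO", 0.30, 1440.0,
                       (FactorSpec("serum_level", 1.0, 1.0, "limiting"),)),
        TransitionSpec("G0", "APO", 0.25, 1440.0,
                       (FactorSpec("local_confluence", 0.82, 10.0, "enhancing"),)),
    ]
    attach_transitions = [
        TransitionSpec("DETACHED", "ATTACHED", 0.60, 20.0),
        TransitionSpec("ATTACHED", "SPREADING", 0.70, 20.0),
    ]
    return CellTypeParams(
        name="NIH3T3",
        d_ref=11.6,
        r_frac=0.75, p_frac=0.25, b_frac=0.0, bias_angle=0.0,
        ref_interval=20.0,
        alpha_growth={"G1": alpha, "G1c": alpha, "S": alpha, "G2": alpha,
                      "M": 0.0, "G0": alpha, "APO": 0.0, "DAMAGED": 0.0},
        v_birth=v_birth,
        transitions=transitions,
        attach_transitions=attach_transitions,
        seed_phase_edges=(("G1", 0.697), ("G1c", 0.711), ("S", 0.957),
                          ("G2", 0.977), ("M", 1.0)),
        s_phase_minutes=360.0,
        repulsion_radius=40.0,
        repulsion_sensitivity=0.25,
        sensing_distance=20.0,
        attractant_degradation_rate=0.5,
        confluence_radius=50.0,
        phase_motility={"G1": 1.0, "G1c": 1.0, "S": 1.0, "G2": 1.0, "M": 0.3,
                        "G0": 0.4, "APO": 0.2, "DAMAGED": 0.05},
        attach_motility={"SPREAD": 1.0, "SPREADING": 0.6, "ATTACHED": 0.3,
                         "DETACHED": 0.05, "DESPREADING": 0.5},
        confluence_motility=FactorSpec("local_confluence", 0.80, 5.0, "limiting"),
        serum_motility=None,
        growth_serum_factor=FactorSpec("serum_level", 1.2, 1.5, "enhancing"),
        growth_confluence_factor=FactorSpec("local_confluence", 0.70, 8.0, "limiting"),
        drug_sensitivity={"antibiotic": 0.002},
        protective_genes={"antibiotic": "resistance"},
    )


def _vero(nominal_cycle: float = 1440.0) -> CellTypeParams:
    p = _nih3t3(nominal_cycle)
    p.name = "VeroE6"
    p.d_ref = 8.0
    return p


_LIBRARY = {"NIH3T3": _nih3t3, "VeroE6": _vero}


def cell_type_library() -> List[str]:
    return sorted(_LIBRARY)


def default_cell_type(name: str = "NIH3T3", **overrides) -> CellTypeParams:
    """A library parameter set, optionally with scalar-field overrides."""
    if name not in _LIBRARY:
        raise ValueError(f"unknown cell type {name!r}; library: {cell_type_library()}")
    params = _LIBRARY[name]()
    for key, val in overrides.items():
        if not hasattr(params, key):
            raise ValueError(f"unknown cell-type parameter {key!r}")
        setattr(params, key, val)
    params.validate()
    return params


def _factor_from_dict(d: Dict) -> FactorSpec:
    return FactorSpec(
        quantity=d["quantity"], x_ref=float(d["x_ref"]),
        k_steep=float(d["k_steep"]), direction=d.get("direction", "enhancing"),
        target=d.get("target"),
    )


def _transition_from_dict(d: Dict) -> TransitionSpec:
    return TransitionSpec(
        from_state=d["from"], to_state=d["to"],
        base_prob=float(d["base_prob"]), prob_time=float(d["prob_time"]),
        factors=tuple(_factor_from_dict(f) for f in d.get("factors", [])),
    )


def params_from_config(config: Dict) -> Dict[str, CellTypeParams]:
    """Build the per-type parameter map from a setup config.

    Each entry of ``config['cell_types']`` names a library base and may
    override scalar fields or replace the transition tables; with no entry
    the packaged NIH3T3-like set is used.
    """
    entries = config.get("cell_types") or [{"base": "NIH3T3"}]
    out: Dict[str, CellTypeParams] = {}
    for entry in entries:
        entry = dict(entry)
        base = entry.pop("base", "NIH3T3")
        name = entry.pop("name", base)
        transitions = entry.pop("transitions", None)
        attach_transitions = entry.pop("attach_transitions", None)
        extra_transitions = entry.pop("extra_transitions", None)
        params = default_cell_type(base, **entry)
        params.name = name
        if transitions is not None:
            params.transitions = [_transition_from_dict(t) for t in transitions]
        if extra_transitions is not None:
            params.transitions = list(params.transitions) + [
                _transition_from_dict(t) for t in extra_transitions
            ]
        if attach_transitions is not None:
            params.attach_transitions = [_transition_from_dict(t) for t in attach_transitions]
        params.validate()
        out[name] = params
    return out


# --------------------------------------------------------------------------
# named scenarios


def _base_config(width, height, serum_type, serum_level, count, duration,
                 interval=20.0, seed=0, **extra):
    cfg = {
        "plate": {"width": width, "height": height,
                  "serum_type": serum_type, "serum_level": serum_level},
        "cell_types": [{"base": "NIH3T3"}],
        "seeding": [{"type": "NIH3T3", "count": count}],
        "events": [],
        "run": {"duration_min": duration, "interval_min": interval, "seed": seed},
    }
    cfg.update(extra)
    return cfg


def _growth_24h(seed=0):
    """100 cells, standard serum, 3 simulated days: replication-time check."""
    return _base_config(3000.0, 3000.0, "FBS", 10.0, 100, 3 * 1440.0, seed=seed)


def _growth_5d(seed=0):
    """100 cells, standard serum, 5 simulated days of exponential growth."""
    return _base_config(4000.0, 4000.0, "FBS", 10.0, 100, 5 * 1440.0, seed=seed)


def _serum_panel(seed=0, days=3.0):
    """Exponential growth at 10% vs 2.5% calf serum (day-3 phase fractions)."""
    runs = {}
    for level in (10.0, 2.5):
        runs[f"cs{level:g}"] = _base_config(
            1500.0, 1500.0, "cs", level, 60, days * 1440.0, seed=seed)
    return {"runs": runs}


def _seeding_panel(seed=0, days=15.0):
    """Four seeding densities at 5% calf serum grown to the stationary state."""
    runs = {}
    for n in (1, 4, 10, 50):
        runs[f"seed{n}"] = _base_config(
            762.0, 762.0, "cs", 5.0, n, days * 1440.0, seed=seed + n)
    return {"runs": runs}


def _starvation_rescue(seed=0, days=7.0):
    """Serum step-down 10% -> 0.5% FBS on day 1, restore on day 4."""
    cfg = _base_config(2500.0, 2500.0, "FBS", 10.0, 100, days * 1440.0, seed=seed)
    cfg["events"] = [
        {"time": 1440.0, "kind": "mediumChange", "payload": {"serum_level": 0.5}},
    ]
    if days > 4:
        cfg["events"].append(
            {"time": 4 * 1440.0, "kind": "mediumChange", "payload": {"serum_level": 10.0}})
    return cfg


def _motion_only_type(name, d_ref, r, p, b, bias_angle=0.0):
    """A cell type that only moves: no cycle transitions, no growth."""
    return {
        "base": "NIH3T3", "name": name, "d_ref": d_ref,
        "r_frac": r, "p_frac": p, "b_frac": b, "bias_angle": bias_angle,
        "alpha_growth": {}, "transitions": [],
        "repulsion_sensitivity": 0.0,
        "confluence_motility": None, "growth_serum_factor": None,
        "growth_confluence_factor": None,
    }


def _random_vs_mixed(seed=0, n_cells=50, n_frames=72):
    """Pure-random vs mixed (persistence + bias) motion demo populations."""
    duration = n_frames * 20.0
    runs = {}
    runs["random"] = {
        "plate": {"width": 4000.0, "height": 4000.0, "serum_level": 10.0},
        "cell_types": [_motion_only_type("random_mover", 8.7, 1.0, 0.0, 0.0)],
        "seeding": [{"type": "random_mover", "count": n_cells, "randomize_cycle": False}],
        "events": [],
        "run": {"duration_min": duration, "interval_min": 20.0, "seed": seed},
    }
    d_tot = 8.7 + 4.0 + 4.0
    runs["mixed"] = {
        "plate": {"width": 4000.0, "height": 4000.0, "serum_level": 10.0},
        "cell_types": [_motion_only_type(
            "mixed_mover", d_tot, 8.7 / d_tot, 4.0 / d_tot, 4.0 / d_tot)],
        "seeding": [{"type": "mixed_mover", "count": n_cells, "randomize_cycle": False}],
        "events": [],
        "run": {"duration_min": duration, "interval_min": 20.0, "seed": seed},
    }
    return {"runs": runs}


def _wound_healing(seed=0, hours=24.0):
    """Confluent layer, scratch, dual self-generated attractant gradients."""
    width, height = 900.0, 600.0
    spacing = 30.0
    positions = []
    x = spacing / 2.0
    while x < width:
        y = spacing / 2.0
        while y < height:
            positions.append((x, y))
            y += spacing
        x += spacing
    x0, x1 = width / 2.0 - 75.0, width / 2.0 + 75.0
    return {
        "plate": {"width": width, "height": height, "serum_type": "FBS", "serum_level": 10.0},
        "cell_types": [{"base": "NIH3T3"}],
        "seeding": [{"type": "NIH3T3", "positions": positions}],
        "events": [
            # flat long-lived serum-factor field, deposited with the wound so
            # the cell-free band stays rich: degradable -> self-generated
            {"time": 60.0, "kind": "gradientAddition", "payload": {
                "name": "serum_factors", "amplitude": 60.0, "half_life": None,
                "degradable_by_cells": True, "gain": 0.15, "node_size": 10.0}},
            {"time": 60.0, "kind": "scratchOnPlate", "payload": {
                "x0": x0, "x1": x1, "damage_level": 1.0,
                "debris_amplitude": 80.0, "debris_half_life": 240.0,
                "debris_gain": 0.15}},
        ],
        "run": {"duration_min": hours * 60.0, "interval_min": 20.0, "seed": seed},
        "wound_band": {"x0": x0, "x1": x1},
    }


def _antibiotic_selection(seed=0, days=4.0, transfect=True):
    """Transfection with a resistance gene, then antibiotic addition at 6 h."""
    cfg = _base_config(2000.0, 2000.0, "FBS", 10.0, 200, days * 1440.0, seed=seed)
    cfg["events"] = []
    if transfect:
        cfg["events"].append({"time": 0.0, "kind": "transfection",
                              "payload": {"gene": "resistance", "efficiency": 0.1}})
    cfg["events"].append({"time": 360.0, "kind": "moleculeAddition",
                          "payload": {"name": "antibiotic", "concentration": 1.0}})
    return cfg


def _ras_foci(seed=0, days=8.0):
    """Ras transfection at 12 h, serum step-down to 1% at 24 h: foci outgrowth."""
    cfg = _base_config(2000.0, 2000.0, "FBS", 10.0, 150, days * 1440.0, seed=seed)
    # constitutively active Ras bypasses serum control of commitment and
    # quiescence exit
    cfg["cell_types"] = [{
        "base": "NIH3T3",
        "extra_transitions": [
            {"from": "G1", "to": "G1c", "base_prob": 0.9, "prob_time": 20.0,
             "factors": [
                 {"quantity": "gene_presence", "target": "RasV12",
                  "x_ref": 0.5, "k_steep": 20.0, "direction": "enhancing"},
                 {"quantity": "volume", "x_ref": 1450.0, "k_steep": 0.015,
                  "direction": "enhancing"}]},
            {"from": "G0", "to": "G1c", "base_prob": 0.5, "prob_time": 20.0,
             "factors": [
                 {"quantity": "gene_presence", "target": "RasV12",
                  "x_ref": 0.5, "k_steep": 20.0, "direction": "enhancing"},
                 {"quantity": "volume", "x_ref": 1300.0, "k_steep": 0.010,
                  "direction": "enhancing"}]},
        ],
    }]
    cfg["events"] = [
        {"time": 720.0, "kind": "transfection",
         "payload": {"gene": "RasV12", "efficiency": 0.05}},
        {"time": 1440.0, "kind": "mediumChange", "payload": {"serum_level": 1.0}},
    ]
    return cfg


def _lytic_plaque(seed=0, days=4.0):
    """Confluent layer, one infected cell, lytic spread in ~9 h waves."""
    width = height = 800.0
    spacing = 32.0
    positions = []
    x = spacing / 2.0
    while x < width:
        y = spacing / 2.0
        while y < height:
            positions.append((x, y))
            y += spacing
        x += spacing
    cfg = {
        "plate": {"width": width, "height": height, "serum_type": "FBS", "serum_level": 10.0},
        "cell_types": [{"base": "VeroE6"}],
        "seeding": [{"type": "VeroE6", "positions": positions}],
        "events": [
            {"time": 0.0, "kind": "viralInfection", "payload": {
                "region": {"x0": width / 2 - 20, "x1": width / 2 + 20,
                           "y0": height / 2 - 20, "y1": height / 2 + 20},
                "lysis_minutes": 540.0, "spread_radius": 45.0, "spread_prob": 0.8}},
        ],
        "run": {"duration_min": days * 1440.0, "interval_min": 20.0, "seed": seed},
    }
    return cfg


_SCENARIOS = {
    "growth_24h": _growth_24h,
    "growth_5d": _growth_5d,
    "serum_panel": _serum_panel,
    "seeding_panel": _seeding_panel,
    "starvation_rescue": _starvation_rescue,
    "random_vs_mixed": _random_vs_mixed,
    "wound_healing": _wound_healing,
    "antibiotic_selection": _antibiotic_selection,
    "ras_foci": _ras_foci,
    "lytic_plaque": _lytic_plaque,
}

SCENARIO_NAMES = sorted(_SCENARIOS)


def scenario(name: str, seed: int = 0, **kwargs) -> Dict:
    """Materialize a named packaged scenario configuration.

    Panel scenarios return ``{"runs": {label: config, ...}}``; single
    scenarios return one config dict.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choices: {SCENARIO_NAMES}")
    return _SCENARIOS[name](seed=seed, **kwargs)
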