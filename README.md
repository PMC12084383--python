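# platesim

Agent-based simulation of adherent eukaryotic cell cultures on a 2-D plate,
with a companion trajectory-analysis suite.

Researchers who study cultured cell populations — growth curves, serum
response, wound-healing migration, drug selection, viral plaques — often
want an in-silico counterpart of their plate: a population of independent
cell agents whose proliferation and movement statistics can be matched to a
real culture, then perturbed ("what if we scratch the layer? starve the
cells? add an antibiotic?"). `platesim` provides that: point-like cell
agents with volume, cycle state, attachment state and genes, living on a
shared plate with medium, attractant fields and physical constraints.

## The models

**Cell cycle.** Each cell advances through G1 → G1c → S → G2 → M →
division in a Markov chain. An edge's probability is stated as a base
probability `p` over a reference time `T`, adapted to the simulation
interval Δt as

    p(Δt) = 1 − (1 − p)^(Δt/T)

and modulated by logistic factors `eff = 1 / (1 + e^{k (X_c − X_ref)})` of
physiological quantities (serum level, cell volume, local confluence,
vitality, drug level, gene presence). Volume grows exponentially,
`V(t+Δt) = V e^{αΔt}`; commitment and mitosis entry are volume-gated, so
the replication clock is volumetric doubling. A reversible quiescence
branch (G1 ↔ G0) responds to starvation and crowding, and apoptosis,
damage and drug action drain a per-cell vitality. Two reporters (cdt1,
p27) follow phase-dependent synthesis/decay, separating cycling from
quiescent cells in the (cdt1, p27) plane.

**Motion.** Per interval a displacement is composed of three vectors:
`d = r + p·û(d_prev) + b` — a **random** ten-step-walk resultant, a
**persistence** vector along the previous displacement, and a **bias**
vector. The moduli derive from base parameters (r, p, b fractions summing
to 1, and the maximal displacement d_ref): conditions (cycle phase,
attachment, vitality, confluence) scale d_ref into d_tot = k·d_ref, and
extra biases — cell–cell repulsion and attractant gradients, including
*self-generated* gradients maintained by cells degrading the attractant
around themselves — fold into the bias fraction before the three fractions
are renormalised.

**Analysis.** From track sets (simulated or experimental, a documented
plain-text dialect) the suite estimates the three components (an OLS
moment decomposition, round-trip consistent with the generator), MSD
curves with weighted power-law fits (`MSD = k·t^α`) and Fürth
persistent-random-walk fits (`MSD = 2S²P[t − P(1 − e^{−t/P})]`),
linearity, coherence, circular statistics (R), per-window component
contributions and 2-D displacement kernel densities.

## Worked example

```python
import platesim as ps

# 100 NIH3T3-like cells, 10% serum, 3 simulated days at 20-min steps
cfg = ps.scenario("growth_24h", seed=1)
rec = ps.run_experiment(cfg, seed=1)
print(round(ps.replication_time(rec), 1), int(rec.history["live"].iloc[-1]))
# 1442.6 781

# motion round trip: generate pure-random tracks, re-estimate the components
ts = ps.simulate_tracks(50, 72, rand=8.7, pers=0.0, bias=0.0, seed=3)
est = ps.estimate_components(ts)
print(round(est.rand_module, 2), round(est.pers_module, 2), round(est.bias_module, 2))
# 8.74 0.08 0.16
```

The first run reports a mean cell age at mitosis of 1442.6 min — the
packaged cell type is calibrated for a 24 h replication time — and 781
live cells after 3 days (growth slightly slower than pure doubling because
a fraction of cells is quiescent or dies). The second shows the estimator
recovering the generating random module (8.7 µm per 20-min interval) with
persistence and bias near zero.

The same machinery is scriptable from a shell:

```bash
platesim scenario wound_healing --seed 1 --out wound.json
platesim run wound.json --seed 1 --out wound_out
platesim analyze wound_out/tracks.txt --out wound_analysis
```

Packaged scenarios: `growth_24h`, `growth_5d`, `serum_panel`,
`seeding_panel`, `starvation_rescue`, `random_vs_mixed`, `wound_healing`,
`antibiotic_selection`, `ras_foci`, `lytic_plaque`.

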