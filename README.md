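# c3ensemble

Conformational-ensemble analysis for C3-symmetric trimeric receptors whose
function hinges on long, intrinsically disordered loops — the situation of
PII-like secondary-messenger receptors such as the c-di-AMP receptor PstA,
where ligand binding at the rigid core reshapes the spatial distribution of
three disordered "B-loops" that capture downstream interaction partners.

The package compares two ensembles (ligand-free *apo* vs ligand-bound
*holo*) through:

- **Loop protrusion geometry.** Per frame, the C3 axis is the unit normal
  of the plane through the three monomer-core centers of mass; the
  reference plane passes through the core center of mass. The signed axial
  distance *d* of a loop-tip reporter atom (Cα of the tip residue) from
  that plane measures forward protrusion toward the partner-binding face.
- **Avidity statistics.** A binding-competent interface needs all three
  loops forward simultaneously. For a threshold θ, the package measures
  P(k of 3 loops with d ≥ θ) and the holo/apo ratio of P(k = 3). For
  independently moving loops P(k = 3) = p(θ)³, so a modest shift of the
  single-loop marginal p(θ) is amplified cubically — the mechanism by which
  a ligand can gate partner binding without ordering the loops.
- **GROMOS/Daura clustering.** Greedy neighbor-count clustering on the
  pairwise minimized-RMSD matrix, with concatenated single-monomer
  trajectories and cutoff calibration to a coverage target (e.g. 85% of
  frames within six clusters).
- **Contacts and persistence.** Residue-pair mean minimum heavy-atom
  distance maps, apo−holo difference maps, and geometric hydrogen-bond /
  salt-bridge occupancy with a strict >10% persistence filter.
- **NMR observables.** Combined amide chemical-shift perturbations
  Δδ = √(Δδ_H² + (0.14·Δδ_N)²), exponential R₁/R₂ fits, steady-state
  hetNOE ratios, and constant-time CPMG relaxation dispersion fitted with
  the general two-site (Carver–Richards) model, reporting the exchange
  contribution R_ex = R₂,eff(ν→0) − R₂,eff(ν→∞).

Every stage has a parameter-recovery test against the built-in synthetic
generator (`c3ensemble.synthetic`), which builds C3 trimers with anchored
pseudo-Cα loops whose protrusion marginal, latch state and inter-loop
correlation are planted and recorded as ground truth.

## Worked example

Run the full apo-vs-holo comparison on synthetic ensembles (a disordered,
rarely latched apo state vs a strongly latched holo state) from Python:

```python
from c3ensemble.config import RunConfig
from c3ensemble.pipeline import run, report

cfg = RunConfig(
    simulate={
        "apo":  {"n_frames": 200, "loop_bias_mean": 9.0,  "loop_bias_sd": 5.0,
                 "latch_prob": 0.35, "seed": 11},
        "holo": {"n_frames": 200, "loop_bias_mean": 16.0, "loop_bias_sd": 3.0,
                 "latch_prob": 0.95, "seed": 12},
        "hbond": {"apo": {"occupancy": 0.181, "n_frames": 1000},
                  "holo": {"occupancy": 0.640, "n_frames": 1000}},
        "dispersion": [{"r20": 12.0, "kex": 2000.0, "pb": 0.05,
                        "dw_ppm": 4.0457, "field_mhz": 600.0, "noise_sd": 0.24}],
    },
    trim_fraction=0.1, output_dir="out", seed=7,
)
print(report(run(cfg)))
```

which prints:

```
C3 trimer ensemble comparison
config hash: 6cf0332e60cce958  seed: 7

== Loop protrusion distribution shift ==
mean apo 7.21 A, mean holo 15.56 A, shift +8.35 A

== Binding-competence ratio (three loops forward) ==
theta = 16.0 A: ratio 27.15 (95% CI 17.09-37.23)  [lower bound]

== Cluster populations ==
apo: cutoff 1.4 A, 13 clusters, top-6 coverage 96.1%
holo: cutoff 1.4 A, 14 clusters, top-6 coverage 94.4%

== Persistent contacts ==
apo: A/9/N->A/95/O 18.1%
holo: A/9/N->A/95/O 64.0%

== Chemical-shift perturbations ==
not computed

== Exchange contributions (Rex) ==
planted 38.0 s^-1 -> fitted 38.1 s^-1 (two-site)
```

Reading the output: the holo ensemble's monomer-averaged loop protrusion is
shifted forward by ~8 Å; because all three loops must clear the 16 Å
threshold at once, that single-loop shift amplifies into a >20-fold excess
of binding-competent frames (flagged as a lower bound because the apo
ensemble produced no fully forward frame in this short demo). The planted
loop-latch hydrogen bond is recovered at exactly its generated occupancies,
and the CPMG stage recovers the planted exchange contribution of 38 s⁻¹.

The same stages are available as shell subcommands
(`c3ensemble simulate | protrusion | cluster | contacts | hbonds | csp |
relax | dispersion | run | report`), e.g.

```sh
c3ensemble simulate --n-frames 200 --latch-prob 0.95 --out holo.pdb
c3ensemble protrusion holo.pdb --out holo_protrusion.tsv
```

## Layout

- `src/c3ensemble/synthetic.py` — generators with planted ground truth
- `src/c3ensemble/io.py` — multi-model PDB, NMR-STAR/CSV shift tables, TSV/JSON results
- `src/c3ensemble/geometry.py` — Kabsch superposition, C3 frames, protrusion, Rg, RMSF, RMSD/trim
- `src/c3ensemble/clustering.py` — Daura clustering, monomer concatenation, coverage calibration
- `src/c3ensemble/loopstats.py` — distributions, collective occupancy, competence ratio, independence diagnostic
- `src/c3ensemble/contacts.py` — distance maps, difference maps, H-bonds, persistence
- `src/c3ensemble/nmr.py` — CSP, relaxation fits, hetNOE, CPMG dispersion
- `src/c3ensemble/pipeline.py`, `config.py`, `cli.py` — orchestration, YAML config, CLI
- `docs/methods.md` — models, conventions, parameter defaults, limitations
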