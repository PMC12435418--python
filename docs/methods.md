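# Methods

## The system and the question

A C3-symmetric homotrimeric receptor carries, per monomer, a long
disordered loop whose spatial placement — not its internal order —
determines whether the trimer can engage a C3-symmetric downstream
partner. Ligand binding at the rigid core does not fold the loops; it
biases where they spend their time. This package quantifies that bias and
its consequences: per-loop protrusion distributions, the collective
(three-loops-forward) statistics that govern interface formation, the
conformational heterogeneity seen by clustering, the transient contacts
that transmit the bias, and the NMR observables that report on core and
loop dynamics.

## Trimer frame and protrusion

For each frame the three monomer-core centers of mass (uniform atom
weights) define a plane; the C3 axis is its unit normal and the reference
plane is translated to the center of mass of all core atoms. The sign of
the axis is fixed by requiring the center of mass of a user-chosen
*orientation selection* — the ligand face — to have a negative axial
coordinate, so positive protrusion means "toward the partner-binding
face". Which face is "forward" is a convention, not a measurement; it is
therefore configurable, and the protrusion sign simply flips if the
orientation selection is moved to the opposite face.

The protrusion d of monomer m in frame f is the axial coordinate of the
reporter atom (Cα of the loop-tip residue; residue 81 in the default
layout) relative to the plane origin. Using the plane normal of the
monomer-COM triangle rather than an inertia tensor is exact for ideal C3
symmetry, degrades gracefully for near-C3 frames, and is manifestly
covariant under global roto-translations — all plane-based observables are
invariant to per-frame rigid-body motion to ~1e-13 Å in practice.

Superposition-based quantities (RMSD time series, pairwise RMSD, RMSF) use
Kabsch superposition (proper rotations only). RMSF is computed about an
iteratively refined mean structure: frames are superposed on the running
mean until it moves < 1e-6 Å (error after 100 iterations). Note that
superposition absorbs six rigid-body degrees of freedom, so for N atoms
under isotropic jitter σ the expected RMSF is σ√3·√(1 − 6/(3N)) — about
1.3% below σ√3 at N = 80; tolerance choices in the tests account for this.

## Daura/GROMOS clustering

Greedy neighbor counting on the pairwise minimized-RMSD matrix: the frame
with the most neighbors within the cutoff (self included; ties broken
toward the lowest frame index) seeds a cluster, the cluster is removed,
and the count repeats. Cluster sizes are therefore non-increasing and the
output is deterministic for a given frame order. Coverage is the fraction
of frames in the top-k clusters. `cutoff_for_coverage` scans a 0.1 Å grid
from below and returns the smallest cutoff meeting the target (e.g. 85%
within six clusters); the per-ensemble cutoff presets (5.0 Å apo / 3.5 Å
holo for loops; 1.3 and 1.2 Å for core-only clustering) are exposed in the
config without asserting between the two core values. Loop clustering uses
the concatenated single-monomer trajectory (A frames, then B, then C) so
that the three symmetric loops share one conformational space. The default
backbone selection (N, Cα, Cβ, C, O, amide H where present) is config-
driven; Cβ is included deliberately to weight sidechain direction.

## Collective occupancy and avidity

"Forward" is d ≥ θ (closed convention). For each θ on a 0–30 Å, 0.5 Å
grid the package counts frames by k = number of forward loops and reports
P(k). The competence ratio is P_holo(k=3)/P_apo(k=3) at a chosen θ
(default 16 Å). For independent loops P(k=3) = p(θ)³, so a marginal ratio
r becomes r³ collectively; `independence_diagnostic` tests this law
directly by comparing observed P(k=3) with the cube of the empirical
marginal, with a bootstrap z-score.

Confidence intervals use a stationary block bootstrap (geometric block
lengths, circular wrap; 1000 resamples by default) with mean block length
equal to the integrated autocorrelation time of the monomer-averaged
protrusion series, because consecutive MD frames are autocorrelated. When
the apo ensemble has zero fully-forward frames the ratio is reported
against one pseudo-count and flagged as a lower bound rather than raising
a division error.

## Contacts and hydrogen bonds

Contact maps store, per residue pair (intra- or inter-monomer scope), the
mean over frames of the per-frame minimum heavy-atom distance; the
per-frame minima are retained so other aggregations remain recomputable.
Difference maps are signed (A − B, negative = closer in A) with outer-join
semantics and missing pairs flagged. H-bonds use donor–acceptor distance
≤ 3.5 Å and donor–H–acceptor angle ≥ 150° (a common MD-analysis
convention; configurable), with donor hydrogens inferred from frame-0
covalent geometry (≤ 1.25 Å). Topologies without hydrogens get an explicit
error directing to the flagged distance-only mode. Salt bridges are a
contact subclass: charged sidechain N (Arg/Lys/His) to charged sidechain O
(Asp/Glu) minimum distance ≤ 4.0 Å. Persistence filtering keeps contacts
with occurrence strictly greater than the threshold (default 10%).

## NMR observables

- **CSP**: Δδ = √(Δδ_H² + (0.14·Δδ_N)²) per residue, with flag thresholds
  at 0.3 and 1.0 ppm by default. Residues missing the amide H or N in
  either state are absent (NaN), never zero.
- **R₁/R₂**: nonlinear least squares of I(t) = I₀e^(−Rt), seeded by a
  log-linear regression (grid fallback when intensities go non-positive),
  error from the covariance matrix.
- **hetNOE**: I_sat/I_ref with quadrature error propagation.
- **CPMG**: constant-time conversion R₂,eff = −ln(I_ν/I₀)/T_cp (non-
  positive intensities flagged and excluded). ν_CPMG = 1/(2δ) with δ the
  spacing between successive 180° pulses; field strength and T_cp are
  explicit inputs, never inferred. Dispersion fitting compares a flat
  (no-exchange) model against the general two-site Carver–Richards closed
  form (equal intrinsic R₂ in both states), multi-started over a kex/Δω
  grid, and prefers exchange only when it undercuts the flat model's AIC
  by more than 2 — on flat curves with 2% noise this selects exchange in
  well under 10% of replicates. R_ex is evaluated analytically from the
  fitted parameters as the ν→0 minus ν→∞ limits of the model, which is
  noise-robust compared to data endpoints. The Luz–Meiboom fast-exchange
  expression is kept as an independent cross-check: the general form must
  reduce to it when kex ≫ Δω.
- **¹⁵N conversion**: Δω(rad/s) = 2π·Δω(ppm)·0.1013757·(¹H field in MHz).

Known degeneracy: when exchange is much faster than the sampled ν range
(kex ≈ 10⁴ s⁻¹ with ν ≤ 1.5 kHz) the dispersion barely develops and the
ν→0 extrapolation — hence R_ex, and kex/p_B/Δω individually — is weakly
determined. The tests assert curve-level agreement there and only bracket
R_ex, rather than pretending the parameters are identifiable.

## Synthetic generator

The generator emulates the study conditions, not the physics. Each monomer
is a rigid pseudo-Cα core arc (40 residues on a ~15 Å ring with axial
undulation, centered so the core plane is exactly z = 0), an orientation
pad on the ligand face (residues 41–44 at negative z), and a 31-residue
anchored loop (residues 66–96, reporter 81) built as a fixed-bond (3.8 Å)
chain along the anchor–tip–anchor polyline with an alternating
perpendicular sawtooth restoring the bond length (exact on straight
segments, approximate at the tip kink) and a small per-frame wobble
(σ = 0.6 Å) so the loop, like a real disordered loop, decorrelates between
frames away from the tip.

The reporter's axial position is drawn per frame and monomer from a
two-state mixture: with probability `latch_prob` the *latched* (directed)
state, Normal(`loop_bias_mean`, `loop_bias_sd`); otherwise an unlatched
state, Normal(6 Å, 6 Å), emulating a freely reorienting stem. Demo apo
and holo conditions use (9 Å, 5 Å, latch 0.35) and (16 Å, 3 Å, latch
0.95) respectively, chosen so the monomer-averaged distributions differ by
about 7 Å and the holo distribution is visibly narrower — the regime the
avidity statistics are designed for. Inter-loop coupling is an
equicorrelated Gaussian copula on the three draws; a 3×3 equicorrelation
matrix requires ρ ≥ −0.5, which the spec validates. Optional per-frame
global roto-translations (uniform random rotations, ±50 Å translations)
stress rigid-body invariance. All randomness flows from a single integer
seed; identical specs give bit-identical trajectories.

What the generator does *not* emulate: force-field energetics, realistic
secondary structure, sidechains, solvent, or kinetics (frames are i.i.d.
given the latch state, so autocorrelation-sensitive machinery is exercised
by the bootstrap's own block structure, not by physical dynamics).
Passing recovery tests therefore demonstrates the *estimators* are
correct, not that any particular biological system behaves this way.

NMR generators use the same closed forms as the fitters (Carver–Richards,
exponential decay) plus Gaussian noise, with planted truth recorded —
including the analytic R_ex of the noiseless dispersion curve. The
contact-fixture generator plants an exact occupancy by placing an ideal
linear N–H···O geometry (2.9 Å) in a seeded random subset of frames and a
clearly violating geometry (6.5 Å) elsewhere.

## I/O conventions

Residue numbering is 1-based at every file boundary (PDB, NMR-STAR, CSV);
carbonyl carbon is stored as atom "C". Multi-model PDB is the mandatory
trajectory format (read and written via biotite, coordinates to 0.001 Å);
inconsistent per-model atom counts are a hard error naming the offending
model. The NMR-STAR reader is a minimal parser for the
`_Atom_chem_shift` loop of v3 depositions; only H, N, C, CA, CB shifts are
retained (others warn and skip), duplicates are an error, and residue
counting is exposed under both conventions (at least one retained shift
vs all five types), since "assigned residues" is ambiguous between them.
Result tables are TSV and summaries JSON, byte-deterministic unless a
timestamp is explicitly requested.

## Problem sizes and numerical choices

Analysis defaults were chosen so the full test suite and the acceptance
script each complete in minutes on a single core: recovery tests use
5000–10000 frames where a standard error matters, 200–500 frames where
only invariance or geometry is at stake, and clustering strides
concatenated trajectories to ≤ 150 pseudo-frames before building the O(n²)
RMSD matrix. Pairwise RMSD on truly identical frames returns ~1e-7 Å
rather than exactly 0 (float64 cancellation); tolerances treat anything
below 1e-5 Å as zero, far below the 1e-3 Å PDB coordinate precision.
Equilibration trimming removes frames with time < 100 ns when frame times
exist (so a uniform 0–1000 ns trajectory retains 90% of frames), or a
fixed leading fraction otherwise.
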