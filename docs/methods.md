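# Methods

This note records what the package computes, the assumptions behind each
stage, the defaults and why they were chosen, and what the synthetic-data
generators do and do not emulate.

## Ensemble geometry

**Superposition.** Rigid-body fits use the Kabsch construction: SVD of the
covariance of the centred selections, with the determinant sign corrected so
reflections are excluded (det R = +1). Selections must contain ≥ 3
non-collinear atoms; collinearity is detected by a rank test on the centred
coordinates (tolerance 1e-8). Pairwise minimum RMSD over a frame stack uses
the singular-value form `msd = (‖A‖² + ‖B‖² − 2(σ₁+σ₂±σ₃))/n` and is computed
blockwise (≤ 2·10⁶ frame pairs per block, ≈ 150 MB of covariance stack) so
the memory bound is explicit rather than quadratic in the number of frames.

**RMSF.** Frames are superposed onto the ensemble mean, and the mean is
refined once (superpose → re-average → re-superpose) so the reference is
self-consistent; a single pass would leave the reference dependent on the
arbitrary initial frame orientation. The residue
value is the RMS over its selected atoms (default backbone N, CA, C, O) of
the per-atom fluctuation. For isotropic per-coordinate noise σ the
expectation is σ√3; superposition absorbs 6 rigid degrees of freedom, biasing
the estimate low by roughly `1 − 6/(3·n_atoms)`, which is why recovery checks
use ≥ 25 residues (100 backbone atoms, ≈ 1% bias).

**SASA.** Shrake–Rupley with a deterministic golden-angle spiral lattice
(default 1200 points, probe 1.4 Å) rather than random sphere points, so
results are bit-reproducible across platforms. A point on atom *i*'s expanded
sphere is accessible iff it lies outside every other expanded sphere;
neighbours are prefiltered by centre distance. Default van der Waals radii
(Å): C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 — a Bondi-like set,
overridable per call. Unknown elements raise rather than defaulting silently.

**Hydrophobic-surface series.** Per frame, full-structure SASA summed over
residues that are both in the hydrophobic class (default ALA, VAL, LEU, ILE,
PRO, PHE, MET, TRP; configurable) and inside a caller-supplied region. The
region is a required scientific input for pocket-scale analyses: a
single-patch hydrophobic area (tens of Å²) is far below whole-protein scale,
so defaulting to the full protein would silently answer a different question.
Ties in the maximum go to the lowest frame index.

**Clustering.** Leader (GROMOS-style) clustering on pairwise superposed
backbone RMSD: the unassigned frame with the most unassigned neighbours
within the cutoff (default 2.0 Å) becomes a centroid and claims its
neighbours; ties go to the lowest frame index, making the partition
deterministic given frame order. Clusters are reported by occupancy
descending. The representative conformation is the centroid of the
most-populated cluster.

**Subsampling.** Time-equidistant selection always keeps frame 1; with
stride *s* the selected 1-based frames are 1, 1+s, …, and the timestep
metadata scales by *s*. A 200 ns trajectory stored at 0.2 ps/frame thinned to
one frame per 200 ps yields exactly 1000 frames.

## Pocket availability

**Distance metric.** "How far is this pose from the reference binding mode"
is measured as ligand heavy-atom RMSD to the reference pose after the pose's
frame is superposed onto the reference frame by the pocket's backbone atoms,
with no ligand re-fitting. This captures translation and orientation of the
ligand relative to the pocket while being insensitive to global tumbling.

**Propensity.** Per frame the lowest-score pose is kept (ties by model
index); a frame counts as binding-competent iff that pose is within the
distance cutoff (default 2.0 Å) **and** its score is at or below the
threshold (pipeline default: reference-pose score + 1 kcal/mol; the library
default is geometry-only). Propensity is monotone non-decreasing in both
cutoffs by construction. Pose grouping histograms the same best-pose
distances into fixed-width bins (default 2 Å) and reports per-group mean
score and distance, mirroring the group-then-compare-energies narrative of
ensemble docking.

**Toy docking engine.** A deliberately transparent stand-in for an empirical
docking program: rigid translations of the ligand centroid on a cubic grid
spanning the pocket bounding box, crossed with seeded rigid orientations,
scored by a soft-sphere clash penalty (quadratic below 2.6 Å, weight 10),
a distance-weighted contact reward (linear to zero at 4.5 Å, weight 0.4) and
an H-bond bonus (1 per polar pair within 3.5 Å). Only interatomic distances
enter, so scores are invariant under rigid motion of the complex. It exists
to make the pipeline exercisable and bit-reproducible end to end; externally
produced poses enter through the scored pose-file reader instead.

**Contacts.** H-bonds are detected geometrically without explicit hydrogens:
donor/acceptor heavy-atom pairs (typing from residue/atom-name templates)
within 3.5 Å whose angle at the donor — measured via the donor's
distance-inferred bonded antecedents (bond cutoff 1.8 Å) — is ≥ 120°; pairs
with no resolvable antecedent pass on distance alone. π-π contacts pair
protein aromatic-ring templates (PHE/TYR/HIS/TRP) with planar 5/6-cycles
perceived on the ligand from distance-inferred connectivity (out-of-plane RMS
< 0.15 Å), using a 5.5 Å centroid cutoff.

## Steady-state SPR

The bound equilibrium response follows the one-site hyperbola
`Req = Bmax·C/(Kd + C)`. Fits are nonlinear least squares with positivity
bounds, seeded by the Scatchard linearization `Req/C = (Bmax − Req)/Kd`
(linear fits of the Scatchard plot itself are known to bias parameters, so
the linearization is initialization only; degenerate Scatchard geometry
falls back to a median-concentration seed). A fit is **saturable** only if
the highest measured concentration reaches 2·Kd; otherwise the Kd is a trend
extrapolation and flagged **presumed**. The factor 2 is a configurable
convention: at C = 2·Kd the curve has reached ⅔ of Bmax, which is about the
least data support on which an asymptote estimate is credible.

Equilibrium extraction averages the final 10% of the injection window and
flags `non_plateau` when the least-squares slope there exceeds 0.05 RU/s.
Blank subtraction interpolates the reference trace linearly onto the active
grid and requires the reference recording to span it. The RU → surface
density conversion uses the dextran-chip convention 1 RU = 1 pg/mm², giving
`density [fmol/mm²] = RU × 10³ / M [Da]`; competition experiments report the
signed percent change `100·(Req_mix − Req_alone)/Req_alone`, so −50 means
half the binding is lost. Kinetic (kon/koff) fitting is intentionally not
implemented — the analysis is steady-state; the kinetic model lives only in
the generator.

## Correlation and report

With a handful of ligands, asymptotic correlation p-values are invalid, so
inference is by exact permutation: all n! pairings are enumerated for n ≤ 8
(seeded Monte-Carlo with 20,000 draws beyond that), one-sided for positive
association, with the identity pairing always counted so p ≥ 1/n!. The
report states this floor explicitly: at n = 4 no association can beat
p = 1/24 ≈ 0.0417. Both Pearson and Spearman are reported since the
appropriate scale (linear response vs rank concordance) is a scientific
choice the data rarely settle at this n. "Maximal RU bound at equilibrium"
maps to fitted Bmax for saturable ligands and to the highest-concentration
Req (with the `presumed` flag visible) otherwise. Non-determinable ligands
are excluded from the correlation and listed as non-binders; ligands present
in only one analysis block produce a warning, not an error.

## Synthetic data: what it emulates, and what it does not

Trajectories are an ideal α-helical backbone template (rise 1.5 Å, twist
100°, Cα radius 2.3 Å; N/C/O at fixed plausible offsets) plus i.i.d. Gaussian
displacements scaled by per-residue σ, optionally with a Bernoulli two-state
displacement of a pocket-lining residue subset. This gives closed-form
targets (RMSF = σ√3, known open-frame lists, known cluster fractions) without
a molecular-dynamics engine, and that is all it gives: there is no covariance
between atoms, no bonded geometry preservation, no solvent, no force field.
Passing recovery tests therefore demonstrates the estimators, not the
realism of the ensemble. Pose sets plant a Bernoulli bound state per frame
(bound: reference pose shifted ≤ 0.5 Å, score below threshold; unbound:
shifted ≥ 6 Å, score above), expressed in each frame's own coordinate system
via the pocket-backbone transform, exactly as a docking engine would report
them. Sensorgrams use the closed-form 1:1 association/dissociation solution
with additive Gaussian noise and linear drift; real SPR artifacts (bulk
shifts, spikes, mass transport, solvent mismatch) are out of scope. All
generators run on NumPy's PCG64; a fixed seed reproduces bit-identical data,
and the seed is recorded in every truth record.

Default study conditions: per-residue σ 0.3 Å within states, two-state
pocket open 30% of frames displaced 5 Å, planted bound fractions
0.48/0.22/0.15/0.15 over the ensemble, Kd values 24.2/40.3/99.3/197.9 μM at
1% Rmax noise with 8 concentrations spanning Kd/4–8·Kd (the weakest binder
probed only to Kd/5, exercising the presumed path), one non-binder, and
competition effects of +94.3% and −50%.

## Problem sizes and numerical checks

The test suite and the acceptance script run scaled ensembles chosen so each
statistical check has adequate power on one CPU: 10,000 frames × 25 residues
for the σ√3 law (sampling error and superposition bias both ≈ 1%), 5,000
frames for amplitude rank recovery, 20 × 300-frame replicates for two-state
clustering (the mean recovered occupancy has SD ≈ 0.5 points), 100 × 1,000
frame replicates per planted fraction for propensity coverage, and 100
replicate isotherms for Kd error. The superposition oracle in the tests is a
brute-force rotation search: a 6° global Euler grid refined locally in
rotation-vector coordinates (no gimbal degeneracy) down to 0.5° steps;
test cases use 0.2–0.5 Å coordinate noise because below that the 0.5° grid's
own discretization error exceeds the 1e-3 Å agreement bound, and the check
would measure the grid rather than the superposition.

## Known limitations

* The toy docking score is not an affinity model; it ranks placements, and
  its coefficients are conventions, not calibrated quantities.
* Ligand ring perception handles isolated planar 5/6-cycles only (no fused
  aromatic perception beyond sharing atoms across cycles, no aromaticity
  model).
* H-bond typing is template-based on standard residues; modified residues
  fall back to backbone donors/acceptors only.
* The one-site fit assumes a single class of non-interacting sites;
  heterogeneous or bivalent binding will fit poorly and is not modelled.
* Leader clustering is order-deterministic but, like all greedy leader
  schemes, not invariant under frame permutation when neighbour counts tie.
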