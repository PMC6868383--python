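# Methods

This note records the models, conventions and numerical choices behind
`triacyl`, in the spirit of a methods appendix: what each stage computes,
which parameters matter, what the synthetic generator does and does not
emulate, and where genuinely open design choices were resolved.

## Containers and units

Everything is in ångström (PDB native); time per frame is metadata only and
never enters a computation. An `Ensemble` couples a `(n_frames, n_atoms, 3)`
coordinate array to a `Topology` whose named atom groups drive all geometry:
`nuc_backbone` (P, OP1, OP2, O5′, C5′, C4′, C3′, O3′, C2′, O2′, C1′, O4′ per
nucleotide, as present), `aa_backbone` (N, CA, C), `base1/2/3` (remaining
heavy atoms of each nucleotide), `sidechain` (amino-acid heavy atoms beyond
the backbone and carbonyl oxygen), and `carbonyl`. The derived
`cluster_backbone` group is the union of nucleotide and amino-acid backbones
for aminoacylated systems and the nucleotide backbone alone for free
trinucleotides. Group definitions are fully overridable in the config by
(residue index, atom name) pairs; hydrogens are excluded from all default
groups. Frames are 0-based in memory, MODEL numbers 1-based on disk.

Open choice: which atoms constitute "the carbonyl group" for SASA. The
default is the ester carbonyl carbon plus its carbonyl oxygen (two heavy
atoms), configurable; including the ester oxygen would systematically raise
the absolute SASA but barely affect relative comparisons.

## SASA and relative carbonyl exposure

Shrake–Rupley with a deterministic golden-spiral point lattice (196 points
per sphere by default) rather than randomized dots, so results are exactly
reproducible at fixed n. A point on atom *i*'s solvent-expanded sphere
(radius r_i + probe, probe 1.4 Å) is accessible iff it lies outside every
other atom's expanded sphere; only atoms within r_i + r_j + 2·probe are
tested. Radii default to the Bondi set (C 1.70, N 1.55, O 1.52, P 1.80,
S 1.80, H 1.20 Å), overridable per atom name.

Quadrature error at 196 points: the isolated-sphere value is exact by
construction; for overlapping pairs the deviation from the spherical-cap
closed form is one to two percent, and whole-cluster totals vary by up to
~2% with molecular orientation (below 0.5% by ~2000 points). The per-frame
exposure statistic divides the summed carbonyl-group SASA by a
normalization constant — 48.4 Å² by default, the maximum carbonyl SASA
observed in the reference simulations of aminoacylated trinucleotides — or,
in `dataset-max` mode, by the maximum over all ensembles of the current run
(making the dataset-wide maximum exactly 1). Values above 1 under a fixed
constant are reported and counted (`n_exceeding_unity`), never clipped.

## Superposition and RMSD

Kabsch superposition via SVD with determinant sign correction, so only
proper rotations are returned (chiral mirror images retain a positive
residual); no mass weighting anywhere, matching the unweighted
center-of-geometry conventions of the contact criteria. The pairwise RMSD
matrix is computed from batched 3×3 cross-covariance SVDs; the trace
formula incurs ~1e-7 Å cancellation noise, and the matrix is explicitly
symmetrized with a zeroed diagonal. The O(n²) cost is capped at 20 000
frames with a hard error directing the caller to subsample first.

## Clustering, state assignment, preference

`gromos_cluster` implements the greedy neighbor-count scheme of Daura et
al.: the unassigned frame with the most neighbors within the cutoff
(default 0.5 Å backbone RMSD) seeds a cluster, it and its neighbors are
removed, and the step repeats. Tie-breaks are deterministic (lowest frame
index); clusters are ordered by decreasing size, then ascending center
index. Each cluster records both its greedy `center_frame` and its
`middle_frame` — the member with the smallest mean RMSD to all members.
The middle frame is the representative written out and used as the state
reference, mirroring the behaviour of the standard clustering tools, and it
is statistically the better estimate of the underlying state geometry: in a
jittered cluster the max-neighbor frame sits on the noise shell while the
medoid concentrates near its center.

`assign_states` labels each frame collapsed/extended/other by backbone RMSD
to the two references with a 1.5 Å shell: inside exactly one shell takes
that label; inside both takes the nearer reference, an exact tie resolving
to collapsed (the dominant state); outside both is "other". With an
unbounded cutoff no frame is labelled other.

The conformational preference is −ln(f_collapsed / f_extended), natural log
as befits a free-energy proxy. The sign convention makes the statistic
positive when the extended state dominates, so it correlates positively
with carbonyl exposure (extended ⇒ exposed) and negatively with
sidechain–base-2 contact frequency (contact ⇒ collapsed). A zero occupancy
makes the statistic undefined: it is reported as NaN with a flag, never
pseudo-counted, and downstream statistics drop such rows listwise with a
logged count.

Coordinate PCA diagonalises the 3m×3m covariance of the selected atoms
after one round of Kabsch fitting to the ensemble-mean structure (the mean
is then recomputed once). The fitting reference is an open choice in the
upstream tools; fitting to the ensemble mean is the deterministic choice
made here.

## Interaction criteria

Base–base stacking: center-of-geometry distance strictly below 5 Å.
Sidechain–base contact: strictly below 8 Å. Boundary-equal distances do not
count. COGs are unweighted means over the heavy atoms of the configured
groups (base groups exclude sugar/phosphate); no periodic imaging is
applied, as ensembles are single molecules. The simultaneous statistic
`sc_b1_and_b2` counts frames in which both sidechain–base distances are
below 8 Å in the same frame, and is therefore bounded by the smaller of the
two marginal frequencies. Free trinucleotides report stacking frequencies
with sidechain fields marked not-applicable.

## Regression layer

Pearson p-values come from the two-sided t-test,
t = r·sqrt(n−2)/sqrt(1−r²) on n−2 degrees of freedom, evaluated through the
regularized incomplete beta function. Multiple regression always contains
an intercept; its F-test compares against the intercept-only model. The PRE
of predictor j is computed by two explicit fits (full model and the model
with j removed, both with intercept) as (RSS_reduced − RSS_full) /
RSS_reduced; for a single predictor it reduces to R². The correlation
screen stratifies (e.g. by attachment or CCA/non-CCA), flags strata with
fewer than three complete observations or constant columns as
not-computable instead of erroring, and drops NaN rows per cell. Predictor
order is fixed as (sc_b1, sc_b2, sc_b3, stack12, stack23, stack13). No
multiple-testing correction is applied; raw two-sided p-values are reported
with the n of every cell.

## Synthetic-ensemble generator

The generator provides ground truth for every statistic above by sampling
mixtures of deterministic pseudo-atomic templates:

- **Resolution.** ~12 backbone pseudo-atoms per nucleotide, a planar
  6-atom base ring (plus 3 in-plane atoms for purines), and an amino acid
  with N/CA/C/O plus 1–10 sidechain pseudo-atoms scaled by residue size.
  This is sufficient for COG distances, backbone RMSD and carbonyl SASA; no
  energetic or chemical realism is claimed.
- **Template geometry.** The collapsed template stacks bases 1–2
  (COG < 5 Å), flips base 3 out (> 5 Å) and folds the sidechain onto base 2
  (< 8 Å) with a partly buried carbonyl; the extended template stacks all
  three bases with the sidechain > 8 Å from every base and an exposed
  carbonyl. The two differ by > 3 Å backbone RMSD, keeping them separable
  at the 1.5 Å assignment shell. 3′ variants orient the carbonyl outward,
  so the collapsed-state carbonyl SASA is higher for 3′ than for 2′
  attachment on an identical nucleotide scaffold; D-chirality mirrors the
  sidechain placement through the CA plane; free systems omit the amino
  acid. A collapsed-inverted template (bases 2–3 stacked, base 1 out, its
  own backbone fold) is provided for multi-reference experiments.
- **Jitter convention.** `jitter_sigma` is the per-atom RMS displacement in
  Å: each coordinate receives independent Gaussian noise of standard
  deviation sigma/sqrt(3), so a jittered frame sits at ≈ sigma backbone
  RMSD from its template and two same-state frames at ≈ sigma·sqrt(2) of
  each other. At the default sigma = 0.3 Å same-state frame pairs therefore
  fall inside the 0.5 Å cluster perimeter while cross-state pairs stay far
  outside it.
- **"Other" conformers** interpolate between the two templates (mixing
  factor uniform in [0.3, 0.7]) with 3× jitter and are re-sampled (up to 50
  attempts) if they enter a 1.6 Å backbone shell of either template, so
  ground-truth labels remain consistent with the 1.5 Å assignment rule by
  construction. An optional per-frame rigid scramble (random proper
  rotation, translation uniform in ±20 Å) verifies superposition
  invariance downstream.
- **Cross-system tables** plant a linear model: predictors uniform on
  [0, 1], response = intercept + Σ slope·predictor + Gaussian noise, strata
  assigned round-robin. `demo_system_specs` spans mixture weights from
  extended- to collapsed-dominated so that cross-system correlations
  (contact ↔ exposure ↔ preference) have signal.

What passing tests on this generator show — and what they do not: the
pipeline provably recovers planted mixtures, contacts and regression
structure under Gaussian positional noise and rigid motion, but real MD
ensembles have correlated, anharmonic fluctuations, intermediate states and
solvent effects the generator does not emulate, so recovery rates measured
here are upper bounds, not field performance claims.

## Pipeline

The orchestrated run joins all 2′ systems (and separately all 3′ systems)
on the cluster backbone, subsamples by a configurable stride, clusters at
0.5 Å, writes the top-two middle structures, assigns every system's frames
against them at 1.5 Å, computes exposure under one shared normalization and
the seven contact frequencies, assembles the per-system table (merging
optional annotation CSVs such as hydrolysis half-lives or affinity scales
on the system key), and runs the correlation screen, the six-predictor
exposure regression and per-predictor PRE. For synthetic systems the two
master centers are mapped to collapsed/extended by proximity to the
generator templates; for external ensembles the most populated cluster is
taken as collapsed, following the empirical dominance of that state. Every
output carries a header with version, parameters and seed; reruns at the
same seed are byte-identical. Stage failures abort with the stage named and
a MANIFEST marking completed outputs.

Default problem sizes (demo config and acceptance runs) are a few hundred
to two thousand frames per system — enough for the recovery tolerances
quoted in the tests while keeping the pairwise-RMSD stage at the
sub-minute scale on a single CPU.

## Known limitations

- The pairwise RMSD matrix is dense O(n²); master ensembles beyond the
  20 000-frame cap must be subsampled (the intended workflow).
- SASA at 196 points carries percent-level quadrature noise; comparisons
  across orientations or tiny SASA differences need a finer grid.
- The collapsed/extended dichotomy is a two-reference model; additional
  states (e.g. the collapsed-inverted fold) require supplying further
  references and are not part of the default pipeline.
- Binary trajectory formats (XTC/DCD) are out of scope; the reference
  interchange format is multi-model PDB.
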