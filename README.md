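# triacyl

Conformational-ensemble analysis of aminoacylated RNA trinucleotides.

When an amino acid is esterified to the 2′- or 3′-hydroxyl of the terminal
ribose of an RNA trinucleotide (the minimal model of a charged tRNA 3′-end),
the conformational dynamics of the conjugate control how exposed the
aminoacylester carbonyl is to solvent — and hence how susceptible the ester
bond is to hydrolysis. Such conjugates interconvert between two recurring
backbone states: a **collapsed** conformation (bases 1–2 stacked, base 3
flipped out, the sidechain folded back onto base 2, carbonyl partly buried)
and an **extended** conformation (all three bases stacked, sidechain
solvent-directed, carbonyl exposed). `triacyl` provides the complete
statistical toolchain for quantifying this picture from conformer ensembles,
for structural bioinformaticians working with multi-model PDB ensembles
(e.g. subsampled MD trajectories):

- **Relative carbonyl exposure** — Shrake–Rupley SASA of the ester carbonyl
  group (probe 1.4 Å, 196 grid points per sphere, Bondi radii), normalized
  by a reference constant of 48.4 Å² (or a dataset-wide maximum) to a value
  in [0, 1].
- **State decomposition** — greedy neighbor-count (GROMOS-style) clustering
  of a joined master ensemble at a stringent 0.5 Å backbone-RMSD cutoff,
  then per-frame assignment to the two top cluster representatives within a
  1.5 Å shell, giving occupancies `f_collapsed`, `f_extended`, `f_other` and
  the conformational preference
  `−ln(f_collapsed / f_extended)` — a free-energy-difference proxy that is
  positive when the extended state dominates.
- **Interaction profiling** — center-of-geometry criteria for base–base
  stacking (< 5 Å) and sidechain–base contact (< 8 Å), reported as per-ensemble
  frequencies.
- **Statistics** — Pearson correlations with two-sided t-test p-values,
  multiple OLS regression with an F-test against the intercept-only model,
  and the Proportional Reduction in Error (PRE) of each predictor,
  `PRE_j = (RSS_without_j − RSS_full) / RSS_without_j`.
- **Synthetic ensembles** — a generator that emulates the mixture structure
  above with pseudo-atomic templates, controllable mixture weights, per-atom
  Gaussian jitter and rigid-body scrambling, returning ground-truth labels
  for every frame (see `docs/methods.md`).

Coordinate I/O is multi-model PDB; all parameters live in a single YAML
config; outputs are TSV/CSV/JSON with provenance headers.

## Worked example

```python
import numpy as np
from triacyl import (SystemDescriptor, SynthSpec, build_templates,
                     generate_ensemble, gromos_cluster, assign_states,
                     carbonyl_exposure, contact_profile)

system = SystemDescriptor("CCA", "ALA", "2p", "L")     # CCA-2'-L-alanine
lib = build_templates(system)
spec = SynthSpec(weights=(0.45, 0.25, 0.30), jitter_sigma=0.3,
                 n_frames=400, seed=11)
ensemble, truth = generate_ensemble(lib, spec)

bb = np.asarray(lib.backbone_atoms)
clusters = gromos_cluster(ensemble, bb, cutoff=0.5)
print("top cluster sizes:", clusters.sizes[:3])
state = assign_states(ensemble, lib.collapsed[bb], lib.extended[bb], bb, cutoff=1.5)
print("fractions: collapsed=%.3f extended=%.3f other=%.3f" % state.fractions)
print("preference: %.3f" % state.preference)
series = carbonyl_exposure(ensemble, normalization=48.4)
print("mean relative exposure: %.3f" % series.mean_relative_exposure)
p = contact_profile(ensemble)
print("sc_b2=%.3f stack23=%.3f stack12=%.3f" % (p.freq_sc_b2, p.freq_stack23, p.freq_stack12))
```

prints

```
top cluster sizes: [199, 92, 1]
fractions: collapsed=0.497 extended=0.230 other=0.273
preference: -0.772
mean relative exposure: 0.608
sc_b2=0.680 stack23=0.270 stack12=1.000
```

The two large clusters are the collapsed and extended states (the remaining
frames are unstructured singletons); the assigned fractions match the
generator's ground-truth labels exactly at this jitter level (the deviation
from the planted weights 0.45/0.25 is the sampling noise of 400 draws).
The negative preference says the collapsed state dominates; with ~68% of
frames holding the sidechain on base 2 and a partly buried carbonyl, the
mean relative exposure sits at 0.61 rather than near the extended-state
level.

The same stages run from the shell over PDB ensembles:

```bash
triacyl synth --weights 0.45 0.25 0.30 --n-frames 400 --seed 11 --out ens.pdb
triacyl exposure --in ens.pdb --norm 48.4 --out exposure.tsv
triacyl cluster --in ens.pdb --cutoff 0.5 --out clusters.tsv
triacyl run --config demo.yaml          # full multi-system pipeline
```

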