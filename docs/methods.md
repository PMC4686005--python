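# Methods

## Model and assumptions

The diagnosis framework rests on a single assumption: an atlas is locally
more similar to the target image where both share the same clinical
condition, because condition-specific morphology (here, great-vessel
topology after different surgical repairs) cannot be absorbed by the
inter-subject registration. Both methods in the package operationalise that
assumption with the local normalised correlation coefficient and differ
only in how the per-atlas similarity evidence is aggregated:

* **VoxAR** pools the per-voxel similarity ranking across *all* databases
  and assigns each ROI voxel to the condition holding an absolute majority
  of the top-`T` slots; the diagnosis is the mode of the assignment
  histogram.
* **ISA** aggregates *within* each database first (rank-weighted intensity
  fusion into a synthetic image) and compares globally via NCC. Because the
  rank weighting favours the best-registered atlases, it partially
  compensates for exactly the morphological mismatch the framework wants to
  detect — which is why the voxelwise method is the package's core and ISA
  the reference.

## Similarity computation

Local moments are Gaussian-convolution moments: `mean = G_σ * I`,
`var = G_σ * I² − mean²` (clamped at 0), `cov = G_σ * (I·J) − mean_I·mean_J`,
with `σ_G = 2` voxels by default (small enough to resolve vessel-scale
differences) and the kernel truncated at 4σ (relative error < 1e−4).

Numerical choices:

* **Boundary rule.** Zero padding with renormalisation by the convolved
  all-ones field, i.e. near the grid edge the Gaussian weights are
  renormalised over in-grid voxels. This avoids edge attenuation inside the
  ROI; the brute-force oracle in the tests implements the same rule
  independently and agrees to ≤ 1e−5.
* **Flat regions.** Where `σ_I σ_J < 1e−6 × (intensity range)²` the
  correlation is a 0/0 form; such voxels are flagged undefined, carry NaN,
  and are excluded from all downstream ranking. Ranks at a voxel are taken
  among the atlases defined there.
* LNCC keeps its sign: anticorrelated atlases rank last, by design.
* z-score normalisation (used before fusion and before the global NCC) uses
  the population standard deviation over ROI voxels; out-of-ROI voxels are
  transformed with the same affine map. Since NCC is affine-invariant,
  z-scoring the target as well as the atlases is neutral; it is done for
  reproducibility of intermediate images.

## Rating rule

The absolute-majority guard is implemented exactly as the ceiling formula
`t* = ⌈T/2 + 1⌉`, computed in integer arithmetic as `(T + 1)//2 + 1`
(T = 7 → 5). Two consequences are worth stating because they are easy to
miss:

* since `t* > T/2`, a tied argmax can never be assigned — asserted on every
  rating map;
* a database with fewer than `t*` atlases can never win a voxel, so for
  `T = 7` balanced databases of ≤ 4 atlases refuse every diagnosis. This is
  the printed rule's faithful behaviour; the threshold is exposed
  (`majority_threshold`, config override) for sensitivity analyses. Note the
  tension with the words "absolute majority", which for 7 would be 4; the
  formula is what is implemented.

Tie-breaking everywhere (within-database ranking, pooled ranking, histogram
argmax, NCC argmax) is deterministic: stable by (condition name, atlas
index), with NCC/histogram ties resolved by condition-name order and logged.
Rank origin is 0 (best atlas), so the best weight is `e⁰ = 1`; starting at 1
would rescale all weights by `e^(−β)`, which cancels in the normalised
average and is therefore diagnosis-neutral.

A voxel where fewer than `T` atlases are defined contributes
`min(T, #defined)` top slots; an all-undefined voxel stays unassigned.
An all-unassigned rating map yields an empty histogram and an explicit
refusal status rather than a guess.

## Registration

Experiments run with the identity backend on phantoms sharing a grid, so
measured performance is attributable to the rating machinery. A built-in
12-parameter affine backend (translation/rotation/log-scale/shear,
NCC-maximising Powell search over a 3-level pyramid, linear image and
nearest-neighbour mask resampling, identity fallback with a warning when the
optimum does not beat identity) covers pre-alignment of real data; a
deformable engine can be plugged in through the external-command contract,
whose configuration carries the validated two-stage parameter set
(coarse-to-fine levels 3, rigid/affine/non-rigid iteration caps 5/8/300,
bending energy 0.005, NMI). Atlases are registered atlas→target directly —
equivalent in intent to registering the target to each atlas and inverting,
without needing the inversion.

## Phantom generator

The generator emulates the statistical structure the method assumes, not MR
physics. Each subject is a condition template (outer envelope ellipsoid =
ground-truth mask; bright body ellipsoid; two tube vessels whose arrangement
encodes the condition — parallel, crossed, or parallel-plus-baffle; an extra
wide-set large-calibre morphology for missing-pathology probes) warped by a
random smooth displacement field, modulated by a smooth bias field, plus
Gaussian noise over a textured background.

Defaults (the study conditions for all shipped experiments): 48³ grid at
1.5 mm isotropic; deformation amplitude 2.5 voxels (about one vessel radius
— within-condition anatomical variability of the same order as the
between-condition differences, which is what makes the diagnosis problem
non-trivial) with smoothness 5 voxels; noise σ = 8 against a
structure/background contrast of ≈ 80 (SNR ≈ 10); 10% multiplicative bias.
The envelope is shared across conditions so that the cross-condition ROI
intersection retains the vessel region where the discriminative signal
lives. Bit-exact determinism under (spec, condition, seed) is tested.

What the phantoms do **not** model: acquisition physics (k-space, coils,
flow), anisotropic resolution, genuinely large deformations, and real
anatomical variability; passing phantom experiments therefore demonstrates
the correctness and the qualitative behaviour of the rating machinery
(size/imbalance/missing-pathology trends), not clinical accuracy.

## Experiment harnesses and problem sizes

All experiments reuse one LNCC evaluation per (target, atlas) pair across
atlas subsets, which makes repeated subsampling cheap. Shipped designs and
their default desk-scale sizes, chosen so the whole suite runs in minutes:

* leave-one-out comparison of VoxAR vs ISA on 3 × 10 subjects at 48³;
* balanced size sweep (a balanced repeated subsampling scheme: per repeat,
  `s` atlases per database drawn uniformly without replacement, excluding
  the target), sizes 3–10 on a 3 × 11 cohort, 10 repeats;
* unbalanced studies at cohort size 10: minority (correct = 5, others 9/9)
  against the balanced-5 baseline, majority (correct = 9, others 5/5)
  against balanced-9 — the baseline is always balanced at the *correct*
  database's size;
* missing-pathology probe: 4 targets of the held-out morphology against
  3 × 8 known databases, with leave-one-out known-condition baselines.

Metrics: overall accuracy over all conditions; sensitivity, specificity,
PPV and NPV for the pathological-vs-normal dichotomy ("normal" is the
negative class; a refused diagnosis does not flag pathology and hence counts
against sensitivity); row-normalised confusion matrices. Full determinism
under a master seed is tested.

## Known limitations

* The rating histogram is a confidence proxy, not a calibrated posterior.
* Conditions absent from the databases cannot be identified, only flagged
  indirectly through low histogram separation.
* The built-in affine backend is deliberately simple (no deformable model);
  real-data use is expected to go through the external backend.
* With the printed majority rule, small databases (< ⌈T/2+1⌉ atlases) make
  the method refuse; choose `T` commensurate with database size.
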