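# Methods

This note records the model implemented by `jointale`, the choices made where
the protocol left room, and what the synthetic-data tests do and do not
establish.

## Coordinate normalization

The working space is Talairach. Three input dialects are recognized:

* `tal` — native Talairach; passed through unchanged.
* `mni` — MNI/ICBM; mapped with the Lancaster `icbm2tal` affine.
* `tal_brett` — "Talairach" produced by the Brett `mni2tal` approximation;
  inverted back to MNI with the exact Brett inverse, then mapped with
  `icbm2tal`. This replaces the older piecewise approximation with the
  better-validated affine while honouring how the coordinates were actually
  produced.

**Lancaster variant.** Several `icbm2tal` fits exist, differing by the
template orientation of the software whose normalization they were fitted to.
The package pins the SPM-oriented matrix (`icbm_spm2tal`), frozen in
`transforms.py`; the variant name is recorded in every run manifest. The
FSL-oriented fit is not shipped — mixing variants silently is worse than
supporting one explicitly.

**Brett branch selection.** The forward map uses the published z ≥ 0 and
z < 0 matrices, selected by the sign of the MNI z (the branches agree on the
plane z = 0). The inverse selects the branch by the sign of the *recovered
MNI* z rather than the Talairach z: in the recovered z-component the y-terms
of the two branch inverses cancel identically, so this candidate always has
the same z-sign as the true MNI point and the inverse is exact everywhere —
including points near the AC plane whose Talairach z changed sign under the
forward map, where a Talairach-z rule would mis-select the branch.

Coordinates are validated against a 120 mm sanity bound per axis, which
catches voxel-index/mm confusion without rejecting any real stereotactic
coordinate.

## Likelihood maps

* **Kernel.** Isotropic Gaussian, FWHM 8 mm (σ ≈ 3.397 mm), configurable.
  The per-voxel hit probability is density at the voxel centre × voxel
  volume; the difference from analytic integration over the voxel cube is far
  below grid error at 2–4 mm voxels. The kernel is truncated at 4σ
  (≈ 13.6 mm), discarding < 1e-4 of its mass while bounding each focus's
  support to a small patch.
* **Study map.** Union of the per-focus hit events,
  `1 − Π (1 − p_f)` — adding a focus can never decrease the map, and values
  stay in [0, 1].
* **Condition mean, joint.** Voxelwise mean over a condition's study maps;
  joint = sum of the two condition means (range [0, 2]). Averaging before
  summation equalizes the two conditions regardless of how many foci each
  reported.
* **Grid.** 2 mm isotropic over x ∈ [−70, 70], y ∈ [−104, 68],
  z ∈ [−50, 78] mm by default. The acceptance simulations run at 4 mm: the
  method's statistics (calibration, attribution ratios) are grid-resolution
  invariant to well within their tolerances, and the coarser lattice keeps
  20-replicate ensembles to minutes on one CPU.
* **Mask.** A user-supplied NIfTI mask on the analysis grid, or a built-in
  procedurally generated ellipsoid inscribed in the bounding box (95% of the
  half-spans). The ellipsoid is a smooth stand-in, adequate wherever only the
  in-mask volume and compactness matter (simulation, null calibration); real
  analyses should supply a template grey-matter mask.

## Inference

* **Null model.** Absence of spatial association between studies: every
  focus is relocated to an independent uniform-random in-mask voxel centre,
  preserving per-study focus counts and per-condition study grouping, and the
  full study → mean → joint pipeline is recomputed. This is the canonical
  coordinate-based-meta-analysis null.
* **Pooled null.** Each permutation's in-mask joint values are pooled into
  one null distribution. Small runs keep the raw sample (exact p-values);
  beyond 4×10⁷ pooled values a 200,000-bin histogram on [0, 2] takes over,
  conservative by at most one bin's occupancy (bin width 1e-5). Voxelwise
  nulls at 10,000 permutations would be memory-prohibitive and buy nothing
  under a spatially homogeneous null.
* **p-values.** Add-one estimator `p = (1 + #{null ≥ obs}) / (1 + N)`:
  a valid permutation p-value that can never be zero.
* **FDR.** Benjamini–Hochberg step-up over all in-mask voxels at q = 0.05
  (delegated to statsmodels, cross-checked against a hand-computed example).
  No dependency correction — BH is the field default.
* **Clusters.** Connected components at 26-connectivity (6/18 selectable);
  volume strictly greater than 100 mm³; sorted by volume. A study *supports*
  a cluster if any of its foci lies within the kernel truncation radius of
  any cluster voxel — beyond that radius a study contributes no kernel mass
  and cannot have generated the signal. Clusters supported by fewer than two
  distinct studies are dropped, so no single study can manufacture a finding.
* **Directions.** Deficit and excess foci are analysed in two fully
  independent runs (separate nulls, separate seeds derived as seed + run
  index).

## Contribution statistic

For a retained cluster the two condition mean maps are **integrated over the
cluster's voxels** and expressed as percentages of their sum. Reading the
ratio at the peak voxel instead is available via
`contribution_mode: "peak"`; integration was chosen as the default because it
is stable for small clusters and both variants agree exactly in the
interpretive anchor cases (single-condition → 100/0, identical maps → 50/50).
The percentages always sum to 100 (to 1e-9) whenever the cluster carries any
joint mass; a zero-mass cluster raises a degenerate-cluster error rather than
returning an arbitrary split. The shared/dominant colour-coding band
(both ≥ 20% → "shared") is presentation only, not part of the statistic.

## Synthetic corpora

The generator emulates the corpus shape of a two-condition VBM foci
meta-analysis: 14 + 11 studies, ~250–400 total foci split roughly 60/40
between conditions, 3–20 foci per study. True effects are *effect centres*
(fixed mm locations reported by each study with a per-condition probability,
displaced by 6 mm-SD Gaussian jitter and rejection-sampled into the mask)
plus 2–6 uniform in-mask noise foci per study. Jitter of 6 mm sits between
the voxel size and the kernel FWHM — large enough to be realistic
between-study scatter, small enough for convergent clusters to form; the
noise foci force the FDR, volume and study-support filters to do real work.
A manifest attributes every focus to exactly one centre or to noise, so
recovery, localization error and attribution can be scored exactly.

What the simulations do **not** model: anatomically structured inter-study
correlation, sample-size differences between studies, publication bias, and
real grey-matter geometry (the mask is an ellipsoid). Passing recovery tests
therefore demonstrate the estimator's correctness and calibration under the
stated generative model, not field performance on any particular literature.

## Known behaviour and limitations

* **Power asymmetry of the joint design.** A condition-unique effect centre
  contributes only one condition's mean map — half the joint amplitude of an
  equally-reported shared centre — so at moderate planted effect strengths
  (10 studies, report probability 0.9) it is recovered in a majority but not
  all replicate runs, while shared centres are recovered essentially always.
  When a condition-unique cluster *is* retained, its attribution is
  recovered at ≥ 99% for the generating condition. This is inherent to
  summing condition means, not an implementation artefact; it mirrors the
  method's conservatism toward condition-specific findings.
* The histogram fallback of the pooled null makes large-run p-values
  conservative by ≤ one bin occupancy; all packaged analyses use the exact
  raw-sample path.
* Determinism: identical configuration and seed give byte-identical cluster
  tables and bit-identical maps; the run manifest records the seed and a
  SHA-256 hash of the full configuration, and every output file carries that
  hash (NIfTI `descrip` field, TSV comment header), so mixed-config outputs
  are detectable.
* Anatomical labelling of cluster centres (atlas lookup) is deliberately out
  of scope; the tables report coordinates, volumes, study support and
  percentages only.

## Acceptance problem sizes

The packaged acceptance computations use a 4 mm grid with the procedural
mask: 20 global-null datasets at 500 permutations for calibration and
false-positive control, 20 recovery replicates at 1,000 permutations for the
attribution checks, and 300-permutation paired runs for the determinism
check — sizes chosen so the full battery completes in a few minutes on a
single CPU while leaving the measured statistics' sampling error well inside
their tolerances.
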