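# Methods

This note documents the models, conventions, and numerical choices behind
`qmribids`, and what its synthetic tests do and do not demonstrate.

## Scope and conventions

The toolkit covers the fourteen entity-linked file collections of the qMRI
extension to BIDS — eight anatomy collections (MP2RAGE, MPM, VFA, IRT1,
MESE, MEGRE, MTR, MTS) and six transmit/receive field-mapping collections
(TB1DAM, TB1EPI, TB1AFI, TB1TFL, TB1SRGE, RB1COR). All fourteen are
described in the schema registry, generated by the phantom module, and
validated; nine (all but MPM, TB1EPI, TB1TFL, TB1SRGE, RB1COR) are also
fitted.

Units follow the convention's interchangeability rules and are never
converted implicitly: relaxation times in seconds, rates in 1/s, ratio maps
(MTRmap, MWFmap) in percent, susceptibility in ppm, transmit-field maps in
relative percent (100 = measured flip equals nominal). MTsat is reported as
the per-excitation saturation × 100, matching the percent-style convention
of the other ratio maps; because its acceptable range is anatomy-dependent,
no range check is enforced for it (nor for PD, stored as "arbitrary").
Angles are stored in degrees in metadata and converted to radians only
inside the models. Proton-density–style amplitudes (M0) are arbitrary units.

The schema registry is a declarative YAML file. Requirement levels printed
in the consensus document are tagged `source: paper`; levels encoded from
the normative BIDS qMRI appendix are tagged `source: appendix` and validate
at warning severity by default (error under `--strict`). The canonical
spelling of the spoiling-increment key is `SpoilingRFPhaseIncrement`, with
`RFSpoilingPhaseIncrement` accepted as an alias and canonicalized on read.

One deliberate deviation from a literal reading of the entity table: for
TB1AFI the two flip-indexed interleaves share a single nominal flip angle
and differ in repetition time, so the registry's per-suffix `distinct_field`
override requires `RepetitionTimeExcitation` (not FlipAngle) to be distinct
across the `flip` indices. Without this, every valid dual-TR acquisition
would be flagged as a duplicate-parameter error.

`MTState` is serialized as a JSON boolean (the BIDS convention); the
parameter table and validator map it onto the `on`/`off` label domain of the
`mt` entity and flag disagreement between label and metadata.

## Signal models

All forward models are pure, elementwise over arrays, homogeneous of degree
one in M0 (the UNI and AFI ratios are degree zero), and are exactly the
approximations their inverses assume — generator and fitter are
self-consistent by construction.

* **SPGR (VFA, MTR, MPM arms)**: S = M0 sin(b a)(1−E1)/(1−E1 cos(b a)),
  E1 = e^(−TR/T1), b the relative transmit field; verified against a
  10,000-pulse discrete recursion iterated to steady state (< 1e−9
  relative).
* **Inversion recovery**: signed S = M0(1 − 2e^(−TI/T1) + e^(−TR/T1));
  magnitude reconstruction is applied by the generator.
* **Monoexponential decay** for MESE (T2) and MEGRE (T2\*).
* **MP2RAGE**: each cycle stage — inversion (mz → −η mz, η the inversion
  efficiency, default 0.96, a convention the fitter shares), free recovery,
  and each excitation of the two GRE blocks — is affine in mz, so the
  steady state is the exact fixed point of the composed map,
  mz\* = B/(1−A). Signals are read at the central excitation of each block
  (linear k-space ordering assumed); |1−A| < 1e−12 raises a
  non-convergent-protocol error. The closed form agrees with 500 explicit
  cycle iterations to < 1e−10 over a 20-point (T1, protocol) grid.
* **Double angle**: S1 = M0 sin(b a), S2 = M0 sin(2 b a) in the long-TR
  regime (no T1 weighting).
* **AFI**: r = (1 + n cos(b a))/(n + cos(b a)) in the ideal-spoiling
  short-TR regime; a warning is raised when TR2 > 0.2 T1.
* **MTS**: rational small-angle SPGR, S = A α R1 TR/(α²/2 + δ + R1 TR),
  with δ = 0 for the mt-off arms.

MTR phantom convention: S_on = S_off (1 − f), so the ratio fitter recovers
100 f exactly. SpoilingRFPhaseIncrement is carried as metadata but
imperfect spoiling is not simulated; slice profiles, EPG/Bloch dynamics,
k-space and motion effects are out of scope.

## Fitters

Fitters are deterministic and pure (identical inputs give bit-identical
maps); unfittable voxels are NaN and excluded from the returned mask, with
counts in the diagnostics.

* **VFA**: linearized least squares on y = S/sin α vs x = S/tan α; slope =
  E1, so T1 = −TR/ln(slope), M0 = intercept/(1 − slope). Exact on noiseless
  data and deterministic; the known noise-induced bias of the linearization
  is accepted at desk scale. A B1+ map (percent) rescales α per voxel.
* **IRT1**: variable projection — for fixed T1 the model is linear in
  (a, b), so a bounded 1-D search over log T1 (tolerance 1e−12, bounds
  1 ms–20 s) with an exact linear solve per evaluation. For magnitude data,
  every candidate polarity (sign-flipping the first k samples) is fitted
  and the lowest residual kept. Identical voxel time-series are
  deduplicated before fitting (exact, a large win on piecewise-constant
  phantoms). Voxels pinned to the search bounds or with constant signal are
  masked.
* **MESE/MEGRE**: log-linear least squares weighted by the signal, which
  counters the heteroscedasticity introduced by the log transform; chosen
  over iterative NLLS for determinism. Non-positive signals mask the voxel.
* **MP2RAGE**: a UNI(T1) lookup on a configurable grid (default 0.05–5 s,
  1 ms step) is restricted to its maximal strictly monotonic sub-interval
  (with the default protocol UNI decreases with T1) and inverted by linear
  interpolation; out-of-span voxels are masked. Fit resolution equals the
  grid step.
* **DAM**: the ratio S2/(2 S1) is clamped to [−1, 1] — noise excursions
  are counted in diagnostics rather than masked, keeping the map dense.
  **AFI** instead masks |cos α| > 1 and the degenerate r = n.
* **MTS**: closed-form inversion of the rational model (exact for the
  forward approximation); non-positive denominators mask the voxel.

Mask semantics (NaN outside the mask) are an original convention of this
package.

## Digital phantom

The default phantom is a 32³ grid with three nested spheres carrying
3 T-typical white-matter-, gray-matter-, and CSF-like parameters
(T1 = 0.85/1.4/3.2 s, T2 = 70/90/500 ms, T2\* = 50/60/300 ms,
M0 = 800/900/1000, MT ratio fraction 0.35/0.25/0.02, MTsat δ =
0.04/0.02/0.002, relative B1+ = 1), zero-M0 background. Default acquisition
protocols are desk-scale but realistic (e.g. MP2RAGE TI 0.8/2.7 s, flips
4°/5°, 160 excitations of 6.2 ms in a 5 s cycle; VFA 6°/20° at TR 15 ms;
MEGRE echoes 5–20 ms). Later regions overwrite earlier ones; geometry is
spheres and boxes in voxel coordinates.

Noise is applied after forward modeling from a seeded generator: Gaussian
by default for analytic testability, Rician available because magnitude MRI
noise is Rician. Phase images carry a smooth spatial phase ramp so
magnitude/phase recombination is genuinely exercised. Collection-constant
metadata is written once at the dataset root and entity-varying metadata in
entity-subset JSONs (one JSON shared by a magnitude/phase pair), so sidecar
inheritance is exercised rather than bypassed. Volumes are written as
float64 NIfTI-1 so noiseless round trips are exact at double precision.
Ground truth goes to a sibling `<name>_truth` directory, keeping the BIDS
tree standard-clean.

What passing phantom tests show: the grammar, grouping, inheritance,
validation, and every fitter's inverse are correct with respect to the
stated forward models, and noise propagation behaves as designed. What they
do not show: robustness to real-data departures from those models —
imperfect spoiling, B0/B1 inhomogeneity beyond a scalar b1_rel, partial
volume, motion, Rician bias at low SNR, or vendor metadata quirks.

## Monte-Carlo conditions

The stochastic recovery checks use 22³ = 10,648 voxels at image SNR 100,
with fixed seeds. The T2\* study uses σ = M0/100 (the first echo is ≈ M0)
with an 8-echo train from 5 to 60 ms sampling the decay of T2\* = 50 ms —
an echo train ending at 0.4 T2\* cannot constrain the decay to the tested
precision regardless of estimator, as a Cramér–Rao analysis shows. The T1
study uses a six-flip protocol (3–30° at TR 15 ms) with σ set to 1% of the
peak SPGR signal: SPGR signals are only a few percent of M0, so noise must
be referenced to the image scale for T1 to be identifiable at the tested
precision. Both medians of the relative error come out near 1.4%, against
a 2% bound.

## Validator

Issues carry stable codes with fixed severities (errors: missing/forbidden
entities, missing required metadata, duplicate or inconsistent linked
parameters, wrong folder, duplicate members, invalid labels/names, wrong
derivative units; warnings: index gaps, mixed index zero-padding, map values
outside the registry range, missing appendix-level metadata, missing BasedOn
provenance, unexpected singletons). Gaps in index numbering
are warnings (they impede readability), duplicate parameter values across
indices are errors (they break fitting). Validation is read-only,
deterministic, idempotent, and sorted by (path, code); reports serialize to
JSON with a summary block.

## Derivatives

Maps are written under `derivatives/<pipeline>/sub-*/{anat,fmap}` with a
`dataset_description.json` marking the tree as derived. Sidecars record
`Units` (refused if they disagree with the registry), `BasedOn`
(dataset-root-relative, forward slashes, every input exactly once, in
parameter-table order), the varying acquisition parameters as vectors, the
constant ones inherited from the raw sidecars, and a `GeneratedBy` block
with the package name, version, and fit configuration, so a re-run is
reproducible from the sidecar alone. Reading validates units and degrades a
missing `BasedOn` to a warning.
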