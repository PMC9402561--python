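# qmribids

A toolkit for **quantitative MRI data in BIDS** (the Brain Imaging Data
Structure): a schema-driven parser and validator for *entity-linked file
collections*, a digital-phantom generator that writes valid raw qMRI-BIDS
datasets, and voxelwise fitters that turn those collections into
standardized quantitative-map derivatives with full provenance.

## Why

Quantitative MRI estimates physical tissue parameters — relaxation times
T1, T2, T2\*, proton density, magnetization transfer, the transmit field
B1+ — by fitting a biophysical signal model to a *set* of images acquired
while one parameter is systematically varied. Those sets do not fit the
classic "one suffix, one contrast" BIDS picture: a filename suffix names the
logical acquisition (`MP2RAGE`, `VFA`, `MEGRE`, `TB1DAM`, ...) and linking
entities index the swept dimension:

| entity | values | linked parameter | collections |
|---|---|---|---|
| `echo-<i>` | 1..n | EchoTime | MEGRE, MESE, MPM |
| `flip-<i>` | 1..n | FlipAngle | VFA, MTS, MPM |
| `inv-<i>`  | 1..n | InversionTime | IRT1, MP2RAGE |
| `mt-<label>` | on/off | MTState | MTR, MTS, MPM |
| `part-<label>` | mag/phase | — | MP2RAGE |

Entities only *index* parameters; the values live in sidecar JSONs, which a
single file can supply for several images through BIDS inheritance (e.g. one
JSON for a magnitude/phase pair). Units of the fitted maps are standardized
so datasets are interchangeable: times in seconds, rates in 1/s, ratio maps
in percent, susceptibility in ppm, transmit field in relative percent where
**100 means the measured flip angle equals the nominal one**. The upstream
validator checks filenames and directory structure; this package also
implements the missing **metadata-level** validation (required fields per
collection, parameter distinctness across indices, units of derivatives).

## Models fitted

* **VFA** — spoiled gradient echo, S = M0 sin α (1−E1)/(1−E1 cos α),
  E1 = e^(−TR/T1); linearized least squares, optional per-voxel B1+
  correction → T1, M0.
* **IRT1** — S(TI) = a + b e^(−TI/T1), signed or magnitude with polarity
  restoration → T1.
* **MESE / MEGRE** — ln S = ln M0 − TE/tc, signal-weighted → T2 / T2\*.
* **MP2RAGE** — exact affine steady state of the inversion + two-GRE-block
  cycle; the bias-free combination UNI = Re(S1 S2\*)/(|S1|²+|S2|²) is
  inverted through a monotone lookup → T1.
* **MTR** — 100 (S_off − S_on)/S_off.
* **MTS** — rational small-angle closed form → MTsat, R1, M0.
* **TB1DAM** — double angle: cos(α) = S2/(2 S1) → relative B1+.
* **TB1AFI** — dual-TR ratio: cos(α) = (rn−1)/(n−r), n = TR2/TR1 → relative B1+.

The remaining collections of the convention (MPM, TB1EPI, TB1TFL, TB1SRGE,
RB1COR) are fully supported by the schema, generator, and validator;
fitting them is out of scope.

## Worked example

```bash
qmri-bids generate --out ds        # digital phantom, all 14 collections
qmri-bids validate ds
# 0 error(s), 0 warning(s)
qmri-bids fit --collection MP2RAGE --root ds --out ds/derivatives
# ds/derivatives/qmribids/sub-01/anat/sub-01_T1map.nii.gz
```

Reading the fitted map back:

```python
>>> import qmribids as q, numpy as np
>>> m = q.read_map("ds/derivatives/qmribids/sub-01/anat/sub-01_T1map.nii.gz")
>>> m.units
's'
>>> sorted(set(np.round(m.volume[np.isfinite(m.volume) & (m.volume > 0)], 4)))
[0.85, 1.4, 3.2]
>>> m.varying_meta["InversionTime"]
[0.8, 2.7]
>>> m.based_on[:2]
['sub-01/anat/sub-01_inv-01_part-mag_MP2RAGE.nii.gz',
 'sub-01/anat/sub-01_inv-01_part-phase_MP2RAGE.nii.gz']
```

The three recovered values are exactly the white-matter-, gray-matter- and
CSF-like T1 values (in seconds) of the default three-sphere phantom; the
sidecar logs the four input files (`BasedOn`), the inversion times as a
vector, and the constant acquisition parameters inherited from the raw
sidecars, including `MagneticFieldStrength`, without which a relaxometry map
cannot be interpreted.

The same library surface is available programmatically:
`q.generate_dataset`, `q.validate_dataset`, `q.group_collections`,
`q.parameter_table`, `q.fit_collection`, `q.write_map` / `q.read_map`.

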