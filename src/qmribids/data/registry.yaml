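# qMRI-BIDS convention registry: entities, file-collection suffixes, map units.
#
# Requirement levels and metadata fields printed in the consensus document are
# tagged `source: paper`; levels encoded from the BIDS qMRI appendix (the
# normative reference the document points to) are tagged `source: appendix`.
# The validator reports missing appendix-sourced metadata at warning severity
# by default and at error severity in strict mode.

entity_order: ["acq", "ce", "rec", "run", "echo", "flip", "inv", "mt", "part"]

entities:
  echo: {value_kind: index, linked_metadata: EchoTime}
  flip: {value_kind: index, linked_metadata: FlipAngle}
  inv: {value_kind: index, linked_metadata: InversionTime}
  mt: {value_kind: label, allowed_labels: ["on", "off"], linked_metadata: MTState}
  part: {value_kind: label, allowed_labels: ["mag", "phase"], linked_metadata: null}

# Canonical metadata keys for spellings that appear in more than one form.
metadata_aliases:
  RFSpoilingPhaseIncrement: SpoilingRFPhaseIncrement

suffixes:
  MP2RAGE:
    folder: anat
    entity_req: {inv: required, part: required, echo: optional, flip: forbidden, mt: forbidden}
    required_metadata:
      - {field: InversionTime, source: paper}
      - {field: FlipAngle, source: paper}
      - {field: RepetitionTimeExcitation, source: paper}
      - {field: RepetitionTimePreparation, source: paper}
      - {field: MagneticFieldStrength, source: paper}
      - {field: NumberShots, source: appendix}
    derived_maps: [T1map, R1map]
  MPM:
    folder: anat
    entity_req: {echo: required, flip: required, mt: required, part: optional, inv: forbidden}
    required_metadata:
      - {field: EchoTime, source: paper}
      - {field: FlipAngle, source: paper}
      - {field: MTState, source: paper}
      - {field: RepetitionTimeExcitation, source: appendix}
      - {field: MagneticFieldStrength, source: paper}
    derived_maps: [T1map, T2starmap, PDmap, MTsat]
  VFA:
    folder: anat
    entity_req: {flip: required, part: optional, echo: forbidden, inv: forbidden, mt: forbidden}
    required_metadata:
      - {field: FlipAngle, source: paper}
      - {field: RepetitionTimeExcitation, source: appendix}
      - {field: MagneticFieldStrength, source: paper}
    derived_maps: [T1map, T2map]
  IRT1:
    folder: anat
    entity_req: {inv: required, part: optional, echo: forbidden, flip: forbidden, mt: forbidden}
    required_metadata:
      - {field: InversionTime, source: paper}
      - {field: RepetitionTimePreparation, source: appendix}
      - {field: MagneticFieldStrength, source: paper}
    derived_maps: [T1map]
  MESE:
    folder: anat
    entity_req: {echo: required, part: optional, flip: forbidden, inv: forbidden, mt: forbidden}
    required_metadata:
      - {field: EchoTime, source: paper}
      - {field: RepetitionTimeExcitation, source: appendix}
      - {field: MagneticFieldStrength, source: paper}
    derived_maps: [T2map, MWFmap]
  MEGRE:
    folder: anat
    entity_req: {echo: required, part: optional, flip: forbidden, inv: forbidden, mt: forbidden}
    required_metadata:
      - {field: EchoTime, source: paper}
      - {field: RepetitionTimeExcitation, source: appendix}
      - {field: MagneticFieldStrength, source: paper}
    derived_maps: [T2starmap]
  MTR:
    folder: anat
    entity_req: {mt: required, part: optional, echo: forbidden, flip: forbidden, inv: forbidden}
    required_metadata:
      - {field: MTState, source: paper}
    derived_maps: [MTRmap]
  MTS:
    folder: anat
    entity_req: {mt: required, flip: required, part: optional, echo: forbidden, inv: forbidden}
    required_metadata:
      - {field: MTState, source: paper}
      - {field: FlipAngle, source: paper}
      - {field: RepetitionTimeExcitation, source: appendix}
      - {field: MagneticFieldStrength, source: paper}
    derived_maps: [MTsat, T1map]
  TB1DAM:
    folder: fmap
    entity_req: {flip: required, part: optional, echo: forbidden, inv: forbidden, mt: forbidden}
    required_metadata:
      - {field: FlipAngle, source: paper}
    derived_maps: [TB1map]
  TB1EPI:
    folder: fmap
    entity_req: {flip: required, echo: required, part: optional, inv: forbidden, mt: forbidden}
    required_metadata:
      - {field: FlipAngle, source: paper}
      - {field: EchoTime, source: appendix}
    derived_maps: [TB1map]
  TB1AFI:
    folder: fmap
    entity_req: {flip: required, part: optional, echo: forbidden, inv: forbidden, mt: forbidden}
    required_metadata:
      - {field: FlipAngle, source: paper}
      - {field: RepetitionTimeExcitation, source: appendix}
    derived_maps: [TB1map]
    # AFI interleaves share one nominal flip angle; the parameter that must
    # differ between the flip-indexed members is the repetition time.
    distinct_field: {flip: RepetitionTimeExcitation}
  TB1TFL:
    folder: fmap
    entity_req: {flip: optional, part: optional, echo: forbidden, inv: forbidden, mt: forbidden}
    required_metadata:
      - {field: FlipAngle, source: appendix}
    derived_maps: [TB1map]
    allow_singleton: true
  TB1SRGE:
    folder: fmap
    entity_req: {flip: required, inv: required, part: optional, echo: forbidden, mt: forbidden}
    required_metadata:
      - {field: FlipAngle, source: appendix}
      - {field: InversionTime, source: appendix}
      - {field: RepetitionTimePreparation, source: appendix}
    derived_maps: [TB1map]
  RB1COR:
    folder: fmap
    entity_req: {echo: forbidden, flip: forbidden, inv: forbidden, mt: forbidden, part: optional}
    required_metadata: []
    derived_maps: [RB1map]
    allow_singleton: true

maps:
  T1map: {units: "s", valid_range: [0.0, null], relaxometry: true}
  T2map: {units: "s", valid_range: [0.0, null], relaxometry: true}
  T2starmap: {units: "s", valid_range: [0.0, null], relaxometry: true}
  R1map: {units: "1/s", valid_range: [0.0, null], relaxometry: true}
  R2map: {units: "1/s", valid_range: [0.0, null], relaxometry: true}
  R2starmap: {units: "1/s", valid_range: [0.0, null], relaxometry: true}
  PDmap: {units: "arbitrary"}
  MTRmap: {units: "%", valid_range: [-100.0, 100.0]}
  MTsat: {units: "arbitrary"}
  MWFmap: {units: "%", valid_range: [0.0, 100.0]}
  Chimap: {units: "ppm"}
  TB1map: {units: "%", valid_range: [0.0, null]}
  RB1map: {units: "%", valid_range: [0.0, null]}
  M0map: {units: "arbitrary"}
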