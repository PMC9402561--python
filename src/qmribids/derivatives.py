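"""Read and write quantitative maps as BIDS derivatives with provenance.

Every map is stored in the registry's canonical units — no unit conversion
happens anywhere, and a non-conforming sidecar (e.g. ``ms`` for a T1 map) is
an error, never silently rescaled: unit interchangeability is the point of
the standard.  Sidecars record the full provenance of the fit: the input
files (``BasedOn``, dataset-root-relative, forward slashes), the
acquisition parameters that varied across them in vector form, the constant
parameters inherited from the raw sidecars (including MagneticFieldStrength,
without which a relaxometry map is uninterpretable), and a generating-
software block with the fit configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import schema
from .bids_io import (
    FormatError,
    ParsedName,
    build_filename,
    parse_filename,
    save_nifti,
    write_json,
)

__all__ = ["QuantitativeMap", "UnitsError", "write_map", "read_map"]


class UnitsError(ValueError):
    """Sidecar units disagree with the registry (code QV_UNITS_INVALID)."""


@dataclass
class QuantitativeMap:
    """A fitted parameter volume with units and provenance."""

    volume: np.ndarray
    map_suffix: str
    units: str
    based_on: list[str] = field(default_factory=list)
    varying_meta: dict[str, list] = field(default_factory=dict)
    constant_meta: dict[str, object] = field(default_factory=dict)
    software: dict = field(default_factory=dict)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        spec = schema.get_map_spec(self.map_suffix)
        if self.units != spec.units:
            raise UnitsError(
                f"QV_UNITS_INVALID: {self.map_suffix} must carry units "
                f"{spec.units!r}, got {self.units!r}"
            )
        if len(self.based_on) != len(set(self.based_on)):
            raise ValueError("BasedOn must list every input exactly once")
        if spec.relaxometry and "MagneticFieldStrength" not in self.constant_meta:
            raise ValueError(
                "MagneticFieldStrength is required in a relaxometry map's "
                "metadata"
            )


def _default_software() -> dict:
    from . import __version__

    return {"Name": "qmribids", "Version": __version__}


def write_map(
    m: QuantitativeMap,
    deriv_root: str | Path,
    subject: str = "01",
    folder: str | None = None,
    pipeline: str = "qmribids",
) -> Path:
    """Write a quantitative map (NIfTI + sidecar) into a derivatives tree.

    The derivatives root gets its own ``dataset_description.json`` marking
    it as derived data.  Returns the image path.
    """
    m.validate()
    deriv_root = Path(deriv_root)
    pipe_root = deriv_root / pipeline
    desc = pipe_root / "dataset_description.json"
    if not desc.exists():
        write_json(
            desc,
            {
                "Name": f"{pipeline} quantitative maps",
                "BIDSVersion": "1.5.0",
                "DatasetType": "derivative",
                "GeneratedBy": [m.software or _default_software()],
            },
        )
    if folder is None:
        folder = "fmap" if m.map_suffix in ("TB1map", "RB1map") else "anat"
    name = ParsedName(
        subject=subject, suffix=m.map_suffix, extension=".nii.gz"
    )
    image_path = pipe_root / f"sub-{subject}" / folder / build_filename(
        name, check_suffix=False
    )
    save_nifti(image_path, np.nan_to_num(m.volume, nan=np.nan), m.affine)

    sidecar = {
        "Units": m.units,
        "BasedOn": [p.replace("\\", "/") for p in m.based_on],
        "GeneratedBy": [m.software or _default_software()],
    }
    for key, vec in m.varying_meta.items():
        sidecar[key] = list(vec)
    for key, value in m.constant_meta.items():
        if key not in sidecar:
            sidecar[key] = value
    write_json(image_path.with_name(image_path.name[: -len(".nii.gz")] + ".json"),
               sidecar)
    return image_path


def read_map(path: str | Path) -> QuantitativeMap:
    """Reconstruct a QuantitativeMap from a written NIfTI + sidecar pair.

    Units are validated against the registry (a dialect such as ``ms`` is
    rejected, not converted).  A missing ``BasedOn`` yields a result carrying
    a provenance-incomplete warning rather than an error.
    """
    import nibabel as nib

    path = Path(path)
    parsed = parse_filename(path.name)
    spec = schema.get_map_spec(parsed.suffix)  # RegistryError if unknown

    stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    sidecar_path = path.with_name(stem + ".json")
    if not sidecar_path.is_file():
        raise FormatError(f"map {path} has no sidecar JSON")
    meta = json.loads(sidecar_path.read_text("utf-8"))

    units = meta.pop("Units", None)
    if units != spec.units:
        raise UnitsError(
            f"QV_UNITS_INVALID: {parsed.suffix} sidecar carries units "
            f"{units!r}, registry requires {spec.units!r}"
        )
    warnings = []
    based_on = meta.pop("BasedOn", None)
    if based_on is None:
        warnings.append("provenance incomplete: sidecar lacks BasedOn")
        based_on = []
    software = (meta.pop("GeneratedBy", None) or [{}])[0]

    varying = {k: v for k, v in meta.items() if isinstance(v, list)}
    constant = {k: v for k, v in meta.items() if not isinstance(v, list)}

    img = nib.load(str(path))
    return QuantitativeMap(
        volume=np.asanyarray(img.dataobj).astype(np.float64),
        map_suffix=parsed.suffix,
        units=units,
        based_on=list(based_on),
        varying_meta=varying,
        constant_meta=constant,
        software=software,
        affine=np.asarray(img.affine),
        warnings=warnings,
    )
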