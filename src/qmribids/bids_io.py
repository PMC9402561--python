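"""Parse and build BIDS filenames, resolve sidecar metadata, read/write volumes.

Filenames follow the entity grammar ``sub-<label>[_ses-<label>]_<key>-<value>
..._<suffix>.<ext>``.  Only the qMRI linking entities (echo, flip, inv, mt,
part) are interpreted; other BIDS entities (acq-, run-, ...) are carried
through opaquely and preserved on rebuild.  Index entities accept unpadded
values on read and are emitted two-digit zero-padded on write.

Sidecar resolution implements the BIDS inheritance principle: all JSON files
applicable to an image — same suffix, entity subset of the image's entities —
are merged from the dataset root down to the image's directory, with the
nearest (deepest, most specific) file winning on conflicts.
"""

from __future__ import annotations

import gzip
import json
import math
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import schema

__all__ = [
    "ParseError",
    "LabelError",
    "CompositionError",
    "FormatError",
    "ParsedName",
    "Sidecar",
    "ImageVolume",
    "parse_filename",
    "build_filename",
    "resolve_sidecar",
    "load_volume",
    "save_nifti",
    "write_json",
]

IMAGE_EXTENSIONS = (".nii.gz", ".nii")
KNOWN_EXTENSIONS = IMAGE_EXTENSIONS + (".json", ".tsv")


class ParseError(ValueError):
    """A filename does not follow the entity grammar."""


class LabelError(ParseError):
    """A label entity carries a value outside its allowed set."""


class CompositionError(ValueError):
    """A ParsedName cannot be serialized (e.g. forbidden entity for suffix)."""


class FormatError(ValueError):
    """A sidecar or image file is unreadable or malformed."""


@dataclass
class ParsedName:
    """Decomposition of a BIDS filename.

    ``entities`` holds the interpreted qMRI linking entities (index values as
    ``int``, labels as ``str``); ``extras`` holds any other entities verbatim,
    in filename order.
    """

    subject: str
    session: str | None = None
    entities: dict[str, int | str] = dc_field(default_factory=dict)
    extras: dict[str, str] = dc_field(default_factory=dict)
    suffix: str = ""
    extension: str = ".nii.gz"
    #: character width of each index entity as written (for padding checks)
    index_widths: dict[str, int] = dc_field(default_factory=dict, compare=False)

    def key(self) -> tuple:
        """Full identity of the file within its dataset (sans extension)."""
        return (
            self.subject,
            self.session,
            tuple(sorted(self.extras.items())),
            tuple(sorted(self.entities.items())),
            self.suffix,
        )


@dataclass
class Sidecar:
    """Resolved sidecar metadata for one image.

    ``provenance`` lists every JSON file that contributed, shallowest first;
    the deepest file wins on conflicting fields.
    """

    values: dict[str, object] = dc_field(default_factory=dict)
    provenance: list[str] = dc_field(default_factory=list)

    def get(self, key: str, default=None):
        return self.values.get(schema.canonical_metadata_key(key), default)

    def __contains__(self, key: str) -> bool:
        return schema.canonical_metadata_key(key) in self.values


@dataclass
class ImageVolume:
    """A 3-D voxel array with its affine and resolved metadata."""

    voxels: np.ndarray
    affine: np.ndarray
    meta: Sidecar = dc_field(default_factory=Sidecar)


def _split_extension(name: str) -> tuple[str, str]:
    for ext in KNOWN_EXTENSIONS:
        if name.endswith(ext):
            return name[: -len(ext)], ext
    raise ParseError(
        f"{name!r}: unrecognized extension (expected one of {KNOWN_EXTENSIONS})"
    )


def parse_filename(name: str) -> ParsedName:
    """Parse a single BIDS path component into its constituents.

    Raises :class:`ParseError` (with the character position of the offending
    token) for malformed names, and :class:`ParseError` for label values
    outside an entity's allowed set.
    """
    if "/" in name or os.sep in name:
        raise ParseError(f"{name!r}: expected a single path component")
    stem, ext = _split_extension(name)
    tokens = stem.split("_")
    pos = 0  # character offset of the current token within `name`

    def fail(msg: str) -> ParseError:
        return ParseError(f"{name!r} at position {pos}: {msg}")

    if not tokens or not tokens[0].startswith("sub-") or len(tokens[0]) <= 4:
        raise fail("filename must start with 'sub-<label>'")
    subject = tokens[0][4:]
    pos += len(tokens[0]) + 1
    idx = 1

    session = None
    if idx < len(tokens) and tokens[idx].startswith("ses-"):
        session = tokens[idx][4:]
        if not session:
            raise fail("empty session label")
        pos += len(tokens[idx]) + 1
        idx += 1

    entities: dict[str, int | str] = {}
    extras: dict[str, str] = {}
    index_widths: dict[str, int] = {}
    if idx == len(tokens):
        raise fail("missing suffix token")
    suffix = tokens[-1]
    if "-" in suffix:
        pos = len(name) - len(suffix) - len(ext)
        raise fail(f"suffix token {suffix!r} must not contain '-'")
    if not suffix:
        raise fail("empty suffix token")

    for tok in tokens[idx:-1]:
        if "-" not in tok:
            raise fail(f"token {tok!r} is not a '<key>-<value>' pair")
        key, _, value = tok.partition("-")
        if not key or not value:
            raise fail(f"token {tok!r} has an empty key or value")
        if key in ("sub", "ses"):
            raise fail(f"'{key}-' entity out of position")
        if key in schema.LINKING_ENTITIES:
            if key in entities:
                raise fail(f"entity {key!r} appears more than once")
            edef = schema.get_entity_def(key)
            if edef.value_kind == "index":
                if not value.isdigit() or int(value) < 1:
                    raise fail(
                        f"entity {key!r} takes a positive integer index, got {value!r}"
                    )
                entities[key] = int(value)
                index_widths[key] = len(value)
            else:
                if value not in edef.allowed_labels:
                    raise LabelError(
                        f"{name!r} at position {pos}: entity {key!r} label must "
                        f"be one of {sorted(edef.allowed_labels)}, got {value!r}"
                    )
                entities[key] = value
        else:
            if key in extras:
                raise fail(f"entity {key!r} appears more than once")
            extras[key] = value
        pos += len(tok) + 1

    return ParsedName(
        subject=subject,
        session=session,
        entities=entities,
        extras=extras,
        suffix=suffix,
        extension=ext,
        index_widths=index_widths,
    )


def build_filename(p: ParsedName, check_suffix: bool = True) -> str:
    """Serialize a ParsedName to its canonical filename.

    Index entities are zero-padded to two digits; entities are emitted in the
    canonical order.  If the suffix is a registered collection suffix and
    ``check_suffix`` is true, entities the schema forbids for it raise
    :class:`CompositionError`.
    """
    if check_suffix and p.suffix in schema.list_suffixes():
        spec = schema.get_suffix_spec(p.suffix)
        for key in p.entities:
            if spec.entity_req.get(key) == "forbidden":
                raise CompositionError(
                    f"entity {key!r} is forbidden for suffix {p.suffix!r}"
                )
    parts = [f"sub-{p.subject}"]
    if p.session:
        parts.append(f"ses-{p.session}")
    order = schema.entity_order()

    def rank(key: str) -> tuple:
        return (order.index(key) if key in order else len(order), key)

    merged: list[tuple[str, object]] = sorted(
        list(p.extras.items()) + list(p.entities.items()), key=lambda kv: rank(kv[0])
    )
    for key, value in merged:
        if isinstance(value, int):
            parts.append(f"{key}-{value:02d}")
        else:
            parts.append(f"{key}-{value}")
    if not p.suffix:
        raise CompositionError("suffix is required")
    parts.append(p.suffix)
    return "_".join(parts) + p.extension


def _lenient_parse(name: str) -> dict | None:
    """Parse a JSON filename for inheritance matching.

    Top-level metadata files may omit the subject prefix (e.g. ``VFA.json``),
    so the strict grammar does not apply.  Returns None for names that cannot
    participate in inheritance.
    """
    try:
        stem, ext = _split_extension(name)
    except ParseError:
        return None
    if ext != ".json":
        return None
    tokens = stem.split("_")
    out: dict = {"subject": None, "session": None, "pairs": {}, "suffix": None}
    if not tokens:
        return None
    suffix = tokens[-1]
    if "-" in suffix or not suffix:
        return None
    out["suffix"] = suffix
    for tok in tokens[:-1]:
        if "-" not in tok:
            return None
        key, _, value = tok.partition("-")
        if not key or not value:
            return None
        if key == "sub":
            out["subject"] = value
        elif key == "ses":
            out["session"] = value
        else:
            out["pairs"][key] = value
    return out


def _applies(json_info: dict, image: ParsedName) -> bool:
    if json_info["suffix"] != image.suffix:
        return False
    if json_info["subject"] is not None and json_info["subject"] != image.subject:
        return False
    if json_info["session"] is not None and json_info["session"] != image.session:
        return False
    image_pairs: dict[str, str] = {k: v for k, v in image.extras.items()}
    for k, v in image.entities.items():
        image_pairs[k] = str(v)
    for k, v in json_info["pairs"].items():
        if k not in image_pairs:
            return False
        if k in schema.LINKING_ENTITIES and schema.get_entity_def(k).value_kind == "index":
            if not v.isdigit() or int(v) != int(image_pairs[k]):
                return False
        elif image_pairs[k] != v:
            return False
    return True


def resolve_sidecar(image_path: str | Path, dataset_root: str | Path) -> Sidecar:
    """Resolve an image's metadata by merging applicable JSONs root-to-leaf.

    Within one directory, less specific files (fewer entities) are merged
    first, so the most specific applicable file wins.  Resolution is
    deterministic and independent of directory listing order.  An image with
    no applicable JSON resolves to an empty Sidecar.
    """
    image_path = Path(image_path).resolve()
    dataset_root = Path(dataset_root).resolve()
    try:
        rel = image_path.relative_to(dataset_root)
    except ValueError:
        raise FormatError(f"{image_path} is not under {dataset_root}") from None
    image = parse_filename(image_path.name)

    candidates: list[tuple[int, int, str, Path]] = []
    directory = dataset_root
    for depth, part in enumerate([None] + list(rel.parts[:-1])):
        if part is not None:
            directory = directory / part
        if not directory.is_dir():
            continue
        for entry in sorted(directory.iterdir()):
            if not entry.is_file():
                continue
            info = _lenient_parse(entry.name)
            if info is None or not _applies(info, image):
                continue
            specificity = (
                len(info["pairs"])
                + (info["subject"] is not None)
                + (info["session"] is not None)
            )
            candidates.append((depth, specificity, entry.name, entry))

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    sidecar = Sidecar()
    for _, _, _, path in candidates:
        try:
            with open(path, encoding="utf-8") as fh:
                data = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise FormatError(f"invalid sidecar JSON {path}: {exc}") from None
        if not isinstance(data, dict):
            raise FormatError(f"sidecar {path} must contain a JSON object")
        for key, value in data.items():
            sidecar.values[schema.canonical_metadata_key(key)] = value
        sidecar.provenance.append(str(path))
    return sidecar


def load_volume(
    image_path: str | Path, dataset_root: str | Path | None = None
) -> ImageVolume:
    """Read a 3-D NIfTI file, optionally resolving its sidecar metadata."""
    image_path = Path(image_path)
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(
            f"{image_path}: expected a 3-D volume, got shape {data.shape}"
        )
    meta = (
        resolve_sidecar(image_path, dataset_root)
        if dataset_root is not None
        else Sidecar()
    )
    return ImageVolume(voxels=data, affine=np.asarray(img.affine), meta=meta)


def save_nifti(path: str | Path, voxels: np.ndarray, affine: np.ndarray) -> None:
    """Write a float64 NIfTI-1 volume (deterministic bytes for fixed input).

    Double precision keeps noiseless phantom round trips exact; desk-scale
    volumes make the size cost irrelevant.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(voxels, dtype=np.float64), np.asarray(affine))
    if path.name.endswith(".gz"):
        # bypass nibabel's opener so the gzip header carries no timestamp
        raw = img.to_bytes()
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        nib.save(img, str(path))


def _jsonify(value):
    """Normalize values for byte-reproducible JSON output."""
    if isinstance(value, dict):
        return {str(k): _jsonify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in value]
    if isinstance(value, (bool, str)) or value is None:
        return value
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, (float, np.floating)):
        v = float(value)
        if not math.isfinite(v):
            raise FormatError(f"non-finite value {v!r} cannot be stored in JSON")
        return float(f"{v:.12g}")  # <= 12 significant digits
    raise FormatError(f"unsupported JSON value type {type(value).__name__}")


def write_json(path: str | Path, values: dict) -> None:
    """Write a sidecar JSON: sorted keys, UTF-8, 4-space indent, 12-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = json.dumps(_jsonify(values), sort_keys=True, indent=4, ensure_ascii=False)
    path.write_text(text + "\n", encoding="utf-8")
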