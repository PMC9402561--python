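"""Schema-driven validation of qMRI-BIDS datasets.

Checks a dataset at three levels — filename grammar, collection structure
(entity requirement levels, index contiguity, labels), and sidecar metadata
(required fields present, linked parameters distinct across indices) — the
last of which is the validation gap this toolkit closes.  Issues are data,
not exceptions: each carries a stable code from a closed taxonomy, a fixed
severity, the offending path, and a message.

Metadata requirements printed in the consensus document validate at error
severity; requirements encoded from the BIDS qMRI appendix validate at
warning severity by default and at error severity under ``strict``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import schema
from .bids_io import LabelError, ParseError, parse_filename
from .collections import (
    DuplicateMemberError,
    FileCollection,
    group_collections,
    iter_image_files,
)

__all__ = [
    "ValidationIssue",
    "SEVERITY",
    "validate_dataset",
    "check_collection",
    "report_json",
]

#: Closed issue taxonomy; severity is fixed per code.
SEVERITY = {
    "QV_NAME_INVALID": "error",      # filename violates the entity grammar
    "QV_LABEL_INVALID": "error",     # label entity value outside allowed set
    "QV_ENTITY_MISSING": "error",    # required entity absent from a member
    "QV_ENTITY_FORBIDDEN": "error",  # forbidden entity present
    "QV_FOLDER_INVALID": "error",    # collection in the wrong BIDS folder
    "QV_DUPLICATE_MEMBER": "error",  # identical full entity mappings
    "QV_INDEX_GAP": "warning",       # index set not contiguous from 1
    "QV_META_MISSING": "error",      # required metadata field absent
    "QV_META_RECOMMENDED": "warning",  # appendix-level metadata field absent
    "QV_PARAM_DUPLICATE": "error",   # linked parameter repeats across indices
    "QV_PARAM_INCONSISTENT": "error",  # linked parameter varies within index
    "QV_UNITS_INVALID": "error",     # derivative units differ from registry
    "QV_RANGE_INVALID": "warning",   # map values outside the registry range
    "QV_PROVENANCE_MISSING": "warning",  # derivative sidecar lacks BasedOn
    "QV_SINGLETON": "warning",       # single-member collection not permitted
    "QV_MIXED_PADDING": "warning",   # inconsistent index zero-padding
}


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    severity: str
    path: str
    message: str

    def __post_init__(self):
        assert self.code in SEVERITY and self.severity == SEVERITY[self.code]


def _issue(code: str, path, message: str) -> ValidationIssue:
    return ValidationIssue(code, SEVERITY[code], str(path), message)


def check_collection(c: FileCollection, strict: bool = False) -> list[ValidationIssue]:
    """Validate one file collection against its suffix schema."""
    issues: list[ValidationIssue] = []
    spec = schema.get_suffix_spec(c.suffix)

    for m in c.members:
        rel = m.path.name
        for key in spec.required_entities():
            if key not in m.name.entities:
                issues.append(
                    _issue(
                        "QV_ENTITY_MISSING",
                        rel,
                        f"entity {key!r} is required for suffix {c.suffix!r}",
                    )
                )
        for key in m.name.entities:
            if spec.entity_req.get(key) == "forbidden":
                issues.append(
                    _issue(
                        "QV_ENTITY_FORBIDDEN",
                        rel,
                        f"entity {key!r} is forbidden for suffix {c.suffix!r}",
                    )
                )

    # index contiguity and padding consistency
    for key in sorted({k for m in c.members for k in m.name.entities}):
        if schema.get_entity_def(key).value_kind != "index":
            continue
        indices = sorted(
            {m.name.entities[key] for m in c.members if key in m.name.entities}
        )
        if indices and indices != list(range(1, len(indices) + 1)):
            issues.append(
                _issue(
                    "QV_INDEX_GAP",
                    c.identity(),
                    f"{key} indices {indices} are not contiguous from 1",
                )
            )
        widths = {
            m.name.index_widths[key]
            for m in c.members
            if key in m.name.index_widths
        }
        if len(widths) > 1:
            issues.append(
                _issue(
                    "QV_MIXED_PADDING",
                    c.identity(),
                    f"{key} indices use mixed zero-padding widths "
                    f"{sorted(widths)}",
                )
            )

    if len(c.members) == 1 and spec.required_entities() and not spec.allow_singleton:
        issues.append(
            _issue(
                "QV_SINGLETON",
                c.identity(),
                f"suffix {c.suffix!r} expects a multi-file collection",
            )
        )

    # metadata requirements (the resolved sidecar of every member)
    for req in spec.required_fields:
        for m in c.members:
            if req.field in m.sidecar:
                continue
            if req.source == "paper" or strict:
                issues.append(
                    _issue(
                        "QV_META_MISSING",
                        m.path.name,
                        f"required metadata {req.field!r} is missing",
                    )
                )
            else:
                issues.append(
                    _issue(
                        "QV_META_RECOMMENDED",
                        m.path.name,
                        f"metadata {req.field!r} (appendix requirement) is missing",
                    )
                )

    # linked-parameter consistency across indices
    for key in sorted({k for m in c.members for k in m.name.entities}):
        edef = schema.get_entity_def(key)
        field_name = spec.distinct_field_for(key)
        if field_name is None:
            continue
        by_index: dict[object, set] = {}
        for m in c.members:
            if key not in m.name.entities or field_name not in m.sidecar:
                continue
            value = m.sidecar.get(field_name)
            if key == "mt":
                label = "on" if value is True else "off" if value is False else str(value)
                if label != m.name.entities[key]:
                    issues.append(
                        _issue(
                            "QV_PARAM_INCONSISTENT",
                            m.path.name,
                            f"MTState {value!r} disagrees with mt-"
                            f"{m.name.entities[key]}",
                        )
                    )
                continue
            by_index.setdefault(m.name.entities[key], set()).add(value)
        if key == "mt":
            continue
        for index, values in sorted(by_index.items()):
            if len(values) > 1:
                issues.append(
                    _issue(
                        "QV_PARAM_INCONSISTENT",
                        c.identity(),
                        f"{field_name} varies within {key} index {index}",
                    )
                )
        if edef.value_kind == "index" and len(by_index) > 1:
            singletons = [next(iter(v)) for v in by_index.values() if len(v) == 1]
            if len(singletons) != len(set(singletons)):
                issues.append(
                    _issue(
                        "QV_PARAM_DUPLICATE",
                        c.identity(),
                        f"{field_name} is not distinct across {key} indices",
                    )
                )
    return issues


def _check_derivatives(root: Path, issues: list[ValidationIssue]) -> None:
    deriv = root / "derivatives"
    if not deriv.is_dir():
        return
    for path in sorted(deriv.rglob("*")):
        if not path.is_file() or not (
            path.name.endswith(".nii") or path.name.endswith(".nii.gz")
        ):
            continue
        try:
            parsed = parse_filename(path.name)
        except ParseError:
            continue
        if parsed.suffix not in schema.list_maps():
            continue
        mapspec = schema.get_map_spec(parsed.suffix)
        stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
        sidecar_path = path.with_name(stem + ".json")
        rel = path.relative_to(root)
        if not sidecar_path.is_file():
            issues.append(
                _issue("QV_META_MISSING", rel, "quantitative map has no sidecar")
            )
            continue
        meta = json.loads(sidecar_path.read_text("utf-8"))
        units = meta.get("Units")
        if units != mapspec.units:
            issues.append(
                _issue(
                    "QV_UNITS_INVALID",
                    rel,
                    f"Units {units!r} != registry units {mapspec.units!r} "
                    f"for {parsed.suffix}",
                )
            )
        if mapspec.relaxometry and "MagneticFieldStrength" not in meta:
            issues.append(
                _issue(
                    "QV_META_MISSING",
                    rel,
                    "MagneticFieldStrength is required to interpret a "
                    "relaxometry map",
                )
            )
        if "BasedOn" not in meta:
            issues.append(
                _issue("QV_PROVENANCE_MISSING", rel, "sidecar lacks BasedOn")
            )
        if mapspec.valid_range is not None:
            import nibabel as nib

            data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
            lo, hi = mapspec.valid_range
            finite = data[np.isfinite(data)]
            bad = np.zeros(finite.shape, bool)
            if lo is not None:
                bad |= finite < lo
            if hi is not None:
                bad |= finite > hi
            if bad.any():
                issues.append(
                    _issue(
                        "QV_RANGE_INVALID",
                        rel,
                        f"{int(bad.sum())} voxel(s) outside the valid "
                        f"{parsed.suffix} range [{lo}, {hi}]",
                    )
                )


def validate_dataset(root: str | Path, strict: bool = False) -> list[ValidationIssue]:
    """Validate a dataset tree; returns all issues sorted by (path, code).

    Never mutates the dataset; deterministic and idempotent.  A missing root
    is a usage error (:class:`FileNotFoundError`).
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    issues: list[ValidationIssue] = []

    parse_ok = True
    for path in iter_image_files(root):
        rel = path.relative_to(root)
        try:
            parsed = parse_filename(path.name)
        except LabelError as exc:
            issues.append(_issue("QV_LABEL_INVALID", rel, str(exc)))
            parse_ok = False
            continue
        except ParseError as exc:
            issues.append(_issue("QV_NAME_INVALID", rel, str(exc)))
            parse_ok = False
            continue
        if parsed.suffix in schema.list_suffixes():
            folder = path.parent.name
            expected = schema.get_suffix_spec(parsed.suffix).folder
            if folder != expected:
                issues.append(
                    _issue(
                        "QV_FOLDER_INVALID",
                        rel,
                        f"suffix {parsed.suffix!r} belongs in {expected!r}, "
                        f"found in {folder!r}",
                    )
                )

    if parse_ok:
        try:
            for c in group_collections(root):
                issues.extend(check_collection(c, strict=strict))
        except DuplicateMemberError as exc:
            issues.append(_issue("QV_DUPLICATE_MEMBER", root, str(exc)))

    _check_derivatives(root, issues)
    issues.sort(key=lambda i: (i.path, i.code, i.message))
    return issues


def report_json(issues: list[ValidationIssue], n_collections: int | None = None) -> dict:
    """Machine-readable report: the issue list plus a summary block."""
    return {
        "issues": [asdict(i) for i in issues],
        "summary": {
            "n_errors": int(np.sum([i.severity == "error" for i in issues])),
            "n_warnings": int(np.sum([i.severity == "warning" for i in issues])),
            "n_collections": n_collections,
        },
    }
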