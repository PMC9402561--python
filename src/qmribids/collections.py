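"""Group parsed image files into entity-linked file collections.

A file collection is the logical unit of a qMRI acquisition: the set of
images sharing one suffix and scope (subject, session, non-linking entities)
whose members differ only in linking entities (echo, flip, inv, mt, part).
The grouping key intentionally includes opaque entities such as acq- and
run-, so repeated acquisitions form separate collections.

Acquisition parameter values are never read from filenames — entities only
index or categorize them; :func:`parameter_table` reads the values from each
member's resolved sidecar and checks their consistency (constant within a
fixed index, distinct across indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import schema
from .bids_io import ParsedName, Sidecar, parse_filename, resolve_sidecar

__all__ = [
    "Member",
    "FileCollection",
    "DuplicateMemberError",
    "IncompleteTableError",
    "group_collections",
    "parameter_table",
    "iter_image_files",
]


class DuplicateMemberError(ValueError):
    """Two files in one collection share an identical full entity mapping."""


class IncompleteTableError(ValueError):
    """Required linked metadata is missing or inconsistent for a member."""


@dataclass
class Member:
    name: ParsedName
    path: Path
    sidecar: Sidecar


@dataclass
class FileCollection:
    """One grouped qMRI acquisition with its members in canonical order."""

    suffix: str
    subject: str
    session: str | None
    extras: tuple[tuple[str, str], ...]
    members: list[Member] = field(default_factory=list)
    root: Path | None = None

    @property
    def linking_entities(self) -> set[str]:
        """Entity keys that vary across members (all present keys if singleton)."""
        keys = {k for m in self.members for k in m.name.entities}
        if len(self.members) <= 1:
            return keys
        varying = set()
        for k in keys:
            values = {m.name.entities.get(k) for m in self.members}
            if len(values) > 1:
                varying.add(k)
        return varying

    def identity(self) -> str:
        parts = [f"sub-{self.subject}"]
        if self.session:
            parts.append(f"ses-{self.session}")
        parts += [f"{k}-{v}" for k, v in self.extras]
        parts.append(self.suffix)
        return "_".join(parts)

    def sort_members(self) -> None:
        self.members.sort(key=lambda m: tuple(sorted(m.name.entities.items())))


def iter_image_files(dataset_root: str | Path):
    """Yield every NIfTI image under the dataset's subject directories."""
    root = Path(dataset_root)
    for sub_dir in sorted(root.glob("sub-*")):
        if not sub_dir.is_dir():
            continue
        for path in sorted(sub_dir.rglob("*")):
            if path.is_file() and (
                path.name.endswith(".nii") or path.name.endswith(".nii.gz")
            ):
                yield path


def group_collections(
    dataset_root: str | Path, resolve_metadata: bool = True
) -> list[FileCollection]:
    """Partition recognized image files into file collections.

    Files whose suffix is not a registered collection suffix are ignored
    (they are ordinary BIDS content).  Two files with identical full entity
    mappings raise :class:`DuplicateMemberError`.
    """
    root = Path(dataset_root)
    groups: dict[tuple, FileCollection] = {}
    seen: dict[tuple, Path] = {}
    for path in iter_image_files(root):
        parsed = parse_filename(path.name)
        if parsed.suffix not in schema.list_suffixes():
            continue
        full_key = parsed.key()
        if full_key in seen:
            raise DuplicateMemberError(
                f"{path} duplicates the entity mapping of {seen[full_key]}"
            )
        seen[full_key] = path
        gkey = (
            parsed.subject,
            parsed.session,
            tuple(sorted(parsed.extras.items())),
            parsed.suffix,
        )
        if gkey not in groups:
            groups[gkey] = FileCollection(
                suffix=parsed.suffix,
                subject=parsed.subject,
                session=parsed.session,
                extras=tuple(sorted(parsed.extras.items())),
                root=root,
            )
        sidecar = resolve_sidecar(path, root) if resolve_metadata else Sidecar()
        groups[gkey].members.append(Member(parsed, path, sidecar))

    collections = [groups[k] for k in sorted(groups)]
    for c in collections:
        c.sort_members()
    return collections


def _mt_label(value) -> str:
    """Canonicalize an MTState metadata value to the on/off label domain."""
    if isinstance(value, bool):
        return "on" if value else "off"
    return str(value)


def parameter_table(c: FileCollection) -> pd.DataFrame:
    """Per-member acquisition parameters, read from resolved sidecars.

    One row per member; columns are the entity values plus the metadata field
    linked to each entity present (EchoTime s, FlipAngle deg, InversionTime
    s, MTState on/off, part label).  Raises :class:`IncompleteTableError`
    when a required linked field is missing, varies within one index, or
    repeats across indices of a sweep entity.
    """
    spec = schema.get_suffix_spec(c.suffix)
    entity_keys = sorted(
        {k for m in c.members for k in m.name.entities},
        key=lambda k: schema.entity_order().index(k),
    )
    rows = []
    for m in c.members:
        row: dict[str, object] = {"filename": m.path.name}
        for key in entity_keys:
            row[key] = m.name.entities.get(key)
            linked = schema.get_entity_def(key).linked_metadata
            if linked is None:
                continue
            if linked not in m.sidecar:
                raise IncompleteTableError(
                    f"{c.identity()}: member {m.path.name} lacks required "
                    f"metadata {linked!r}"
                )
            value = m.sidecar.get(linked)
            row[linked] = _mt_label(value) if key == "mt" else value
        rows.append(row)
    table = pd.DataFrame(rows)

    for key in entity_keys:
        edef = schema.get_entity_def(key)
        field_name = spec.distinct_field_for(key)
        if field_name is None:
            continue
        if field_name not in table.columns:
            # distinct_field override: pull the field from the sidecars
            values = []
            for m in c.members:
                if field_name not in m.sidecar:
                    raise IncompleteTableError(
                        f"{c.identity()}: member {m.path.name} lacks required "
                        f"metadata {field_name!r}"
                    )
                values.append(m.sidecar.get(field_name))
            table[field_name] = values
        per_index = table.groupby(key, dropna=True)[field_name]
        if (per_index.nunique() > 1).any():
            raise IncompleteTableError(
                f"{c.identity()}: {field_name} varies within a fixed "
                f"{key} index"
            )
        if edef.value_kind == "index":
            firsts = per_index.first()
            if firsts.duplicated().any():
                raise IncompleteTableError(
                    f"{c.identity()}: {field_name} is not distinct across "
                    f"{key} indices"
                )
        if key == "mt":
            mismatched = table[key].notna() & (table[key] != table[field_name])
            if mismatched.any():
                raise IncompleteTableError(
                    f"{c.identity()}: MTState metadata disagrees with the mt "
                    "entity label"
                )
    return table


def table_to_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Export a parameter table as TSV for inspection."""
    table.to_csv(path, sep="\t", index=False)
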