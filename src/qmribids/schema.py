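"""Machine-readable registry of the qMRI-BIDS convention.

The registry is a declarative YAML file shipped with the package
(``data/registry.yaml``).  It records, for every entity-linked file
collection suffix (MP2RAGE, VFA, MEGRE, TB1DAM, ...):

* the BIDS folder the collection lives in (``anat`` or ``fmap``),
* the requirement level of each linking entity (required / optional /
  forbidden),
* the metadata fields required in the sidecar JSONs, each tagged with its
  provenance (``paper`` for levels printed in the consensus document,
  ``appendix`` for levels encoded from the normative BIDS qMRI appendix),
* the quantitative maps derivable from the collection.

It also records the linking entities themselves (``echo``, ``flip``,
``inv``, ``mt``, ``part``) together with the acquisition parameter each one
indexes (EchoTime, FlipAngle, InversionTime, MTState), and a units registry
for every derivable map: relaxation times in seconds, rates in reciprocal
seconds, unitless ratio maps in percent, susceptibility in ppm, and transmit
field maps in relative percent where 100 denotes the nominal flip angle.

The registry is loaded once per process and validated against a small
structural meta-schema at load time.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "RegistryError",
    "EntityDef",
    "SuffixSpec",
    "MapSpec",
    "entity_order",
    "get_entity_def",
    "list_entities",
    "get_suffix_spec",
    "list_suffixes",
    "units_for_map",
    "required_metadata",
    "get_map_spec",
    "list_maps",
    "canonical_metadata_key",
]

#: Linking entities recognized by the convention (in canonical order).
LINKING_ENTITIES = ("echo", "flip", "inv", "mt", "part")

REQ_LEVELS = frozenset({"required", "optional", "forbidden"})


class RegistryError(KeyError):
    """An unknown suffix, entity, or map was requested from the registry."""


@dataclass(frozen=True)
class EntityDef:
    """One linking entity: its value kind and the metadata field it indexes."""

    key: str
    value_kind: str  # "index" | "label"
    allowed_labels: frozenset[str] = frozenset()
    linked_metadata: str | None = None


@dataclass(frozen=True)
class RequiredField:
    """A required sidecar metadata field and the provenance of that level."""

    field: str
    source: str  # "paper" | "appendix"


@dataclass(frozen=True)
class SuffixSpec:
    """Schema record for one file-collection suffix."""

    suffix: str
    folder: str  # "anat" | "fmap"
    entity_req: dict[str, str]  # entity key -> required|optional|forbidden
    required_fields: tuple[RequiredField, ...]
    derived_maps: tuple[str, ...]
    allow_singleton: bool = False
    #: per-entity override of the metadata field that must be distinct
    #: across that entity's indices (defaults to the entity's linked field)
    distinct_field: dict[str, str] = field(default_factory=dict)

    @property
    def required_metadata(self) -> list[str]:
        return [f.field for f in self.required_fields]

    def required_entities(self) -> list[str]:
        return [k for k, v in self.entity_req.items() if v == "required"]

    def distinct_field_for(self, entity: str) -> str | None:
        """Metadata field that must differ across this entity's values."""
        if entity in self.distinct_field:
            return self.distinct_field[entity]
        return get_entity_def(entity).linked_metadata


@dataclass(frozen=True)
class MapSpec:
    """Units and acceptable numeric range for one quantitative map suffix."""

    map_suffix: str
    units: str
    valid_range: tuple[float | None, float | None] | None = None
    relaxometry: bool = False


def _check_registry(raw: dict) -> None:
    """Structural meta-schema for the registry file."""
    for section in ("entities", "suffixes", "maps", "entity_order"):
        if section not in raw:
            raise ValueError(f"registry is missing section {section!r}")
    for key, ent in raw["entities"].items():
        if ent["value_kind"] not in ("index", "label"):
            raise ValueError(f"entity {key!r}: bad value_kind")
        if ent["value_kind"] == "label" and not ent.get("allowed_labels"):
            raise ValueError(f"label entity {key!r} needs allowed_labels")
    for suffix, rec in raw["suffixes"].items():
        if rec["folder"] not in ("anat", "fmap"):
            raise ValueError(f"suffix {suffix!r}: folder must be anat or fmap")
        for ekey, level in rec["entity_req"].items():
            if ekey not in raw["entities"]:
                raise ValueError(f"suffix {suffix!r}: unknown entity {ekey!r}")
            if level not in REQ_LEVELS:
                raise ValueError(f"suffix {suffix!r}: bad level {level!r}")
        for item in rec.get("required_metadata", []):
            if item.get("source") not in ("paper", "appendix"):
                raise ValueError(
                    f"suffix {suffix!r}: field {item.get('field')!r} needs a "
                    "source of 'paper' or 'appendix'"
                )
        for m in rec.get("derived_maps", []):
            if m not in raw["maps"]:
                raise ValueError(
                    f"suffix {suffix!r}: derived map {m!r} has no units entry"
                )
    for m, rec in raw["maps"].items():
        if not isinstance(rec.get("units"), str):
            raise ValueError(f"map {m!r}: units must be a string")


@functools.cache
def _load() -> dict:
    text = (
        resources.files("qmribids").joinpath("data/registry.yaml").read_text("utf-8")
    )
    raw = yaml.safe_load(text)
    _check_registry(raw)

    entities = {
        key: EntityDef(
            key=key,
            value_kind=rec["value_kind"],
            allowed_labels=frozenset(rec.get("allowed_labels") or ()),
            linked_metadata=rec.get("linked_metadata"),
        )
        for key, rec in raw["entities"].items()
    }
    suffixes = {
        suffix: SuffixSpec(
            suffix=suffix,
            folder=rec["folder"],
            entity_req=dict(rec["entity_req"]),
            required_fields=tuple(
                RequiredField(field=i["field"], source=i["source"])
                for i in rec.get("required_metadata", [])
            ),
            derived_maps=tuple(rec.get("derived_maps", ())),
            allow_singleton=bool(rec.get("allow_singleton", False)),
            distinct_field=dict(rec.get("distinct_field", {})),
        )
        for suffix, rec in raw["suffixes"].items()
    }
    maps = {
        m: MapSpec(
            map_suffix=m,
            units=rec["units"],
            valid_range=tuple(rec["valid_range"]) if rec.get("valid_range") else None,
            relaxometry=bool(rec.get("relaxometry", False)),
        )
        for m, rec in raw["maps"].items()
    }
    return {
        "entities": entities,
        "suffixes": suffixes,
        "maps": maps,
        "entity_order": list(raw["entity_order"]),
        "aliases": dict(raw.get("metadata_aliases", {})),
    }


def entity_order() -> list[str]:
    """Canonical ordering of entity keys within a filename."""
    return list(_load()["entity_order"])


def list_entities() -> list[str]:
    return sorted(_load()["entities"])


def get_entity_def(key: str) -> EntityDef:
    try:
        return _load()["entities"][key]
    except KeyError:
        raise RegistryError(f"unknown linking entity {key!r}") from None


def list_suffixes() -> list[str]:
    return sorted(_load()["suffixes"])


def get_suffix_spec(suffix: str) -> SuffixSpec:
    try:
        return _load()["suffixes"][suffix]
    except KeyError:
        raise RegistryError(
            f"unknown file-collection suffix {suffix!r}; proprietary sequence "
            "names (e.g. 'FLASH') are not valid suffixes"
        ) from None


def list_maps() -> list[str]:
    return sorted(_load()["maps"])


def get_map_spec(map_suffix: str) -> MapSpec:
    try:
        return _load()["maps"][map_suffix]
    except KeyError:
        raise RegistryError(f"unknown quantitative map suffix {map_suffix!r}") from None


def units_for_map(map_suffix: str) -> str:
    """Canonical units for a quantitative map (s, 1/s, %, ppm, arbitrary)."""
    return get_map_spec(map_suffix).units


def required_metadata(suffix: str) -> list[str]:
    """Required sidecar metadata fields for a collection suffix."""
    return get_suffix_spec(suffix).required_metadata


def canonical_metadata_key(key: str) -> str:
    """Resolve alternate metadata spellings to the canonical registry key."""
    return _load()["aliases"].get(key, key)
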