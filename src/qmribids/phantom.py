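"""Digital phantom and synthetic qMRI-BIDS dataset generator.

Rasterizes simple geometric regions with tissue-like parameter values into
ground-truth volumes, evaluates the forward signal models of every supported
file collection, and writes a valid raw qMRI-BIDS dataset: one 3-D NIfTI per
entity combination, sidecar JSONs placed so BIDS inheritance is genuinely
exercised (collection constants at the dataset root, entity-varying fields
in entity-subset JSONs shared by magnitude and phase members), and
``dataset_description.json`` pinned to the BIDS release that incorporated
the qMRI extension (1.5.0).

Ground-truth parameter volumes are written to a sibling ``<name>_truth``
directory so the generated dataset itself stays standard-clean.  With a
fixed seed, generation is fully reproducible: byte-identical JSON and
voxel-identical NIfTI output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import schema
from .bids_io import ParsedName, build_filename, save_nifti, write_json
from .signal_models import (
    AfiProtocol,
    Mp2rageProtocol,
    MtsArm,
    MtsProtocol,
    SpgrProtocol,
    TissueParams,
    afi_ratio,
    dam_signals,
    ir_signal,
    monoexp_signal,
    mp2rage_block_signals,
    mts_signals,
    spgr_signal,
)

__all__ = [
    "ConfigurationError",
    "Region",
    "NoiseSpec",
    "PhantomSpec",
    "ProtocolSpec",
    "make_phantom",
    "default_phantom_spec",
    "default_protocols",
    "generate_dataset",
    "load_config",
    "PARAMETER_NAMES",
]


class ConfigurationError(ValueError):
    """A phantom or protocol configuration violates its invariants."""


PARAMETER_NAMES = (
    "T1",
    "T2",
    "T2star",
    "M0",
    "mtr_frac",
    "mtsat_delta",
    "chi",
    "b1_rel",
)

#: Tissue-like parameter triples for the default phantom (3 T-typical values;
#: times in seconds, M0 arbitrary).
DEFAULT_TISSUES = {
    "wm": dict(T1=0.85, T2=0.07, T2star=0.05, M0=800.0, mtr_frac=0.35,
               mtsat_delta=0.04, chi=0.02, b1_rel=1.0),
    "gm": dict(T1=1.4, T2=0.09, T2star=0.06, M0=900.0, mtr_frac=0.25,
               mtsat_delta=0.02, chi=0.01, b1_rel=1.0),
    "csf": dict(T1=3.2, T2=0.5, T2star=0.3, M0=1000.0, mtr_frac=0.02,
                mtsat_delta=0.002, chi=0.0, b1_rel=1.0),
}


@dataclass
class Region:
    """A sphere or box in voxel coordinates carrying one tissue."""

    geometry: dict
    tissue: TissueParams

    def mask(self, shape) -> np.ndarray:
        idx = np.indices(shape, dtype=float)
        g = self.geometry
        if g["type"] == "sphere":
            center = np.asarray(g["center"], dtype=float).reshape(3, 1, 1, 1)
            dist2 = ((idx - center) ** 2).sum(axis=0)
            return dist2 <= float(g["radius"]) ** 2
        if g["type"] == "box":
            lo = np.asarray(g["lo"], dtype=float).reshape(3, 1, 1, 1)
            hi = np.asarray(g["hi"], dtype=float).reshape(3, 1, 1, 1)
            return np.all((idx >= lo) & (idx <= hi), axis=0)
        raise ConfigurationError(f"unknown geometry type {g.get('type')!r}")


@dataclass
class NoiseSpec:
    model: str = "none"  # none | gaussian | rician
    sigma: float = 0.0
    seed: int = 2021

    def __post_init__(self):
        if self.model not in ("none", "gaussian", "rician"):
            raise ConfigurationError(f"unknown noise model {self.model!r}")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (32, 32, 32)
    regions: list[Region] = field(default_factory=list)
    background: TissueParams = field(
        default_factory=lambda: TissueParams(T1=1.0, T2=0.1, T2star=0.05, M0=0.0)
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)


@dataclass
class ProtocolSpec:
    """Acquisition protocol for one collection suffix plus constant metadata."""

    suffix: str
    parameters: dict = field(default_factory=dict)
    constants: dict = field(default_factory=dict)

    def __post_init__(self):
        schema.get_suffix_spec(self.suffix)


def default_phantom_spec(noise: NoiseSpec | None = None) -> PhantomSpec:
    """The default 32^3 phantom: three nested WM/GM/CSF-like spheres."""
    center = [16.0, 16.0, 16.0]
    radii = {"wm": 12.0, "gm": 8.0, "csf": 4.0}
    regions = [
        Region(
            geometry={"type": "sphere", "center": center, "radius": radii[name]},
            tissue=TissueParams(**DEFAULT_TISSUES[name]),
        )
        for name in ("wm", "gm", "csf")
    ]
    return PhantomSpec(
        shape=(32, 32, 32), regions=regions, noise=noise or NoiseSpec()
    )


def make_phantom(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Rasterize regions into per-parameter ground-truth volumes.

    Later regions overwrite earlier ones where they overlap.
    """
    if not spec.regions:
        raise ConfigurationError("phantom needs at least one region")
    shape = tuple(int(n) for n in spec.shape)
    volumes = {
        name: np.full(shape, float(getattr(spec.background, name)))
        for name in PARAMETER_NAMES
    }
    for region in spec.regions:
        region.tissue.validate()
        mask = region.mask(shape)
        if not mask.any():
            raise ConfigurationError("region lies entirely outside the grid")
        for name in PARAMETER_NAMES:
            volumes[name][mask] = float(getattr(region.tissue, name))
    return volumes


def _tissue_from_volumes(vols: dict[str, np.ndarray]) -> TissueParams:
    return TissueParams(**{name: vols[name] for name in PARAMETER_NAMES})


# ---------------------------------------------------------------------------
# per-suffix forward generation
#
# Each generator returns (files, sidecars):
#   files:    list of (entities, extras, volume) per image file
#   sidecars: list of (entity_subset | None, values); None places the JSON at
#             the dataset root (<suffix>.json), a subset dict in the leaf
#             directory, shared by every member matching the subset.

FIELD_STRENGTH = 3.0


def _gen_mp2rage(t: TissueParams, prm: dict):
    p = Mp2rageProtocol(
        tr_prep=prm["tr_prep"],
        tr_exc=prm["tr_exc"],
        ti=tuple(prm["ti"]),
        flips_deg=tuple(prm["flips_deg"]),
        n_exc=int(prm["n_exc"]),
        inv_eff=prm.get("inv_eff", 0.96),
    )
    s1, s2 = mp2rage_block_signals(t, p)
    shape = np.broadcast(s1, np.asarray(t.M0)).shape
    ii, jj, _ = np.indices(shape, dtype=float)
    ramp = 0.6 * np.pi * ii / shape[0] + 0.4 * np.pi * jj / shape[1] - 0.5 * np.pi
    files = []
    for inv, s in ((1, s1), (2, s2)):
        cplx = np.broadcast_to(s, shape) * np.exp(1j * ramp)
        files.append(({"inv": inv, "part": "mag"}, {}, np.abs(cplx)))
        files.append(({"inv": inv, "part": "phase"}, {}, np.angle(cplx)))
    sidecars = [
        (None, {
            "RepetitionTimePreparation": p.tr_prep,
            "RepetitionTimeExcitation": p.tr_exc,
            "NumberShots": p.n_exc,
            "MagneticFieldStrength": FIELD_STRENGTH,
        }),
        ({"inv": 1}, {"InversionTime": p.ti[0], "FlipAngle": p.flips_deg[0]}),
        ({"inv": 2}, {"InversionTime": p.ti[1], "FlipAngle": p.flips_deg[1]}),
    ]
    return files, sidecars


def _gen_vfa(t: TissueParams, prm: dict):
    tr = prm["tr"]
    files, sidecars = [], [
        (None, {
            "RepetitionTimeExcitation": tr,
            "MagneticFieldStrength": FIELD_STRENGTH,
        })
    ]
    for i, flip in enumerate(prm["flips_deg"], start=1):
        vol = spgr_signal(t, SpgrProtocol(tr=tr, flip_deg=flip))
        files.append(({"flip": i}, {}, vol))
        sidecars.append(({"flip": i}, {"FlipAngle": flip}))
    return files, sidecars


def _gen_irt1(t: TissueParams, prm: dict):
    tr = prm["tr_prep"]
    files, sidecars = [], [
        (None, {
            "RepetitionTimePreparation": tr,
            "MagneticFieldStrength": FIELD_STRENGTH,
        })
    ]
    for i, ti in enumerate(prm["tis"], start=1):
        vol = np.abs(ir_signal(t, ti, tr))  # magnitude reconstruction
        files.append(({"inv": i}, {}, vol))
        sidecars.append(({"inv": i}, {"InversionTime": ti}))
    return files, sidecars


def _gen_multiecho(which: str):
    def gen(t: TissueParams, prm: dict):
        tc = t.T2 if which == "T2" else t.T2star
        files, sidecars = [], [
            (None, {
                "RepetitionTimeExcitation": prm["tr"],
                "MagneticFieldStrength": FIELD_STRENGTH,
            })
        ]
        for i, te in enumerate(prm["tes"], start=1):
            files.append(({"echo": i}, {}, monoexp_signal(t.M0, tc, te)))
            sidecars.append(({"echo": i}, {"EchoTime": te}))
        return files, sidecars

    return gen


def _gen_mtr(t: TissueParams, prm: dict):
    off = spgr_signal(t, SpgrProtocol(tr=prm["tr"], flip_deg=prm["flip_deg"]))
    on = off * (1.0 - np.asarray(t.mtr_frac))
    files = [({"mt": "off"}, {}, off), ({"mt": "on"}, {}, on)]
    sidecars = [
        (None, {
            "FlipAngle": prm["flip_deg"],
            "RepetitionTimeExcitation": prm["tr"],
        }),
        ({"mt": "off"}, {"MTState": False}),
        ({"mt": "on"}, {"MTState": True}),
    ]
    return files, sidecars


def _gen_mts(t: TissueParams, prm: dict):
    arms = prm["arms"]
    p = MtsProtocol(
        mtw=MtsArm(arms["mtw"]["flip_deg"], arms["mtw"]["tr"], "on"),
        pdw=MtsArm(arms["pdw"]["flip_deg"], arms["pdw"]["tr"], "off"),
        t1w=MtsArm(arms["t1w"]["flip_deg"], arms["t1w"]["tr"], "off"),
    )
    smt, spd, st1 = mts_signals(t, p)
    files = [
        ({"flip": 1, "mt": "on"}, {}, smt),
        ({"flip": 1, "mt": "off"}, {}, spd),
        ({"flip": 2, "mt": "off"}, {}, st1),
    ]
    sidecars = [
        (None, {
            "RepetitionTimeExcitation": p.pdw.tr,
            "MagneticFieldStrength": FIELD_STRENGTH,
        }),
        ({"flip": 1}, {"FlipAngle": p.pdw.flip_deg}),
        ({"flip": 2}, {"FlipAngle": p.t1w.flip_deg}),
        ({"mt": "on"}, {"MTState": True}),
        ({"mt": "off"}, {"MTState": False}),
    ]
    return files, sidecars


def _gen_tb1dam(t: TissueParams, prm: dict):
    nominal = prm["nominal_deg"]
    s1, s2 = dam_signals(t, nominal)
    files = [({"flip": 1}, {}, s1), ({"flip": 2}, {}, s2)]
    sidecars = [
        (None, {"MagneticFieldStrength": FIELD_STRENGTH}),
        ({"flip": 1}, {"FlipAngle": nominal}),
        ({"flip": 2}, {"FlipAngle": 2 * nominal}),
    ]
    return files, sidecars


def _gen_tb1afi(t: TissueParams, prm: dict):
    p = AfiProtocol(tr1=prm["tr1"], tr2=prm["tr2"], flip_deg=prm["flip_deg"])
    s1 = np.asarray(t.M0) * np.sin(np.deg2rad(p.flip_deg) * np.asarray(t.b1_rel))
    s2 = s1 * afi_ratio(t, p)
    files = [({"flip": 1}, {}, s1), ({"flip": 2}, {}, s2)]
    sidecars = [
        (None, {
            "FlipAngle": p.flip_deg,
            "MagneticFieldStrength": FIELD_STRENGTH,
        }),
        ({"flip": 1}, {"RepetitionTimeExcitation": p.tr1}),
        ({"flip": 2}, {"RepetitionTimeExcitation": p.tr2}),
    ]
    return files, sidecars


def _gen_tb1epi(t: TissueParams, prm: dict):
    files, sidecars = [], [(None, {"MagneticFieldStrength": FIELD_STRENGTH})]
    for fi, flip in enumerate(prm["flips_deg"], start=1):
        sidecars.append(({"flip": fi}, {"FlipAngle": flip}))
        for ei, te in enumerate(prm["tes"], start=1):
            vol = np.abs(
                np.asarray(t.M0)
                * np.sin(np.deg2rad(flip) * np.asarray(t.b1_rel))
            ) * np.exp(-te / np.asarray(t.T2star))
            files.append(({"flip": fi, "echo": ei}, {}, vol))
            if fi == 1:
                sidecars.append(({"echo": ei}, {"EchoTime": te}))
    return files, sidecars


def _gen_tb1tfl(t: TissueParams, prm: dict):
    # flip-angle-map acquisition: voxel value proportional to the local flip
    vol = np.asarray(t.b1_rel) * prm["flip_deg"] * 10.0
    files = [({}, {"acq": "famp"}, vol)]
    sidecars = [(None, {"FlipAngle": prm["flip_deg"]})]
    return files, sidecars


def _gen_tb1srge(t: TissueParams, prm: dict):
    files, sidecars = [], [
        (None, {
            "RepetitionTimePreparation": prm["tr_prep"],
            "MagneticFieldStrength": FIELD_STRENGTH,
        })
    ]
    for fi, flip in enumerate(prm["flips_deg"], start=1):
        sidecars.append(({"flip": fi}, {"FlipAngle": flip}))
    for ii, ti in enumerate(prm["tis"], start=1):
        sidecars.append(({"inv": ii}, {"InversionTime": ti}))
    for fi, flip in enumerate(prm["flips_deg"], start=1):
        for ii, ti in enumerate(prm["tis"], start=1):
            vol = np.asarray(t.M0) * np.sin(
                np.deg2rad(flip) * np.asarray(t.b1_rel)
            ) * (1 - np.exp(-ti / np.asarray(t.T1)))
            files.append(({"flip": fi, "inv": ii}, {}, vol))
    return files, sidecars


def _gen_rb1cor(t: TissueParams, prm: dict):
    files = [
        ({}, {"acq": "head"}, np.asarray(t.M0) * 1.0),
        ({}, {"acq": "body"}, np.asarray(t.M0) * 0.8),
    ]
    return files, [(None, {})]


def _gen_mpm(t: TissueParams, prm: dict):
    tr = prm["tr"]
    arms = prm["arms"]  # list of {"flip_deg", "mt"}
    flips = sorted({a["flip_deg"] for a in arms})
    flip_index = {f: i + 1 for i, f in enumerate(flips)}
    files, sidecars = [], [
        (None, {
            "RepetitionTimeExcitation": tr,
            "MagneticFieldStrength": FIELD_STRENGTH,
        })
    ]
    for f in flips:
        sidecars.append(({"flip": flip_index[f]}, {"FlipAngle": f}))
    for ei, te in enumerate(prm["tes"], start=1):
        sidecars.append(({"echo": ei}, {"EchoTime": te}))
    sidecars.append(({"mt": "on"}, {"MTState": True}))
    sidecars.append(({"mt": "off"}, {"MTState": False}))
    for arm in arms:
        base = spgr_signal(t, SpgrProtocol(tr=tr, flip_deg=arm["flip_deg"]))
        if arm["mt"] == "on":
            base = base * (1.0 - np.asarray(t.mtr_frac))
        for ei, te in enumerate(prm["tes"], start=1):
            vol = base * np.exp(-te / np.asarray(t.T2star))
            files.append(
                ({"echo": ei, "flip": flip_index[arm["flip_deg"]],
                  "mt": arm["mt"]}, {}, vol)
            )
    return files, sidecars


_GENERATORS = {
    "MP2RAGE": _gen_mp2rage,
    "VFA": _gen_vfa,
    "IRT1": _gen_irt1,
    "MESE": _gen_multiecho("T2"),
    "MEGRE": _gen_multiecho("T2star"),
    "MTR": _gen_mtr,
    "MTS": _gen_mts,
    "TB1DAM": _gen_tb1dam,
    "TB1AFI": _gen_tb1afi,
    "TB1EPI": _gen_tb1epi,
    "TB1TFL": _gen_tb1tfl,
    "TB1SRGE": _gen_tb1srge,
    "RB1COR": _gen_rb1cor,
    "MPM": _gen_mpm,
}

DEFAULT_PARAMETERS = {
    "MP2RAGE": {"tr_prep": 5.0, "tr_exc": 0.0062, "ti": [0.8, 2.7],
                "flips_deg": [4.0, 5.0], "n_exc": 160, "inv_eff": 0.96},
    "VFA": {"flips_deg": [6.0, 20.0], "tr": 0.015},
    "IRT1": {"tis": [0.1, 0.4, 0.9, 2.0], "tr_prep": 5.0},
    "MESE": {"tes": [0.02, 0.04, 0.06, 0.08], "tr": 3.0},
    "MEGRE": {"tes": [0.005, 0.010, 0.015, 0.020], "tr": 0.05},
    "MTR": {"flip_deg": 10.0, "tr": 0.03},
    "MTS": {"arms": {"mtw": {"flip_deg": 6.0, "tr": 0.025},
                     "pdw": {"flip_deg": 6.0, "tr": 0.025},
                     "t1w": {"flip_deg": 20.0, "tr": 0.025}}},
    "TB1DAM": {"nominal_deg": 60.0},
    "TB1AFI": {"tr1": 0.02, "tr2": 0.1, "flip_deg": 60.0},
    "TB1EPI": {"flips_deg": [60.0, 120.0], "tes": [0.01, 0.03]},
    "TB1TFL": {"flip_deg": 60.0},
    "TB1SRGE": {"flips_deg": [4.0, 10.0], "tis": [0.1, 0.9], "tr_prep": 2.4},
    "RB1COR": {},
    "MPM": {"tr": 0.025, "tes": [0.005, 0.010],
            "arms": [{"flip_deg": 6.0, "mt": "off"},
                     {"flip_deg": 20.0, "mt": "off"},
                     {"flip_deg": 6.0, "mt": "on"}]},
}


def default_protocols(suffixes=None) -> list[ProtocolSpec]:
    """Default protocol for each requested suffix (all 14 if none given)."""
    if suffixes is None:
        suffixes = sorted(_GENERATORS)
    return [
        ProtocolSpec(suffix=s, parameters=dict(DEFAULT_PARAMETERS[s]))
        for s in suffixes
    ]


def _apply_noise(volume: np.ndarray, noise: NoiseSpec, rng) -> np.ndarray:
    if noise.model == "none" or noise.sigma == 0:
        return volume
    if noise.model == "gaussian":
        return volume + rng.normal(0.0, noise.sigma, volume.shape)
    # rician: magnitude of a complex signal with iid gaussian channels
    re = volume + rng.normal(0.0, noise.sigma, volume.shape)
    im = rng.normal(0.0, noise.sigma, volume.shape)
    return np.hypot(re, im)


def generate_dataset(
    phantom: PhantomSpec | dict[str, np.ndarray],
    protocols: list[ProtocolSpec],
    out_root: str | Path,
    subject: str = "01",
    write_truth: bool = True,
) -> Path:
    """Write a raw qMRI-BIDS dataset for the given phantom and protocols.

    Returns the dataset root.  Noise (from the phantom spec, if any) is
    applied after forward modeling, with a generator seeded per dataset so
    repeated runs are identical.
    """
    out_root = Path(out_root)
    if isinstance(phantom, PhantomSpec):
        volumes = make_phantom(phantom)
        noise = phantom.noise
    else:
        volumes = phantom
        noise = NoiseSpec()
    tissue = _tissue_from_volumes(volumes)
    affine = np.eye(4)
    rng = np.random.default_rng(noise.seed)

    out_root.mkdir(parents=True, exist_ok=True)
    write_json(
        out_root / "dataset_description.json",
        {
            "Name": "qmribids digital phantom",
            "BIDSVersion": "1.5.0",
            "DatasetType": "raw",
            "GeneratedBy": [{"Name": "qmribids", "Version": _version()}],
        },
    )

    for proto in sorted(protocols, key=lambda p: p.suffix):
        if proto.suffix not in _GENERATORS:
            raise ConfigurationError(f"no generator for suffix {proto.suffix!r}")
        spec = schema.get_suffix_spec(proto.suffix)
        params = {**DEFAULT_PARAMETERS[proto.suffix], **proto.parameters}
        files, sidecars = _GENERATORS[proto.suffix](tissue, params)
        folder = out_root / f"sub-{subject}" / spec.folder
        for entities, extras, volume in files:
            name = ParsedName(
                subject=subject, entities=dict(entities), extras=dict(extras),
                suffix=proto.suffix,
            )
            noisy = _apply_noise(np.asarray(volume, dtype=float), noise, rng)
            save_nifti(folder / build_filename(name), noisy, affine)
        for subset, values in sidecars:
            values = {**values, **proto.constants}
            if not values:
                continue
            if subset is None:
                write_json(out_root / f"{proto.suffix}.json", values)
            else:
                name = ParsedName(
                    subject=subject, entities=dict(subset),
                    suffix=proto.suffix, extension=".json",
                )
                write_json(folder / build_filename(name), values)

    if write_truth:
        truth_dir = out_root.parent / f"{out_root.name}_truth"
        for pname, vol in volumes.items():
            save_nifti(truth_dir / f"{pname}.nii.gz", vol, affine)
    return out_root


def _version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# configuration file


def load_config(path: str | Path) -> tuple[PhantomSpec, list[ProtocolSpec]]:
    """Read a phantom + protocol configuration from a YAML file.

    Structure::

        phantom:
          shape: [32, 32, 32]
          regions:
            - geometry: {type: sphere, center: [16, 16, 16], radius: 12}
              tissue: {T1: 0.85, T2: 0.07, T2star: 0.05, M0: 800}
          noise: {model: gaussian, sigma: 8.0, seed: 2021}
        protocols: [VFA, MEGRE]          # or records with parameter overrides

    Omitted sections fall back to the package defaults.
    """
    raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
    ph = raw.get("phantom")
    if ph is None:
        spec = default_phantom_spec()
    else:
        regions = [
            Region(
                geometry=dict(r["geometry"]),
                tissue=_tissue_with_defaults(r.get("tissue", {})),
            )
            for r in ph.get("regions", [])
        ]
        if not regions:
            spec = default_phantom_spec()
            regions = spec.regions
        noise = NoiseSpec(**ph.get("noise", {}))
        background = _tissue_with_defaults(
            ph.get("background", {"T1": 1.0, "T2": 0.1, "T2star": 0.05, "M0": 0.0})
        )
        spec = PhantomSpec(
            shape=tuple(ph.get("shape", (32, 32, 32))),
            regions=regions,
            background=background,
            noise=noise,
        )
    protos = raw.get("protocols")
    if protos is None:
        protocols = default_protocols()
    else:
        protocols = []
        for item in protos:
            if isinstance(item, str):
                protocols.append(
                    ProtocolSpec(item, dict(DEFAULT_PARAMETERS[item]))
                )
            else:
                protocols.append(
                    ProtocolSpec(
                        item["suffix"],
                        {**DEFAULT_PARAMETERS[item["suffix"]],
                         **item.get("parameters", {})},
                        dict(item.get("constants", {})),
                    )
                )
    return spec, protocols


def _tissue_with_defaults(values: dict) -> TissueParams:
    known = {f.name for f in dataclasses.fields(TissueParams)}
    unknown = set(values) - known
    if unknown:
        raise ConfigurationError(f"unknown tissue parameters {sorted(unknown)}")
    base = dict(T1=1.0, T2=0.1, T2star=0.05, M0=0.0)
    base.update(values)
    return TissueParams(**base)
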