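"""Voxelwise inverse problems: file collections in, quantitative maps out.

Every fitter is pure (same inputs and configuration give bit-identical
maps), accepts bare arrays or :class:`~qmribids.bids_io.ImageVolume` lists,
and returns a :class:`FitResult` whose maps carry NaN at unfittable voxels.
Map keys are registered map suffixes, so units always resolve through the
schema registry.

Solver choices favor determinism: VFA uses the linearized least-squares
form (exact on noiseless data, with a documented bias under noise);
multi-echo decay uses signal-weighted log-linear least squares; inversion
recovery uses a 1-D variable-projection search with polarity restoration for
magnitude data; MP2RAGE inverts a monotone UNI(T1) lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import schema
from .bids_io import ImageVolume
from .signal_models import (
    AfiProtocol,
    Mp2rageProtocol,
    MtsProtocol,
    ProtocolError,
    TissueParams,
    mp2rage_block_signals,
    mp2rage_uni,
)

__all__ = [
    "FitResult",
    "fit_vfa",
    "fit_ir",
    "fit_monoexp",
    "compute_mtr",
    "compute_mtsat",
    "fit_mp2rage",
    "fit_dam",
    "fit_afi",
]


@dataclass
class FitResult:
    """Fitted parameter volumes plus the voxel mask and solver diagnostics."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        for suffix in self.maps:
            schema.get_map_spec(suffix)  # unknown suffix -> RegistryError
        self.diagnostics.setdefault("n_masked", int(np.sum(~self.mask)))

    def units(self, map_suffix: str) -> str:
        return schema.units_for_map(map_suffix)


def _as_array(v) -> np.ndarray:
    if isinstance(v, ImageVolume):
        return v.voxels
    return np.asarray(v, dtype=float)


def _stack(signals) -> np.ndarray:
    arrays = [_as_array(s) for s in signals]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError(f"volume shapes differ: {a.shape} vs {shape}")
    return np.stack(arrays, axis=0)


def _masked(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.where(mask, volume, np.nan)
    return out


# ---------------------------------------------------------------------------
# relaxometry


def fit_vfa(signals, flips_deg, tr: float, b1map=None) -> FitResult:
    """T1 and M0 from variable-flip-angle SPGR via the linearized form.

    Regressing y = S/sin(a) on x = S/tan(a) per voxel gives slope
    E1 = exp(-TR/T1), so T1 = -TR/ln(slope) and M0 = intercept/(1 - slope).
    With a relative B1+ map (percent, 100 = nominal) the nominal flips are
    scaled per voxel before linearization.
    """
    flips = np.asarray(flips_deg, dtype=float)
    if flips.size < 2 or np.unique(flips).size < 2:
        raise ProtocolError("VFA needs at least two distinct flip angles")
    s = _stack(signals)
    a = np.deg2rad(flips).reshape((-1,) + (1,) * (s.ndim - 1))
    if b1map is not None:
        a = a * (np.asarray(b1map, dtype=float) / 100.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = s / np.sin(a)
        x = s / np.tan(a)
        n = s.shape[0]
        xm = x.mean(axis=0)
        ym = y.mean(axis=0)
        sxx = ((x - xm) ** 2).sum(axis=0)
        sxy = ((x - xm) * (y - ym)).sum(axis=0)
        slope = sxy / sxx
        intercept = ym - slope * xm
        valid = (
            np.isfinite(slope)
            & (slope > 0)
            & (slope < 1)
            & np.any(s != 0, axis=0)
        )
        t1 = np.where(valid, -tr / np.log(np.where(valid, slope, 0.5)), np.nan)
        m0 = np.where(valid, intercept / (1.0 - slope), np.nan)
    return FitResult(
        maps={"T1map": _masked(t1, valid), "M0map": _masked(m0, valid)},
        mask=valid,
        diagnostics={"solver": "linearized least squares", "n_flips": int(n)},
    )


def _ir_varpro(signal: np.ndarray, tis: np.ndarray, t1_bounds=(1e-3, 20.0)):
    """Best (residual, T1, a, b) for S(ti) = a + b exp(-ti/T1), signed data."""

    def linfit(t1):
        design = np.column_stack([np.ones_like(tis), np.exp(-tis / t1)])
        coef, res, *_ = np.linalg.lstsq(design, signal, rcond=None)
        r = signal - design @ coef
        return float(r @ r), coef

    def objective(log_t1):
        return linfit(np.exp(log_t1))[0]

    result = optimize.minimize_scalar(
        objective,
        bounds=(np.log(t1_bounds[0]), np.log(t1_bounds[1])),
        method="bounded",
        options={"xatol": 1e-12},
    )
    t1 = float(np.exp(result.x))
    res, coef = linfit(t1)
    return res, t1, float(coef[0]), float(coef[1])


def fit_ir(signals, tis, tr: float, magnitude: bool = False) -> FitResult:
    """T1 from inversion recovery, S(TI) = a + b exp(-TI/T1).

    For magnitude data the polarity of the early inversion times is unknown;
    every candidate null-crossing position is tried (sign-flipping the first
    k samples) and the lowest-residual fit kept.  Identical voxel
    time-series are deduplicated before the per-voxel 1-D solve, which is
    exact, not an approximation.
    """
    tis = np.asarray(tis, dtype=float)
    if tis.size < 3:
        raise ProtocolError("inversion recovery needs at least three TIs")
    s = _stack(signals)
    shape = s.shape[1:]
    flat = s.reshape(s.shape[0], -1).T  # (voxels, n_ti)
    order = np.argsort(tis)
    tis_sorted = tis[order]
    flat = flat[:, order]

    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    t1_u = np.full(uniq.shape[0], np.nan)
    m0_u = np.full(uniq.shape[0], np.nan)
    for i, sig in enumerate(uniq):
        if not np.all(np.isfinite(sig)) or np.ptp(sig) == 0:
            continue  # constant signal carries no decay information
        candidates = [sig] if not magnitude else [
            np.concatenate([-sig[:k], sig[k:]]) for k in range(len(sig) + 1)
        ]
        best = None
        for cand in candidates:
            res, t1, a, b = _ir_varpro(cand, tis_sorted)
            if best is None or res < best[0]:
                best = (res, t1, a, b)
        res, t1, a, b = best
        if t1 <= 1.001e-3 or t1 >= 19.9:
            continue  # pinned to the search bounds: not converged
        t1_u[i] = t1
        m0_u[i] = -b / 2.0

    t1_map = t1_u[inverse].reshape(shape)
    m0_map = m0_u[inverse].reshape(shape)
    mask = np.isfinite(t1_map)
    return FitResult(
        maps={"T1map": t1_map, "M0map": m0_map},
        mask=mask,
        diagnostics={
            "solver": "variable projection + polarity restoration",
            "n_unique_series": int(uniq.shape[0]),
        },
    )


def fit_monoexp(signals, tes, map_suffix: str = "T2map") -> FitResult:
    """Monoexponential decay time from multi-echo data.

    Signal-weighted log-linear least squares of ln S = ln M0 - TE/tc; the
    weights counter the heteroscedasticity the log transform introduces.
    Serves MESE (tc = T2) and MEGRE (tc = T2*).  Voxels with a non-positive
    signal at any echo are masked.
    """
    if map_suffix not in ("T2map", "T2starmap"):
        raise ValueError("map_suffix must be 'T2map' or 'T2starmap'")
    tes = np.asarray(tes, dtype=float)
    if tes.size < 2 or np.unique(tes).size != tes.size:
        raise ProtocolError("need at least two distinct echo times")
    s = _stack(signals)
    te = tes.reshape((-1,) + (1,) * (s.ndim - 1))
    valid = np.all(s > 0, axis=0) & np.all(np.isfinite(s), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(s > 0, s, np.nan)
        logs = np.log(np.where(s > 0, s, np.nan))
        wsum = np.nansum(w, axis=0)
        xm = np.nansum(w * te, axis=0) / wsum
        ym = np.nansum(w * logs, axis=0) / wsum
        sxx = np.nansum(w * (te - xm) ** 2, axis=0)
        sxy = np.nansum(w * (te - xm) * (logs - ym), axis=0)
        slope = sxy / sxx
        valid &= np.isfinite(slope) & (slope < 0)
        tc = np.where(valid, -1.0 / slope, np.nan)
        m0 = np.where(valid, np.exp(ym - slope * xm), np.nan)
    return FitResult(
        maps={map_suffix: tc, "M0map": _masked(m0, valid)},
        mask=valid,
        diagnostics={"solver": "weighted log-linear least squares"},
    )


# ---------------------------------------------------------------------------
# ratio and MT maps


def compute_mtr(s_off, s_on) -> FitResult:
    """Magnetization transfer ratio, 100 (S_off - S_on)/S_off, in percent."""
    off = _as_array(s_off)
    on = _as_array(s_on)
    if off.shape != on.shape:
        raise ValueError(f"shape mismatch: {off.shape} vs {on.shape}")
    valid = off > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mtr = np.where(valid, 100.0 * (off - on) / off, np.nan)
    n_sub_zero = int(np.sum(mtr[valid] < 0))
    return FitResult(
        maps={"MTRmap": mtr},
        mask=valid,
        diagnostics={"n_negative": n_sub_zero},
    )


def compute_mtsat(s_mt, s_pd, s_t1, p: MtsProtocol) -> FitResult:
    """MT saturation, apparent R1 and amplitude from the MTS triple.

    Closed-form inversion of the rational small-angle SPGR model: the PDw
    and T1w arms give R1 and the apparent amplitude A, and the MTw arm's
    signal deficit gives the per-excitation saturation delta.  MTsat is
    reported as delta*100, following the percent-style convention of ratio
    maps (the acceptable numeric range is anatomy-dependent and not
    enforced).
    """
    smt, spd, st1 = (_as_array(v) for v in (s_mt, s_pd, s_t1))
    a_pd = np.deg2rad(p.pdw.flip_deg)
    a_t1 = np.deg2rad(p.t1w.flip_deg)
    a_mt = np.deg2rad(p.mtw.flip_deg)
    tr_pd, tr_t1, tr_mt = p.pdw.tr, p.t1w.tr, p.mtw.tr
    if np.isclose(a_pd, a_t1):
        raise ProtocolError("PDw and T1w flip angles must differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom_r1 = spd / a_pd - st1 / a_t1
        denom_a = st1 * tr_pd * a_t1 - spd * tr_t1 * a_pd
        valid = (
            (denom_r1 > 0) & (denom_a != 0) & (smt > 0) & (spd > 0) & (st1 > 0)
        )
        r1 = 0.5 * (st1 * a_t1 / tr_t1 - spd * a_pd / tr_pd) / denom_r1
        amp = spd * st1 * (tr_pd * a_t1 / a_pd - tr_t1 * a_pd / a_t1) / denom_a
        delta = (amp * a_mt / smt - 1.0) * r1 * tr_mt - a_mt**2 / 2.0
        valid &= np.isfinite(delta) & (r1 > 0)
    return FitResult(
        maps={
            "MTsat": _masked(delta * 100.0, valid),
            "R1map": _masked(r1, valid),
            "M0map": _masked(amp, valid),
        },
        mask=valid,
        diagnostics={"solver": "rational small-angle closed form"},
    )


# ---------------------------------------------------------------------------
# MP2RAGE


def mp2rage_lookup(
    p: Mp2rageProtocol, t1_range=(0.05, 5.0), t1_step: float = 0.001
):
    """UNI(T1) lookup restricted to its maximal monotonic sub-interval.

    Returns (t1_grid, uni_values), both ordered by increasing T1, plus a
    flag telling whether the full requested range had to be restricted.
    """
    t1_grid = np.arange(t1_range[0], t1_range[1] + t1_step / 2, t1_step)
    tissue = TissueParams(
        T1=t1_grid,
        T2=np.minimum(t1_grid, 1.0),
        T2star=np.minimum(t1_grid, 1.0),
        M0=1.0,
    )
    s1, s2 = mp2rage_block_signals(tissue, p)
    uni = mp2rage_uni(s1, s2)

    diffs = np.sign(np.diff(uni))
    # longest run of strictly consistent monotonicity
    best_start, best_len = 0, 0
    start = 0
    for i in range(1, len(diffs) + 1):
        if i == len(diffs) or diffs[i] != diffs[start] or diffs[i] == 0:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    lo, hi = best_start, best_start + best_len + 1
    restricted = (lo, hi) != (0, len(t1_grid))
    return t1_grid[lo:hi], uni[lo:hi], restricted


def fit_mp2rage(
    s1,
    s2,
    p: Mp2rageProtocol,
    t1_range=(0.05, 5.0),
    t1_step: float = 0.001,
) -> FitResult:
    """T1 by interpolated inversion of the monotone UNI(T1) lookup table.

    ``s1``/``s2`` are the complex block signals (magnitude times e^{i phase});
    their UNI combination is invariant to receive field and M0.  Voxels whose
    UNI falls outside the lookup span are masked; the fit resolution equals
    the grid step (1 ms by default).
    """
    s1 = np.asarray(_as_array_complex(s1))
    s2 = np.asarray(_as_array_complex(s2))
    grid, uni_grid, restricted = mp2rage_lookup(p, t1_range, t1_step)
    uni = mp2rage_uni(s1, s2)
    increasing = uni_grid[-1] > uni_grid[0]
    xs = uni_grid if increasing else uni_grid[::-1]
    ys = grid if increasing else grid[::-1]
    valid = np.isfinite(uni) & (uni >= xs[0]) & (uni <= xs[-1])
    t1 = np.where(valid, np.interp(np.where(valid, uni, xs[0]), xs, ys), np.nan)
    diag = {
        "lookup_points": int(len(grid)),
        "lookup_restricted": bool(restricted),
        "t1_step": float(t1_step),
    }
    return FitResult(maps={"T1map": t1}, mask=valid, diagnostics=diag)


def _as_array_complex(v):
    if isinstance(v, ImageVolume):
        return v.voxels.astype(complex)
    return np.asarray(v, dtype=complex)


# ---------------------------------------------------------------------------
# B1+ mapping


def fit_dam(s1, s2, nominal_deg: float) -> FitResult:
    """Relative B1+ from the double-angle method.

    TB1map = 100 arccos(S2 / (2 S1)) / a_nominal; the ratio is clamped to
    [-1, 1] (noise excursions are counted in diagnostics rather than
    masked, keeping the map dense).  Voxels with S1 <= 0 are masked.
    """
    a_nom = np.deg2rad(nominal_deg)
    v1 = _as_array(s1)
    v2 = _as_array(s2)
    if v1.shape != v2.shape:
        raise ValueError(f"shape mismatch: {v1.shape} vs {v2.shape}")
    valid = v1 > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, v2 / (2.0 * v1), np.nan)
    n_clipped = int(np.nansum((ratio < -1) | (ratio > 1)))
    ratio = np.clip(ratio, -1.0, 1.0)
    tb1 = np.where(valid, 100.0 * np.arccos(ratio) / a_nom, np.nan)
    return FitResult(
        maps={"TB1map": tb1},
        mask=valid,
        diagnostics={"n_clipped": n_clipped},
    )


def fit_afi(s1, s2, p: AfiProtocol, nominal_deg: float | None = None) -> FitResult:
    """Relative B1+ from actual flip angle imaging.

    With r = S2/S1 and n = TR2/TR1, cos(a) = (r n - 1)/(n - r); the actual
    flip is referenced to the nominal one in relative percent.  Voxels with
    |cos(a)| > 1 or r = n are masked.
    """
    if p.n <= 1:
        raise ProtocolError("AFI requires TR2 > TR1")
    nominal = p.flip_deg if nominal_deg is None else nominal_deg
    v1 = _as_array(s1)
    v2 = _as_array(s2)
    if v1.shape != v2.shape:
        raise ValueError(f"shape mismatch: {v1.shape} vs {v2.shape}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(v1 != 0, v2 / v1, np.nan)
        denom = p.n - r
        cosa = np.where(denom != 0, (r * p.n - 1.0) / denom, np.nan)
    valid = np.isfinite(cosa) & (np.abs(cosa) <= 1.0) & (v1 > 0)
    tb1 = np.where(
        valid,
        100.0 * np.arccos(np.clip(cosa, -1, 1)) / np.deg2rad(nominal),
        np.nan,
    )
    return FitResult(
        maps={"TB1map": tb1},
        mask=valid,
        diagnostics={"n": float(p.n)},
    )


# ---------------------------------------------------------------------------
# collection-level dispatch

#: suffixes fit_collection can process (the others are schema-only)
FITTABLE_SUFFIXES = (
    "VFA", "IRT1", "MESE", "MEGRE", "MTR", "MTS", "MP2RAGE", "TB1DAM", "TB1AFI",
)


def _member_volumes(c) -> list[np.ndarray]:
    from .bids_io import load_volume

    return [load_volume(m.path).voxels for m in c.members]


def _shared_constants(c) -> dict:
    """Scalar metadata identical across every member's resolved sidecar."""
    keys = set.intersection(*(set(m.sidecar.values) for m in c.members))
    constants = {}
    for key in sorted(keys):
        values = [m.sidecar.values[key] for m in c.members]
        if all(isinstance(v, (int, float, str, bool)) for v in values) and all(
            v == values[0] for v in values
        ):
            constants[key] = values[0]
    return constants


def fit_collection(c, b1map=None, **options) -> list:
    """Fit one file collection and package the results with provenance.

    Dispatches on the collection suffix, reads every acquisition parameter
    from resolved sidecars (never from filenames), and returns a list of
    :class:`~qmribids.derivatives.QuantitativeMap` ready to be written.
    ``b1map`` (relative percent) feeds the flip-angle correction of the VFA
    fitter.  Raises :class:`~qmribids.signal_models.ProtocolError` for
    schema-only suffixes.
    """
    from .collections import parameter_table
    from .derivatives import QuantitativeMap

    if c.suffix not in FITTABLE_SUFFIXES:
        raise ProtocolError(f"no fitter is implemented for suffix {c.suffix!r}")
    parameter_table(c)  # raises if linked metadata is missing or inconsistent
    constants = _shared_constants(c)
    root = c.root
    based_on = [
        (str(m.path.relative_to(root)) if root else m.path.name).replace("\\", "/")
        for m in c.members
    ]
    varying: dict[str, list] = {}
    affine = _first_affine(c)

    if c.suffix == "VFA":
        flips = [m.sidecar.get("FlipAngle") for m in c.members]
        tr = c.members[0].sidecar.get("RepetitionTimeExcitation")
        result = fit_vfa(_member_volumes(c), flips, tr, b1map=b1map)
        varying = {"FlipAngle": flips}
    elif c.suffix == "IRT1":
        tis = [m.sidecar.get("InversionTime") for m in c.members]
        tr = c.members[0].sidecar.get("RepetitionTimePreparation")
        result = fit_ir(_member_volumes(c), tis, tr, magnitude=True)
        varying = {"InversionTime": tis}
    elif c.suffix in ("MESE", "MEGRE"):
        tes = [m.sidecar.get("EchoTime") for m in c.members]
        suffix = "T2map" if c.suffix == "MESE" else "T2starmap"
        result = fit_monoexp(_member_volumes(c), tes, suffix)
        varying = {"EchoTime": tes}
    elif c.suffix == "MTR":
        members = {m.name.entities["mt"]: m for m in c.members}
        from .bids_io import load_volume

        result = compute_mtr(
            load_volume(members["off"].path).voxels,
            load_volume(members["on"].path).voxels,
        )
        varying = {"MTState": [False, True]}
    elif c.suffix == "MTS":
        result, varying = _fit_mts_collection(c)
    elif c.suffix == "MP2RAGE":
        result, varying = _fit_mp2rage_collection(c, **options)
    elif c.suffix == "TB1DAM":
        members = sorted(c.members, key=lambda m: m.name.entities["flip"])
        a1 = members[0].sidecar.get("FlipAngle")
        a2 = members[1].sidecar.get("FlipAngle")
        if not np.isclose(a2, 2 * a1):
            raise ProtocolError(
                f"double-angle method needs FlipAngle2 = 2*FlipAngle1, got "
                f"{a1} and {a2}"
            )
        from .bids_io import load_volume

        result = fit_dam(
            load_volume(members[0].path).voxels,
            load_volume(members[1].path).voxels,
            nominal_deg=a1,
        )
        varying = {"FlipAngle": [a1, a2]}
    elif c.suffix == "TB1AFI":
        members = sorted(c.members, key=lambda m: m.name.entities["flip"])
        trs = [m.sidecar.get("RepetitionTimeExcitation") for m in members]
        flip = members[0].sidecar.get("FlipAngle")
        from .bids_io import load_volume

        p = AfiProtocol(tr1=trs[0], tr2=trs[1], flip_deg=flip)
        result = fit_afi(
            load_volume(members[0].path).voxels,
            load_volume(members[1].path).voxels,
            p,
        )
        varying = {"RepetitionTimeExcitation": trs}

    from . import __version__

    software = {
        "Name": "qmribids",
        "Version": __version__,
        "Configuration": {"suffix": c.suffix, **{
            k: (float(v) if isinstance(v, (int, float)) else v)
            for k, v in options.items()
        }},
    }
    maps = []
    for map_suffix, volume in result.maps.items():
        maps.append(
            QuantitativeMap(
                volume=volume,
                map_suffix=map_suffix,
                units=schema.units_for_map(map_suffix),
                based_on=list(based_on),
                varying_meta=dict(varying),
                constant_meta=constants,
                software=software,
                affine=affine,
            )
        )
    return maps


def _first_affine(c) -> np.ndarray:
    from .bids_io import load_volume

    return load_volume(c.members[0].path).affine


def _fit_mts_collection(c):
    on = [m for m in c.members if m.name.entities.get("mt") == "on"]
    off = [m for m in c.members if m.name.entities.get("mt") == "off"]
    if len(on) != 1 or len(off) != 2:
        raise ProtocolError("MTS needs one mt-on and two mt-off members")
    off.sort(key=lambda m: m.sidecar.get("FlipAngle"))
    pdw, t1w = off
    mtw = on[0]
    p = MtsProtocol(
        mtw=_mts_arm(mtw, "on"), pdw=_mts_arm(pdw, "off"), t1w=_mts_arm(t1w, "off")
    )
    from .bids_io import load_volume

    result = compute_mtsat(
        load_volume(mtw.path).voxels,
        load_volume(pdw.path).voxels,
        load_volume(t1w.path).voxels,
        p,
    )
    varying = {
        "FlipAngle": [m.sidecar.get("FlipAngle") for m in (mtw, pdw, t1w)],
        "MTState": [True, False, False],
    }
    return result, varying


def _mts_arm(m, state):
    from .signal_models import MtsArm

    return MtsArm(
        flip_deg=m.sidecar.get("FlipAngle"),
        tr=m.sidecar.get("RepetitionTimeExcitation"),
        mt_state=state,
    )


def _fit_mp2rage_collection(c, t1_range=(0.05, 5.0), t1_step=0.001, inv_eff=0.96):
    from .bids_io import load_volume

    by_key = {
        (m.name.entities["inv"], m.name.entities.get("part", "mag")): m
        for m in c.members
    }
    try:
        mags = [by_key[(i, "mag")] for i in (1, 2)]
        phases = [by_key[(i, "phase")] for i in (1, 2)]
    except KeyError as exc:
        raise ProtocolError(
            "MP2RAGE needs magnitude and phase members for inv-1 and inv-2"
        ) from exc
    side = mags[0].sidecar
    tis = [m.sidecar.get("InversionTime") for m in mags]
    flips = [m.sidecar.get("FlipAngle") for m in mags]
    p = Mp2rageProtocol(
        tr_prep=side.get("RepetitionTimePreparation"),
        tr_exc=side.get("RepetitionTimeExcitation"),
        ti=tuple(tis),
        flips_deg=tuple(flips),
        n_exc=int(side.get("NumberShots")),
        inv_eff=inv_eff,
    )
    signals = []
    for mag_m, phase_m in zip(mags, phases):
        mag = load_volume(mag_m.path).voxels
        phase = load_volume(phase_m.path).voxels
        signals.append(mag * np.exp(1j * phase))
    result = fit_mp2rage(signals[0], signals[1], p, t1_range, t1_step)
    varying = {"InversionTime": tis, "FlipAngle": flips}
    return result, varying
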