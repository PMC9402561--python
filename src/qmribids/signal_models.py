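"""Forward signal models for the supported qMRI file collections.

Pure functions mapping tissue parameters and acquisition protocols to image
intensities.  They serve two roles: the phantom generator evaluates them to
synthesize raw datasets, and the fitters' tests use them as oracles (each
fitter inverts exactly the approximation its forward model assumes, keeping
generator and fitter self-consistent).

All operations accept scalars or arrays elementwise and are homogeneous of
degree 1 in M0 (the ratio models — MP2RAGE UNI and the AFI ratio — are
degree 0).  Angles cross module boundaries in degrees (the sidecar
convention) and are converted to radians internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueParams",
    "SpgrProtocol",
    "Mp2rageProtocol",
    "AfiProtocol",
    "MtsArm",
    "MtsProtocol",
    "ProtocolError",
    "spgr_signal",
    "ir_signal",
    "monoexp_signal",
    "mp2rage_block_signals",
    "mp2rage_uni",
    "dam_signals",
    "afi_ratio",
    "mts_signals",
]


class ProtocolError(ValueError):
    """A protocol record violates its invariants or a model's regime."""


def _rad(deg):
    return np.deg2rad(np.asarray(deg, dtype=float))


@dataclass
class TissueParams:
    """Voxelwise tissue properties; every field may be a scalar or an array.

    T1, T2, T2star are relaxation time constants in seconds (T2* <= T2 <= T1);
    M0 is the equilibrium magnetization amplitude (arbitrary units);
    mtr_frac is the fractional MT-induced signal drop in [0, 1);
    mtsat_delta is the per-excitation saturation of the bound pool
    (dimensionless, the quantity MTsat estimates);
    chi is magnetic susceptibility in ppm (carried as ground truth only);
    b1_rel is the actual/nominal flip-angle ratio (1 = nominal).
    """

    T1: float | np.ndarray = 1.0
    T2: float | np.ndarray = 0.08
    T2star: float | np.ndarray = 0.05
    M0: float | np.ndarray = 1000.0
    mtr_frac: float | np.ndarray = 0.3
    mtsat_delta: float | np.ndarray = 0.04
    chi: float | np.ndarray = 0.0
    b1_rel: float | np.ndarray = 1.0

    def validate(self) -> None:
        if not np.all(np.asarray(self.T1) > 0):
            raise ValueError("T1 must be positive")
        if not np.all(np.asarray(self.T2) > 0) or not np.all(
            np.asarray(self.T2) <= np.asarray(self.T1)
        ):
            raise ValueError("T2 must satisfy 0 < T2 <= T1")
        if not np.all(np.asarray(self.T2star) > 0) or not np.all(
            np.asarray(self.T2star) <= np.asarray(self.T2)
        ):
            raise ValueError("T2* must satisfy 0 < T2* <= T2")
        if not np.all(np.asarray(self.M0) >= 0):
            raise ValueError("M0 must be non-negative")
        mf = np.asarray(self.mtr_frac)
        if not np.all((mf >= 0) & (mf < 1)):
            raise ValueError("mtr_frac must lie in [0, 1)")


@dataclass
class SpgrProtocol:
    """Spoiled gradient echo: excitation repetition time (s) and flip (deg)."""

    tr: float
    flip_deg: float
    te: float | None = None

    def __post_init__(self):
        if self.tr <= 0:
            raise ProtocolError("tr must be positive")
        if not 0 < self.flip_deg < 180:
            raise ProtocolError("flip_deg must lie in (0, 180)")


@dataclass
class Mp2rageProtocol:
    """Magnetization-prepared two rapid gradient echoes.

    One cycle of duration ``tr_prep`` (RepetitionTimePreparation) contains an
    adiabatic inversion followed by two GRE blocks of ``n_exc`` excitations
    each (spacing ``tr_exc``, flips ``flips_deg``), centered at the two
    inversion times ``ti``.
    """

    tr_prep: float
    tr_exc: float
    ti: tuple[float, float]
    flips_deg: tuple[float, float]
    n_exc: int
    inv_eff: float = 0.96

    def __post_init__(self):
        ti1, ti2 = self.ti
        if not 0 < ti1 < ti2 < self.tr_prep:
            raise ProtocolError("inversion times must satisfy 0 < TI1 < TI2 < TRprep")
        if not 0 < self.inv_eff <= 1:
            raise ProtocolError("inversion efficiency must lie in (0, 1]")
        if self.n_exc < 1 or self.tr_exc <= 0:
            raise ProtocolError("GRE block needs n_exc >= 1 and tr_exc > 0")
        half = self.n_exc * self.tr_exc / 2.0
        if ti1 - half < -1e-12 or ti2 - ti1 - 2 * half < -1e-12 or (
            self.tr_prep - ti2 - half
        ) < -1e-12:
            raise ProtocolError("GRE blocks do not fit within the cycle timing")


@dataclass
class AfiProtocol:
    """Actual flip angle imaging: interleaved dual repetition times (s)."""

    tr1: float
    tr2: float
    flip_deg: float

    def __post_init__(self):
        if not 0 < self.tr1 < self.tr2:
            raise ProtocolError("AFI requires 0 < tr1 < tr2")

    @property
    def n(self) -> float:
        return self.tr2 / self.tr1


@dataclass
class MtsArm:
    flip_deg: float
    tr: float
    mt_state: str  # "on" | "off"


@dataclass
class MtsProtocol:
    """The MT-weighted / PD-weighted / T1-weighted triple of SPGR arms."""

    mtw: MtsArm
    pdw: MtsArm
    t1w: MtsArm

    def __post_init__(self):
        if self.mtw.mt_state != "on" or "on" in (self.pdw.mt_state, self.t1w.mt_state):
            raise ProtocolError("MTw arm must be mt-on; PDw/T1w arms mt-off")
        if self.t1w.flip_deg <= self.pdw.flip_deg:
            raise ProtocolError("T1w arm must use a larger flip angle than PDw")


# ---------------------------------------------------------------------------
# closed-form models


def spgr_signal(t: TissueParams, p: SpgrProtocol):
    """Steady-state spoiled gradient echo (Ernst equation).

    S = M0 sin(b1*a) (1 - E1) / (1 - E1 cos(b1*a)), E1 = exp(-TR/T1); a TE
    adds a T2* decay factor.
    """
    a = _rad(p.flip_deg) * np.asarray(t.b1_rel, dtype=float)
    e1 = np.exp(-p.tr / np.asarray(t.T1, dtype=float))
    s = np.asarray(t.M0, dtype=float) * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
    if p.te is not None:
        s = s * np.exp(-p.te / np.asarray(t.T2star, dtype=float))
    return s


def ir_signal(t: TissueParams, ti, tr):
    """Signed inversion-recovery signal: M0 (1 - 2 e^{-TI/T1} + e^{-TR/T1})."""
    ti = np.asarray(ti, dtype=float)
    t1 = np.asarray(t.T1, dtype=float)
    return np.asarray(t.M0, dtype=float) * (
        1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-np.asarray(tr, float) / t1)
    )


def monoexp_signal(m0, tc, te):
    """Monoexponential decay S = m0 e^{-TE/tc} (tc = T2 for spin echo,
    T2* for gradient echo)."""
    return np.asarray(m0, dtype=float) * np.exp(
        -np.asarray(te, dtype=float) / np.asarray(tc, dtype=float)
    )


# ---------------------------------------------------------------------------
# MP2RAGE

def _compose(stages):
    """Compose affine maps mz -> a*mz + b, first stage applied first."""
    a_tot, b_tot = 1.0, 0.0
    for a, b in stages:
        a_tot = a * a_tot
        b_tot = a * b_tot + b
    return a_tot, b_tot


def _mp2rage_stages(t: TissueParams, p: Mp2rageProtocol):
    """The per-cycle stage list, with markers for the two block centers.

    Longitudinal magnetization is normalized to M0; every stage is affine,
    mz' = a*mz + b.  Yields tuples (a, b, tag) where tag marks the reading
    point ("c1"/"c2") immediately before the central excitation of a block.
    """
    t1 = np.asarray(t.T1, dtype=float)
    b1 = np.asarray(t.b1_rel, dtype=float)
    cos1 = np.cos(_rad(p.flips_deg[0]) * b1)
    cos2 = np.cos(_rad(p.flips_deg[1]) * b1)
    e_exc = np.exp(-p.tr_exc / t1)

    def relax(dt):
        e = np.exp(-max(dt, 0.0) / t1)
        return (e, 1.0 - e)

    half = p.n_exc * p.tr_exc / 2.0
    ta = p.ti[0] - half
    tb = p.ti[1] - p.ti[0] - 2 * half
    tc = p.tr_prep - p.ti[1] - half
    center = p.n_exc // 2

    stages = [(-p.inv_eff, 0.0, None), (*relax(ta), None)]
    for cosa, tag in ((cos1, "c1"), (cos2, "c2")):
        for k in range(p.n_exc):
            if k == center:
                stages.append((1.0, 0.0, tag))
            stages.append((cosa, 0.0, None))
            stages.append((e_exc, 1.0 - e_exc, None))
        if tag == "c1":
            stages.append((*relax(tb), None))
    stages.append((*relax(tc), None))
    return stages


def mp2rage_block_signals(t: TissueParams, p: Mp2rageProtocol):
    """Steady-state complex GRE signals of the two MP2RAGE blocks.

    The cycle (inversion, recovery, block 1, recovery, block 2, recovery) is
    affine in mz, so the steady state is the exact fixed point of the
    composed map, mz* = B / (1 - A).  Each returned signal is
    M0 sin(b1*flip_i) * mz at the central excitation of block i, with the
    inversion sign carried in the (real) phase.
    """
    stages = _mp2rage_stages(t, p)
    a_tot, b_tot = _compose([(a, b) for a, b, _ in stages])
    denom = 1.0 - a_tot
    if np.any(np.abs(denom) < 1e-12):
        raise ProtocolError("non-convergent protocol: cycle map has no fixed point")
    mz = b_tot / denom

    b1 = np.asarray(t.b1_rel, dtype=float)
    m0 = np.asarray(t.M0, dtype=float)
    out = {}
    for a, b, tag in stages:
        if tag is not None:
            out[tag] = mz
        mz = a * mz + b
    s1 = m0 * np.sin(_rad(p.flips_deg[0]) * b1) * out["c1"]
    s2 = m0 * np.sin(_rad(p.flips_deg[1]) * b1) * out["c2"]
    return s1.astype(complex), s2.astype(complex)


def mp2rage_uni(s1, s2):
    """The bias-free MP2RAGE combination Re(S1 conj(S2)) / (|S1|^2 + |S2|^2).

    Bounded in [-0.5, 0.5]; invariant to any common complex scaling of the
    inputs (receive field, M0).  Voxels with S1 = S2 = 0 are undefined and
    propagate as NaN.
    """
    s1 = np.asarray(s1, dtype=complex)
    s2 = np.asarray(s2, dtype=complex)
    denom = np.abs(s1) ** 2 + np.abs(s2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, np.real(s1 * np.conj(s2)) / denom, np.nan)


# ---------------------------------------------------------------------------
# B1+ mapping and MT

def dam_signals(t: TissueParams, nominal_deg):
    """Double-angle method pair under the long-TR (no T1 weighting) regime:
    S1 = M0 sin(b1*a), S2 = M0 sin(2 b1*a)."""
    a = _rad(nominal_deg) * np.asarray(t.b1_rel, dtype=float)
    m0 = np.asarray(t.M0, dtype=float)
    return m0 * np.sin(a), m0 * np.sin(2 * a)


def afi_ratio(t: TissueParams, p: AfiProtocol):
    """AFI steady-state ratio S2/S1 = (1 + n cos(b1*a)) / (n + cos(b1*a)).

    Valid in the short-TR regime tr1, tr2 << T1 (ideal spoiling assumed); a
    warning is raised when the protocol leaves it.
    """
    if np.any(p.tr2 > 0.2 * np.asarray(t.T1, dtype=float)):
        warnings.warn(
            "AFI short-TR approximation violated (tr2 > 0.2*T1)", stacklevel=2
        )
    cosa = np.cos(_rad(p.flip_deg) * np.asarray(t.b1_rel, dtype=float))
    return (1.0 + p.n * cosa) / (p.n + cosa)


def mts_signals(t: TissueParams, p: MtsProtocol):
    """Rational small-angle SPGR signals of the three MTS arms.

    For an mt-off arm, S = A a (R1 TR) / (a^2/2 + R1 TR) with A the apparent
    amplitude (M0) and a the effective flip in radians; the MT pulse of the
    mt-on arm adds its per-cycle saturation delta to the denominator.
    Returns (S_MTw, S_PDw, S_T1w).
    """
    r1 = 1.0 / np.asarray(t.T1, dtype=float)
    amp = np.asarray(t.M0, dtype=float)
    b1 = np.asarray(t.b1_rel, dtype=float)
    delta = np.asarray(t.mtsat_delta, dtype=float)

    def arm(a: MtsArm, sat):
        al = _rad(a.flip_deg) * b1
        return amp * al * (r1 * a.tr) / (al**2 / 2.0 + sat + r1 * a.tr)

    return arm(p.mtw, delta), arm(p.pdw, 0.0), arm(p.t1w, 0.0)
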