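"""Histogram entropy and mutual-information estimators.

Spatial entropies are plug-in estimates of ``-∫ p ln(p/J) dq`` in units
of the gas constant R (nats), where J is the per-DOF reference measure of
the BAT Jacobian: ``b^2`` for bond-type DOFs, ``sin(theta)`` for
angle-type DOFs and 1 for torsions.  Mutual information is formed as
``S_i + S_j - S_ij`` on one shared 2D binning, so the Jacobian factors
cancel identically and the plug-in value is nonnegative up to rounding.

The analytic momentum term (Gaussian momentum integral) and the external
rigid-body reference term ``ln(8 pi^2 V°)`` live here as well; both are
constants for fixed composition/temperature and cancel in binding
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

from .topology import BATTrajectory

__all__ = [
    "HistogramSpec",
    "EntropyValue",
    "MIMatrix",
    "entropy_1d",
    "entropy_2d",
    "mutual_information",
    "pairwise_mi_matrix",
    "momentum_entropy",
    "external_reference_entropy",
    "R_GAS",
]

R_GAS = 8.314462618  # J mol^-1 K^-1

_BOND_KINDS = ("bond", "ext_bond")
_ANGLE_KINDS = ("angle", "ext_angle")
_TORSION_KINDS = ("torsion", "ext_torsion")


@dataclass(frozen=True)
class HistogramSpec:
    """Binning policy for the plug-in estimators.

    The 50/50 defaults follow common practice for protein-scale BAT
    ensembles; periodic and angular DOFs use fixed ranges, bond-type DOFs
    are binned over their observed support plus a small guard.
    ``miller_madow`` enables the (k_occupied - 1)/(2n) bias correction;
    off by default (plain plug-in).
    """

    bins_1d: int = 50
    bins_2d: int = 50
    bond_range_guard: float = 1e-9
    miller_madow: bool = False

    def __post_init__(self) -> None:
        if self.bins_1d < 2 or self.bins_2d < 2:
            raise ValueError("bin counts must be >= 2")


@dataclass(frozen=True)
class EntropyValue:
    """An entropy in units of R with its provenance kind."""

    value: float
    kind: str

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class MIMatrix:
    """Symmetric nonnegative pairwise MI matrix (units of R)."""

    values: np.ndarray
    dofs: tuple = ()
    clamped_total: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("MI matrix must be square")

    @property
    def n_dofs(self) -> int:
        return self.values.shape[0]


def default_range(kind: str, samples: np.ndarray | None = None,
                  guard: float = 1e-9) -> tuple[float, float]:
    """Range policy per DOF kind (fixed for periodic/angular, data-driven
    for bond-type DOFs)."""
    if kind in _TORSION_KINDS:
        return (-np.pi, np.pi)
    if kind in _ANGLE_KINDS:
        return (0.0, np.pi)
    if kind in _BOND_KINDS:
        if samples is None:
            raise ValueError("bond-type DOFs need samples to determine a range")
        lo, hi = float(np.min(samples)), float(np.max(samples))
        if hi - lo < guard:
            hi = lo + guard
        return (lo - guard, hi + guard)
    raise ValueError(f"unknown DOF kind {kind!r}")


def _digitize(x: np.ndarray, lo: float, hi: float, k: int) -> np.ndarray:
    """Uniform binning shared by every estimator (one code path, so 1D
    marginals, 2D joints and the MI matrix are mutually consistent)."""
    idx = np.floor((np.asarray(x, float) - lo) * (k / (hi - lo))).astype(np.int64)
    return np.clip(idx, 0, k - 1)


def _ln_jacobian(kind: str, midpoints: np.ndarray) -> np.ndarray:
    if kind in _BOND_KINDS:
        return 2.0 * np.log(midpoints)
    if kind in _ANGLE_KINDS:
        return np.log(np.sin(midpoints))
    return np.zeros_like(midpoints)


def entropy_1d(samples, kind: str, spec: HistogramSpec | None = None,
               value_range: tuple[float, float] | None = None,
               use_jacobian: bool = True) -> EntropyValue:
    """Plug-in 1D spatial entropy of one DOF, in units of R.

    ``value_range`` overrides the default range policy (used e.g. to put
    bound and unbound bond histograms on a common discretization).
    """
    spec = spec or HistogramSpec()
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = value_range if value_range is not None else default_range(
        kind, x, spec.bond_range_guard)
    k = spec.bins_1d
    counts = np.bincount(_digitize(x, lo, hi, k), minlength=k)
    n = counts.sum()
    width = (hi - lo) / k
    mids = lo + (np.arange(k) + 0.5) * width
    p = counts / n
    nz = p > 0
    if nz.sum() == 1:
        warnings.warn(
            "all samples fall in a single bin; returning the pure-Jacobian "
            "value (degenerate distribution)", stacklevel=2)
    lnj = _ln_jacobian(kind, mids) if use_jacobian else np.zeros(k)
    s = float(-np.sum(p[nz] * (np.log(p[nz] / width) - lnj[nz])))
    if spec.miller_madow:
        s += (nz.sum() - 1) / (2.0 * n)
    return EntropyValue(s, "spatial_1d")


def entropy_2d(samples_i, samples_j, kinds, spec: HistogramSpec | None = None,
               ranges=None, use_jacobian: bool = True) -> EntropyValue:
    """Plug-in 2D spatial entropy of a DOF pair with product reference
    measure J_i * J_j, in units of R."""
    spec = spec or HistogramSpec()
    xi = np.asarray(samples_i, float)
    xj = np.asarray(samples_j, float)
    if xi.shape != xj.shape or xi.size < 2:
        raise ValueError("need two equal-length sample vectors (n >= 2)")
    ki, kj = kinds
    if ranges is None:
        ranges = (None, None)
    ri = ranges[0] if ranges[0] is not None else default_range(ki, xi, spec.bond_range_guard)
    rj = ranges[1] if ranges[1] is not None else default_range(kj, xj, spec.bond_range_guard)
    k = spec.bins_2d
    ii = _digitize(xi, *ri, k)
    jj = _digitize(xj, *rj, k)
    counts = np.bincount(ii * k + jj, minlength=k * k).reshape(k, k)
    n = counts.sum()
    wi = (ri[1] - ri[0]) / k
    wj = (rj[1] - rj[0]) / k
    p = counts / n
    nz = p > 0
    if use_jacobian:
        mi_ = ri[0] + (np.arange(k) + 0.5) * wi
        mj_ = rj[0] + (np.arange(k) + 0.5) * wj
        lnj = _ln_jacobian(ki, mi_)[:, None] + _ln_jacobian(kj, mj_)[None, :]
    else:
        lnj = np.zeros((k, k))
    s = float(-np.sum(p[nz] * (np.log(p[nz] / (wi * wj)) - lnj[nz])))
    if spec.miller_madow:
        s += (nz.sum() - 1) / (2.0 * n)
    # degenerate-support warning: near-perfect correlation collapses the
    # joint onto ~1D support
    occ_rows = (counts.sum(axis=1) > 0).sum()
    occ = nz.sum()
    if occ <= 2 * max(occ_rows, 1) and occ_rows >= 5:
        warnings.warn("2D sample support is nearly one-dimensional "
                      "(high correlation)", stacklevel=2)
    return EntropyValue(s, "spatial_2d")


def _mi_from_counts(counts: np.ndarray) -> float:
    """Discrete plug-in MI of a contingency table (always >= 0)."""
    n = counts.sum()
    p = counts / n
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    nz = p > 0
    outer = pi[:, None] * pj[None, :]
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def mutual_information(samples_i, samples_j, kinds,
                       spec: HistogramSpec | None = None, ranges=None,
                       use_jacobian: bool = True,
                       return_parts: bool = False):
    """Pairwise MI as S_i + S_j - S_ij on one shared binning (units of R).

    Marginal entropies reuse the 2D table's own margins, so the Jacobian
    reference measures cancel exactly and the estimate is nonnegative up
    to floating-point rounding; any negative residual is clamped to 0.
    """
    spec = spec or HistogramSpec()
    xi = np.asarray(samples_i, float)
    xj = np.asarray(samples_j, float)
    if xi.shape != xj.shape or xi.size < 2:
        raise ValueError("need two equal-length sample vectors (n >= 2)")
    ki, kj = kinds
    if ranges is None:
        ranges = (None, None)
    ri = ranges[0] if ranges[0] is not None else default_range(ki, xi, spec.bond_range_guard)
    rj = ranges[1] if ranges[1] is not None else default_range(kj, xj, spec.bond_range_guard)
    k = spec.bins_2d
    counts = np.bincount(
        _digitize(xi, *ri, k) * k + _digitize(xj, *rj, k), minlength=k * k
    ).reshape(k, k)
    n = counts.sum()
    wi = (ri[1] - ri[0]) / k
    wj = (rj[1] - rj[0]) / k
    p = counts / n
    pi_ = p.sum(axis=1)
    pj_ = p.sum(axis=0)
    if use_jacobian:
        lji = _ln_jacobian(ki, ri[0] + (np.arange(k) + 0.5) * wi)
        ljj = _ln_jacobian(kj, rj[0] + (np.arange(k) + 0.5) * wj)
    else:
        lji = ljj = np.zeros(k)
    nzi, nzj, nz = pi_ > 0, pj_ > 0, p > 0
    s_i = -np.sum(pi_[nzi] * (np.log(pi_[nzi] / wi) - lji[nzi]))
    s_j = -np.sum(pj_[nzj] * (np.log(pj_[nzj] / wj) - ljj[nzj]))
    lnj2 = lji[:, None] + ljj[None, :]
    s_ij = -np.sum(p[nz] * (np.log(p[nz] / (wi * wj)) - lnj2[nz]))
    mi = float(s_i + s_j - s_ij)
    clamped = 0.0
    if mi < 0.0:
        clamped = -mi
        mi = 0.0
    if return_parts:
        return mi, clamped
    return mi


def pairwise_mi_matrix(traj: BATTrajectory, spec: HistogramSpec | None = None,
                       ranges: dict[int, tuple[float, float]] | None = None
                       ) -> MIMatrix:
    """Full symmetric pairwise MI matrix over the trajectory's DOFs.

    Each DOF is digitized once with ``bins_2d`` bins; every pair's joint
    table is then a single bincount, which keeps the d(d-1)/2 sweep
    affordable for protein-scale DOF counts.  Degenerate (single-bin)
    DOFs are computed with a warning rather than dropped.
    """
    spec = spec or HistogramSpec()
    d = traj.n_dofs
    if d < 2:
        raise ValueError("need at least 2 DOFs for a pairwise MI matrix")
    k = spec.bins_2d
    ranges = ranges or {}
    codes = np.empty((d, traj.frame_count), dtype=np.int64)
    for i, dof in enumerate(traj.dofs):
        x = traj.values[:, i]
        r = ranges.get(i) or default_range(dof.kind, x, spec.bond_range_guard)
        codes[i] = _digitize(x, *r, k)
        if np.unique(codes[i]).size == 1:
            warnings.warn(f"DOF {i} ({dof.kind}) is degenerate: all samples "
                          "in one bin; its MI row is 0", stacklevel=2)
    out = np.zeros((d, d))
    clamped_total = 0.0
    for i in range(d):
        base = codes[i] * k
        for j in range(i + 1, d):
            counts = np.bincount(base + codes[j], minlength=k * k).reshape(k, k)
            mi = _mi_from_counts(counts)
            if spec.miller_madow:
                ri = (counts.sum(axis=1) > 0).sum()
                rj = (counts.sum(axis=0) > 0).sum()
                rij = (counts > 0).sum()
                mi += (ri - 1) / (2.0 * counts.sum()) + (rj - 1) / (
                    2.0 * counts.sum()) - (rij - 1) / (2.0 * counts.sum())
            if mi < 0.0:
                clamped_total += -mi
                mi = 0.0
            out[i, j] = out[j, i] = mi
    return MIMatrix(out, traj.dofs, clamped_total)


def momentum_entropy(atoms, temperature: float) -> EntropyValue:
    """Closed-form Gaussian momentum integral in units of R.

    ``S_m/R = sum_i (3/2) [1 + ln(2 pi m_i k_B T / h^2)]`` with masses in
    u converted to kg.  Constant for fixed composition and temperature;
    carries no physical dimension on its own and cancels exactly in
    binding entropy differences.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    masses = np.asarray(atoms.masses, dtype=float) * _const.atomic_mass
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    arg = 2.0 * np.pi * masses * _const.k * temperature / _const.h**2
    s = float(np.sum(1.5 * (1.0 + np.log(arg))))
    return EntropyValue(s, "momentum")


def external_reference_entropy(standard_concentration: float = 1.0,
                               volume_nm3: float | None = None) -> EntropyValue:
    """Rigid-body reference term ``ln(8 pi^2 V°)`` in units of R.

    ``V°`` is the volume per molecule, in nm^3, at the given standard
    concentration (mol/L, default 1).  Pass ``volume_nm3`` to specify the
    per-molecule reference volume directly instead.
    """
    if volume_nm3 is None:
        if standard_concentration <= 0:
            raise ValueError("standard concentration must be positive")
        # C° mol/L -> molecules per nm^3; V° is its reciprocal
        volume_nm3 = 1e24 / (standard_concentration * _const.N_A)
    elif volume_nm3 <= 0:
        raise ValueError("reference volume must be positive")
    return EntropyValue(float(np.log(8.0 * np.pi**2 * volume_nm3)),
                        "external_reference")
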