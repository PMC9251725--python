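"""Synthetic BAT ensembles with closed-form entropy/MI references.

Every generator here ships the analytic value of whatever an estimator
should recover from its output: Gaussian ensembles carry exact marginal
and joint differential entropies (with the BAT Jacobian reference terms
evaluated by Gauss-Hermite quadrature), coupled pairs carry the Gaussian
MI ``-1/2 ln(1 - rho^2)``, and the toy binding generator returns every
term of the binding decomposition in closed form.

Angular variables are kept far from their range boundaries by
construction (boundary mass < 1e-6) so that the closed forms remain
exact; wrap-around is rejected, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .estimators import external_reference_entropy
from .topology import BATTrajectory, DOFDescriptor

__all__ = [
    "SyntheticSpec",
    "SyntheticReference",
    "sample_gaussian_bat",
    "closed_form_entropy",
    "toy_binding_generator",
    "two_regime_trajectory",
    "gaussian_entropy_1d",
    "mixture_entropy_1d",
]

_ANGULAR_RANGES = {"torsion": (-np.pi, np.pi), "ext_torsion": (-np.pi, np.pi),
                   "angle": (0.0, np.pi), "ext_angle": (0.0, np.pi)}
_WRAP_TOL = 1e-6

# free rigid-body reference on the pseudobond coordinates, radius R:
# radius ~ b^2 on [0, R], angles ~ sin(theta), torsions uniform; the
# product of the per-DOF entropies is then exactly ln(8 pi^2 * 4/3 pi R^3)
_FREE_SD = {
    "ext_bond": np.sqrt(3.0 / 5.0 - 9.0 / 16.0),     # x R
    "ext_angle": np.sqrt(np.pi**2 / 4.0 - 2.0),
    "ext_torsion": np.pi / np.sqrt(3.0),
}

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def expected_ln_jacobian(kind: str, mu: float, sigma: float) -> float:
    """E[ln J(X)] for X ~ N(mu, sigma^2) by Gauss-Hermite quadrature."""
    if kind in ("torsion", "ext_torsion"):
        return 0.0
    x = mu + np.sqrt(2.0) * sigma * _GH_NODES
    if kind in ("bond", "ext_bond"):
        valid = x > 0
        f = lambda v: 2.0 * np.log(v)  # noqa: E731
    elif kind in ("angle", "ext_angle"):
        valid = (x > 0) & (x < np.pi)
        f = lambda v: np.log(np.sin(v))  # noqa: E731
    else:
        raise ValueError(f"unknown DOF kind {kind!r}")
    # far-tail quadrature nodes may fall outside the domain with
    # exponentially negligible weight; real out-of-domain mass is an error
    dropped = _GH_WEIGHTS[~valid].sum() / np.sqrt(np.pi)
    if dropped > 1e-9:
        raise ValueError(
            f"{kind} distribution (mu={mu:.3f}, sigma={sigma:.3f}) has "
            f"{dropped:.2e} probability mass outside its domain")
    return float(np.sum(_GH_WEIGHTS[valid] * f(x[valid])) / np.sqrt(np.pi))


def gaussian_entropy_1d(kind: str, mu: float, sigma: float) -> float:
    """Closed-form 1D entropy -E[ln(p/J)] of a Gaussian DOF, units of R."""
    return 0.5 * np.log(2.0 * np.pi * np.e * sigma**2) + expected_ln_jacobian(
        kind, mu, sigma)


def _check_wraparound(kinds, means, sds) -> None:
    for kind, mu, sd in zip(kinds, means, sds):
        rng_ = _ANGULAR_RANGES.get(kind)
        if rng_ is None:
            continue
        lo, hi = rng_
        mass = stats.norm.cdf(lo, mu, sd) + stats.norm.sf(hi, mu, sd)
        if mass > _WRAP_TOL:
            raise ValueError(
                f"{kind} with mean {mu:.3f}, sd {sd:.3f} puts {mass:.2e} "
                f"probability mass outside [{lo:.3f}, {hi:.3f}]")


@dataclass
class SyntheticSpec:
    """Generative description of a Gaussian BAT ensemble."""

    dof_kinds: tuple[str, ...]
    means: np.ndarray
    covariance: np.ndarray
    n_frames: int
    seed: int = 0
    subsystems: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        d = len(self.dof_kinds)
        if self.means.shape != (d,) or self.covariance.shape != (d, d):
            raise ValueError("means/covariance shape mismatch with dof_kinds")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        try:
            self._chol = np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
        _check_wraparound(self.dof_kinds, self.means,
                          np.sqrt(np.diag(self.covariance)))
        if self.subsystems is None:
            self.subsystems = tuple(
                "Y" if k.startswith("ext_") else "A" for k in self.dof_kinds)

    @property
    def n_dofs(self) -> int:
        return len(self.dof_kinds)

    def descriptors(self) -> tuple[DOFDescriptor, ...]:
        return tuple(DOFDescriptor(k, (), s)
                     for k, s in zip(self.dof_kinds, self.subsystems))


@dataclass
class SyntheticReference:
    """Closed-form values an estimator should recover from a spec."""

    marginal_entropies: np.ndarray
    joint_entropy: float
    mi_matrix: np.ndarray


def sample_gaussian_bat(spec: SyntheticSpec,
                        rng: np.random.Generator | None = None) -> BATTrajectory:
    """Draw ``n_frames`` multivariate-normal BAT frames, reproducibly."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, spec.n_dofs))
    values = spec.means + z @ spec._chol.T
    bond_cols = [i for i, k in enumerate(spec.dof_kinds)
                 if k in ("bond", "ext_bond")]
    if bond_cols and np.any(values[:, bond_cols] <= 0):
        raise ValueError("sampled non-positive bond length; increase the "
                         "bond mean or decrease its variance")
    return BATTrajectory(values, spec.descriptors())


def closed_form_entropy(spec: SyntheticSpec) -> SyntheticReference:
    """Exact marginal/joint entropies and pairwise MIs of a Gaussian spec.

    Entropies include the Jacobian reference corrections E[ln J] used by
    the histogram estimators; pairwise MI is Jacobian-free by
    construction.
    """
    sds = np.sqrt(np.diag(spec.covariance))
    lnj = np.array([expected_ln_jacobian(k, m, s)
                    for k, m, s in zip(spec.dof_kinds, spec.means, sds)])
    marg = 0.5 * np.log(2.0 * np.pi * np.e * sds**2) + lnj
    sign, logdet = np.linalg.slogdet(spec.covariance)
    if sign <= 0:
        raise ValueError("covariance must be positive definite")
    d = spec.n_dofs
    joint = 0.5 * (d * np.log(2.0 * np.pi * np.e) + logdet) + lnj.sum()
    corr = spec.covariance / np.outer(sds, sds)
    off = np.clip(corr - np.eye(d), -0.999999999, 0.999999999)
    mi = -0.5 * np.log1p(-off**2)
    np.fill_diagonal(mi, 0.0)
    return SyntheticReference(marg, float(joint), mi)


def _chain_kinds(n_atoms: int) -> list[str]:
    """Internal DOF kinds of an n-atom chain, in BAT-tree order."""
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms per molecule")
    kinds = ["bond", "bond", "angle"]
    for _ in range(n_atoms - 3):
        kinds += ["bond", "angle", "torsion"]
    return kinds


_Y_KINDS = ("ext_bond", "ext_angle", "ext_torsion",
            "ext_angle", "ext_torsion", "ext_torsion")

_DEFAULT_MARGINALS = {
    # mean, sd per internal DOF kind: bond lengths ~0.15 nm, tetrahedral
    # angles, torsions wide enough that 50-bin histograms resolve them
    "bond": (0.15, 0.005),
    "angle": (1.9111, 0.15),
    "torsion": (0.0, 0.5),
}


def _free_y_sample(rng: np.random.Generator, n: int, r_max: float) -> np.ndarray:
    """Sample the 6 pseudobond DOFs from the Jacobian-weighted free state."""
    out = np.empty((n, 6))
    out[:, 0] = r_max * rng.random(n) ** (1.0 / 3.0)          # ~ b^2
    out[:, 1] = np.arccos(1.0 - 2.0 * rng.random(n))          # ~ sin(theta)
    out[:, 3] = np.arccos(1.0 - 2.0 * rng.random(n))
    for c in (2, 4, 5):
        out[:, c] = rng.uniform(-np.pi, np.pi, n)
    return out


def _free_y_entropy(r_max: float) -> float:
    """Sum of per-DOF free-state entropies; equals ln(8 pi^2 V_sphere)."""
    return (np.log(r_max**3 / 3.0) + 2.0 * np.log(2.0)
            + 3.0 * np.log(2.0 * np.pi))


def toy_binding_generator(n_atoms_a: int = 5, n_atoms_b: int = 4,
                          couplings=(), y_narrow_factor: float | None = 10.0,
                          n_frames: int = 100_000, seed: int = 0,
                          scale_a: float = 1.0, scale_b: float = 1.0,
                          r_max: float = 1.0):
    """Paired bound/unbound chain-molecule ensembles with known terms.

    The unbound ensembles are separable by construction (independent
    Gaussian DOFs); the bound ensemble imposes the requested pairwise
    Gaussian ``couplings`` — a list of ``(category, rho)`` with category
    in {"AA", "BB", "YY", "AB", "AY", "BY"} — on torsion-type DOF pairs
    (each DOF used at most once, so the coupling graph is a forest and
    all decomposition terms are sums of closed-form pair MIs).

    ``y_narrow_factor`` divides the free-state standard deviation of each
    pseudobond DOF to model rototranslational restriction upon binding;
    ``None`` samples Y from the free reference instead (null binding:
    every decomposition term is exactly 0 in closed form, provided no Y
    couplings are requested).  ``scale_a``/``scale_b`` shrink the bound
    internal marginal widths of the respective molecule.

    Returns ``(bound, unbound_a, unbound_b, reference)`` where
    ``reference`` is a dict holding every closed-form decomposition term,
    the matched per-molecule reference volume (nm^3) and the coupled pair
    indices.
    """
    couplings = list(couplings)
    if y_narrow_factor is None and couplings:
        raise ValueError("null binding (y_narrow_factor=None) is the "
                         "uncoupled reference; couplings are not supported")

    kinds_a = _chain_kinds(n_atoms_a)
    kinds_b = _chain_kinds(n_atoms_b)
    d_a, d_b = len(kinds_a), len(kinds_b)
    kinds_bound = kinds_a + kinds_b + list(_Y_KINDS)
    labels_bound = ["A"] * d_a + ["B"] * d_b + ["Y"] * 6

    mean = np.empty(d_a + d_b + 6)
    sd_unbound = np.empty(d_a + d_b + 6)
    for i, k in enumerate(kinds_bound):
        if k in _DEFAULT_MARGINALS:
            mean[i], sd_unbound[i] = _DEFAULT_MARGINALS[k]
        else:  # Y block: center of the free ranges
            mean[i] = {"ext_bond": r_max / 2.0, "ext_angle": np.pi / 2.0,
                       "ext_torsion": 0.0}[k]
            sd_unbound[i] = _FREE_SD[k] * (r_max if k == "ext_bond" else 1.0)
    sd_bound = sd_unbound.copy()
    sd_bound[:d_a] *= scale_a
    sd_bound[d_a:d_a + d_b] *= scale_b
    if y_narrow_factor is not None:
        sd_bound[d_a + d_b:] /= float(y_narrow_factor)

    # deterministic coupling-pair assignment: torsion-type DOFs per block
    pools = {
        "A": [i for i in range(d_a) if kinds_bound[i] == "torsion"],
        "B": [d_a + i for i in range(d_b) if kinds_bound[d_a + i] == "torsion"],
        "Y": [d_a + d_b + i for i in range(6)
              if kinds_bound[d_a + d_b + i] == "ext_torsion"],
    }
    pairs: list[tuple[int, int, float, str]] = []
    for cat, rho in couplings:
        if sorted(cat) not in (["A", "A"], ["B", "B"], ["Y", "Y"],
                               ["A", "B"], ["A", "Y"], ["B", "Y"]):
            raise ValueError(f"unknown coupling category {cat!r}")
        if not -1.0 < rho < 1.0:
            raise ValueError("coupling rho must be in (-1, 1)")
        s1, s2 = cat[0], cat[1]
        try:
            i = pools[s1].pop(0)
            j = pools[s2].pop(0)
        except IndexError:
            raise ValueError(
                f"not enough free torsion DOFs for coupling {cat!r}; "
                "increase the molecule sizes") from None
        pairs.append((i, j, float(rho), "".join(sorted(cat))))

    cov_bound = np.diag(sd_bound**2)
    for i, j, rho, _ in pairs:
        cov_bound[i, j] = cov_bound[j, i] = rho * sd_bound[i] * sd_bound[j]

    ss = np.random.SeedSequence(seed)
    rng_a, rng_b, rng_c = (np.random.default_rng(c) for c in ss.spawn(3))

    spec_a = SyntheticSpec(tuple(kinds_a), mean[:d_a],
                           np.diag(sd_unbound[:d_a]**2), n_frames, seed,
                           subsystems=("A",) * d_a)
    spec_b = SyntheticSpec(tuple(kinds_b), mean[d_a:d_a + d_b],
                           np.diag(sd_unbound[d_a:d_a + d_b]**2), n_frames,
                           seed, subsystems=("B",) * d_b)
    unbound_a = sample_gaussian_bat(spec_a, rng_a)
    unbound_b = sample_gaussian_bat(spec_b, rng_b)

    descr = tuple(DOFDescriptor(k, (), s)
                  for k, s in zip(kinds_bound, labels_bound))
    if y_narrow_factor is None:
        vals = np.empty((n_frames, d_a + d_b + 6))
        za = rng_c.standard_normal((n_frames, d_a))
        zb = rng_c.standard_normal((n_frames, d_b))
        vals[:, :d_a] = mean[:d_a] + za * sd_bound[:d_a]
        vals[:, d_a:d_a + d_b] = mean[d_a:d_a + d_b] + zb * sd_bound[d_a:d_a + d_b]
        vals[:, d_a + d_b:] = _free_y_sample(rng_c, n_frames, r_max)
        bound = BATTrajectory(vals, descr)
    else:
        _check_wraparound(kinds_bound, mean, np.sqrt(np.diag(cov_bound)))
        chol = np.linalg.cholesky(cov_bound)
        vals = mean + rng_c.standard_normal((n_frames, len(mean))) @ chol.T
        bound = BATTrajectory(vals, descr)

    # ---- closed-form reference ----------------------------------------
    volume = 4.0 * np.pi * r_max**3 / 3.0
    ln8pi2v = float(external_reference_entropy(volume_nm3=volume))
    assert abs(ln8pi2v - _free_y_entropy(r_max)) < 1e-12

    def _s1d_sum(idx, sds):
        return sum(gaussian_entropy_1d(kinds_bound[i], mean[i], sds[i])
                   for i in idx)

    idx_a = range(d_a)
    idx_b = range(d_a, d_a + d_b)
    idx_y = range(d_a + d_b, d_a + d_b + 6)
    ds1d_a = _s1d_sum(idx_a, sd_bound) - _s1d_sum(idx_a, sd_unbound)
    ds1d_b = _s1d_sum(idx_b, sd_bound) - _s1d_sum(idx_b, sd_unbound)
    if y_narrow_factor is None:
        ds1d_y = 0.0
    else:
        ds1d_y = _s1d_sum(idx_y, sd_bound) - ln8pi2v

    cat_mi = {c: 0.0 for c in ("AA", "BB", "YY", "AB", "AY", "BY")}
    for _, _, rho, cat in pairs:
        cat_mi[cat] += -0.5 * np.log1p(-rho**2)
    ds_total = (ds1d_a + ds1d_b + ds1d_y - cat_mi["AA"] - cat_mi["BB"]
                - cat_mi["YY"] - cat_mi["AB"] - cat_mi["AY"] - cat_mi["BY"])
    reference = {
        "dS1D_A": float(ds1d_a), "dS1D_B": float(ds1d_b),
        "dS1D_Y": float(ds1d_y),
        "dI2D_AA": cat_mi["AA"], "dI2D_BB": cat_mi["BB"],
        "I2D_YY": cat_mi["YY"], "I2_AB": cat_mi["AB"],
        "I2_AY": cat_mi["AY"], "I2_BY": cat_mi["BY"],
        "dS_total": float(ds_total),
        "reference_volume_nm3": float(volume),
        "coupled_pairs": [(i, j, rho, cat) for i, j, rho, cat in pairs],
    }
    return bound, unbound_a, unbound_b, reference


def two_regime_trajectory(spec_1: SyntheticSpec, spec_2: SyntheticSpec,
                          switch_fraction: float = 0.5,
                          seed: int = 0) -> BATTrajectory:
    """Concatenate two Gaussian regimes (a slow conformational switch).

    The first ``switch_fraction`` of ``spec_1.n_frames`` total frames is
    drawn from regime 1, the rest from regime 2.  An unshuffled block
    analysis of the result converges late; a shuffled one does not.
    """
    if spec_1.dof_kinds != spec_2.dof_kinds:
        raise ValueError("regimes must share DOF kinds/dimensionality")
    if not 0.0 <= switch_fraction <= 1.0:
        raise ValueError("switch_fraction must be in [0, 1]")
    n = spec_1.n_frames
    n1 = int(round(switch_fraction * n))
    ss = np.random.SeedSequence(seed)
    r1, r2 = (np.random.default_rng(c) for c in ss.spawn(2))
    parts = []
    if n1 > 0:
        parts.append(sample_gaussian_bat(
            SyntheticSpec(spec_1.dof_kinds, spec_1.means, spec_1.covariance,
                          n1, seed, spec_1.subsystems), r1).values)
    if n - n1 > 0:
        parts.append(sample_gaussian_bat(
            SyntheticSpec(spec_2.dof_kinds, spec_2.means, spec_2.covariance,
                          n - n1, seed, spec_2.subsystems), r2).values)
    values = np.vstack(parts)
    return BATTrajectory(values, spec_1.descriptors())


def mixture_entropy_1d(kind: str, mu1: float, sigma1: float, mu2: float,
                       sigma2: float, weight: float = 0.5) -> float:
    """Numeric 1D entropy -∫ p ln(p/J) of a two-Gaussian mixture (oracle
    for the two-regime generator), units of R."""
    w = weight

    def p(x):
        return (w * stats.norm.pdf(x, mu1, sigma1)
                + (1 - w) * stats.norm.pdf(x, mu2, sigma2))

    def integrand(x):
        px = p(x)
        if px <= 0:
            return 0.0
        if kind in ("bond", "ext_bond"):
            lnj = 2.0 * np.log(x)
        elif kind in ("angle", "ext_angle"):
            lnj = np.log(np.sin(x))
        else:
            lnj = 0.0
        return -px * (np.log(px) - lnj)

    lo = min(mu1 - 10 * sigma1, mu2 - 10 * sigma2)
    hi = max(mu1 + 10 * sigma1, mu2 + 10 * sigma2)
    if kind in ("angle", "ext_angle"):
        lo, hi = max(lo, 1e-12), min(hi, np.pi - 1e-12)
    elif kind in ("bond", "ext_bond"):
        lo = max(lo, 1e-12)
    val, _ = integrate.quad(integrand, lo, hi, limit=200)
    return float(val)
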