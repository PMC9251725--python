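"""Binding configurational-entropy decomposition.

The configurational entropy change of binary binding is split, at
pairwise MIST order, into nine named terms (all in units of R):

``dS_total = dS1D_A + dS1D_B + dS1D_Y
             - dI2D_AA - dI2D_BB - I2D_YY - I2_AB - I2_AY - I2_BY``

where ``dS1D_A/B`` are bound-minus-unbound sums of 1D entropies over the
internal DOFs of each molecule, ``dS1D_Y = S_1D(Y_bound) - ln(8 pi^2 V°)``
is the rototranslational restriction of molecule 2 relative to the free
rigid-body reference, ``dI2D_AA/BB`` are bound-minus-unbound
within-molecule couplings, and the four remaining terms are bound-state
couplings read off one global MIST whose tree edges are attributed to
subsystem categories.  The momentum entropy and molecule 1's external
term are identical in bound and unbound states and cancel; they never
enter the decomposition.

The user-facing surface is the statsmodels-style pair
:class:`BindingEntropyModel` / :class:`BindingEntropyResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import (HistogramSpec, R_GAS, default_range, entropy_1d,
                         external_reference_entropy, pairwise_mi_matrix)
from .mist import MISTResult, mist_pairwise, mist_partitioned
from .topology import BATTrajectory

__all__ = [
    "DecompositionResult",
    "ConvergenceSeries",
    "SpanTable",
    "BindingEntropyModel",
    "BindingEntropyResults",
    "unbound_terms",
    "bound_terms",
    "binding_decomposition",
    "select_root_set",
    "convergence_series",
    "span_table",
]

TERM_NAMES = ("dS1D_A", "dS1D_B", "dS1D_Y", "dI2D_AA", "dI2D_BB",
              "I2D_YY", "I2_AB", "I2_AY", "I2_BY")
#: sign with which each term enters dS_total
TERM_SIGNS = dict(zip(TERM_NAMES, (1, 1, 1, -1, -1, -1, -1, -1, -1)))

_BOND_KINDS = ("bond", "ext_bond")


@dataclass
class DecompositionResult:
    """The named decomposition terms, in units of R.

    ``dS_total`` is always the exact signed sum of the nine terms (the
    bookkeeping identity); it is computed, never stored independently.
    """

    dS1D_A: float
    dS1D_B: float
    dS1D_Y: float
    dI2D_AA: float
    dI2D_BB: float
    I2D_YY: float
    I2_AB: float
    I2_AY: float
    I2_BY: float
    temperature: float = 300.0
    standard_concentration: float = 1.0
    root_set_B: tuple[int, int, int] | None = None
    n_dofs: int | None = None
    clamped_mi_total: float = 0.0

    @property
    def dS_total(self) -> float:
        return sum(TERM_SIGNS[t] * getattr(self, t) for t in TERM_NAMES)

    def term_dict(self, include_total: bool = True) -> dict[str, float]:
        d = {t: float(getattr(self, t)) for t in TERM_NAMES}
        if include_total:
            d["dS_total"] = float(self.dS_total)
        return d


@dataclass
class ConvergenceSeries:
    """Per-term decomposition values on cumulative frame prefixes."""

    block_ends: np.ndarray
    terms: dict[str, np.ndarray]
    shuffled: bool
    seed: int | None

    def final(self, term: str) -> float:
        return float(self.terms[term][-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.terms)
        df.insert(0, "block_end", self.block_ends)
        return df


@dataclass
class SpanTable:
    """Across-complex spans of the decomposition terms.

    ``percent`` expresses each term's span (max - min across complexes)
    relative to the span of ``dS_total`` (100% by definition).
    """

    per_complex: pd.DataFrame
    spans: pd.Series
    percent: pd.Series
    normalized_by_dofs: bool


def _term_ranges(bound: BATTrajectory, unbound_a: BATTrajectory,
                 unbound_b: BATTrajectory, spec: HistogramSpec):
    """Common bound/unbound histogram ranges per internal DOF.

    Bond-type DOFs get the union of bound and unbound supports so that
    entropy differences are taken on one discretization; fixed-range
    kinds need no attention.  Returns (ranges_bound, ranges_a, ranges_b)
    keyed by column index.
    """
    labels = bound.subsystem_labels()
    idx_a = np.flatnonzero(labels == "A")
    idx_b = np.flatnonzero(labels == "B")
    rb: dict[int, tuple[float, float]] = {}
    ra: dict[int, tuple[float, float]] = {}
    rbb: dict[int, tuple[float, float]] = {}
    for cols, unb, r_un in ((idx_a, unbound_a, ra), (idx_b, unbound_b, rbb)):
        for local, col in enumerate(cols):
            kind = bound.dofs[col].kind
            if kind not in _BOND_KINDS:
                continue
            both = np.concatenate([bound.values[:, col], unb.values[:, local]])
            r = default_range(kind, both, spec.bond_range_guard)
            rb[col] = r
            r_un[local] = r
    return rb, ra, rbb


@dataclass
class UnboundTerms:
    s1d: np.ndarray
    mist: MISTResult

    @property
    def s1d_sum(self) -> float:
        return float(self.s1d.sum())

    @property
    def i2d(self) -> float:
        return self.mist.i2d_total


def unbound_terms(traj: BATTrajectory, spec: HistogramSpec | None = None,
                  ranges: dict[int, tuple[float, float]] | None = None
                  ) -> UnboundTerms:
    """S_1D and within-molecule MIST coupling of one unbound molecule."""
    spec = spec or HistogramSpec()
    if any(d.subsystem == "Y" for d in traj.dofs):
        raise ValueError("unbound trajectory must not contain external (Y) DOFs")
    ranges = ranges or {}
    s1d = np.array([
        float(entropy_1d(traj.values[:, i], d.kind, spec,
                         value_range=ranges.get(i)))
        for i, d in enumerate(traj.dofs)
    ])
    if traj.n_dofs < 2:
        return UnboundTerms(s1d, MISTResult(float(s1d.sum()), [], 0.0))
    mi = pairwise_mi_matrix(traj, spec, ranges)
    return UnboundTerms(s1d, mist_pairwise(s1d, mi))


@dataclass
class BoundTerms:
    s1d: np.ndarray
    labels: np.ndarray
    mist: MISTResult
    category_sums: dict[tuple[str, str], float]
    clamped_mi_total: float

    def s1d_sum(self, label: str) -> float:
        return float(self.s1d[self.labels == label].sum())


def bound_terms(traj: BATTrajectory, spec: HistogramSpec | None = None,
                ranges: dict[int, tuple[float, float]] | None = None
                ) -> BoundTerms:
    """Per-subsystem S_1D and partitioned MIST couplings of a complex."""
    spec = spec or HistogramSpec()
    labels = traj.subsystem_labels()
    missing = set(labels) - {"A", "B", "Y"}
    if missing:
        raise ValueError(f"unknown subsystem labels: {sorted(missing)}")
    n_y = int((labels == "Y").sum())
    if n_y != 6:
        raise ValueError(f"a complex must carry exactly 6 Y DOFs, found {n_y}")
    ranges = ranges or {}
    s1d = np.array([
        float(entropy_1d(traj.values[:, i], d.kind, spec,
                         value_range=ranges.get(i)))
        for i, d in enumerate(traj.dofs)
    ])
    mi = pairwise_mi_matrix(traj, spec, ranges)
    mist, sums = mist_partitioned(s1d, mi, labels)
    return BoundTerms(s1d, labels, mist, sums, mi.clamped_total)


def binding_decomposition(bound: BATTrajectory, unbound_a: BATTrajectory,
                          unbound_b: BATTrajectory, temperature: float = 300.0,
                          standard_concentration: float = 1.0,
                          spec: HistogramSpec | None = None,
                          reference_volume_nm3: float | None = None,
                          root_set_B=None) -> DecompositionResult:
    """Assemble the full binding decomposition from three ensembles.

    The bound trajectory's DOF list must be the concatenation of the
    unbound molecules' internal DOFs (same kinds, same deterministic
    ordering) followed by the 6 Y DOFs; bond-type histograms use the
    union of bound and unbound supports per DOF.
    """
    spec = spec or HistogramSpec()
    labels = bound.subsystem_labels()
    for label, unb in (("A", unbound_a), ("B", unbound_b)):
        cols = np.flatnonzero(labels == label)
        if len(cols) != unb.n_dofs:
            raise ValueError(
                f"subsystem {label}: bound has {len(cols)} DOFs, unbound "
                f"has {unb.n_dofs}")
        for local, col in enumerate(cols):
            kb, ku = bound.dofs[col].kind, unb.dofs[local].kind
            if kb != ku:
                raise ValueError(
                    f"topology mismatch at subsystem {label} DOF {local}: "
                    f"bound kind {kb!r} vs unbound kind {ku!r}")

    rb, ra, rbb = _term_ranges(bound, unbound_a, unbound_b, spec)
    ub_a = unbound_terms(unbound_a, spec, ra)
    ub_b = unbound_terms(unbound_b, spec, rbb)
    bt = bound_terms(bound, spec, rb)

    ln8pi2v = float(external_reference_entropy(standard_concentration,
                                               reference_volume_nm3))
    cs = bt.category_sums
    return DecompositionResult(
        dS1D_A=bt.s1d_sum("A") - ub_a.s1d_sum,
        dS1D_B=bt.s1d_sum("B") - ub_b.s1d_sum,
        dS1D_Y=bt.s1d_sum("Y") - ln8pi2v,
        dI2D_AA=cs[("A", "A")] - ub_a.i2d,
        dI2D_BB=cs[("B", "B")] - ub_b.i2d,
        I2D_YY=cs[("Y", "Y")],
        I2_AB=cs[("A", "B")],
        I2_AY=cs[("A", "Y")],
        I2_BY=cs[("B", "Y")],
        temperature=temperature,
        standard_concentration=standard_concentration,
        root_set_B=tuple(root_set_B) if root_set_B is not None else None,
        n_dofs=bound.n_dofs,
        clamped_mi_total=bt.clamped_mi_total,
    )


class BindingEntropyModel:
    """Binding entropy decomposition model over three BAT ensembles.

    Parameters
    ----------
    bound, unbound_a, unbound_b
        BAT trajectories of the complex and of each free molecule; the
        bound DOF ordering must extend the unbound ones (see
        :func:`binding_decomposition`).
    temperature
        Kelvin; used only for the -T*dS reporting columns.
    standard_concentration
        mol/L; fixes the free rigid-body reference volume V° = 1/C°.
    reference_volume_nm3
        Direct per-molecule reference volume override (nm^3).
    histogram
        Binning policy; defaults to 50 bins in 1D and 50x50 in 2D.

    Examples
    --------
    >>> model = BindingEntropyModel(bound, ua, ub, temperature=300.0)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, bound: BATTrajectory, unbound_a: BATTrajectory,
                 unbound_b: BATTrajectory, *, temperature: float = 300.0,
                 standard_concentration: float = 1.0,
                 reference_volume_nm3: float | None = None,
                 histogram: HistogramSpec | None = None,
                 root_set_B=None) -> None:
        self.bound = bound
        self.unbound_a = unbound_a
        self.unbound_b = unbound_b
        self.temperature = float(temperature)
        self.standard_concentration = float(standard_concentration)
        self.reference_volume_nm3 = reference_volume_nm3
        self.histogram = histogram or HistogramSpec()
        self.root_set_B = root_set_B

    @classmethod
    def from_cartesian(cls, tree_complex, frames_bound, tree_a, frames_a,
                       tree_b, frames_b, **kwargs) -> "BindingEntropyModel":
        """Build the model from Cartesian ensembles and their BAT trees."""
        from .topology import cartesian_to_bat
        return cls(cartesian_to_bat(frames_bound, tree_complex),
                   cartesian_to_bat(frames_a, tree_a),
                   cartesian_to_bat(frames_b, tree_b), **kwargs)

    def fit(self) -> "BindingEntropyResults":
        result = binding_decomposition(
            self.bound, self.unbound_a, self.unbound_b,
            temperature=self.temperature,
            standard_concentration=self.standard_concentration,
            spec=self.histogram,
            reference_volume_nm3=self.reference_volume_nm3,
            root_set_B=self.root_set_B,
        )
        return BindingEntropyResults(self, result)

    def convergence(self, n_blocks: int = 10, shuffled: bool = False,
                    seed: int | None = None) -> ConvergenceSeries:
        return convergence_series(
            self.bound, self.unbound_a, self.unbound_b, n_blocks=n_blocks,
            shuffled=shuffled, seed=seed, temperature=self.temperature,
            standard_concentration=self.standard_concentration,
            spec=self.histogram,
            reference_volume_nm3=self.reference_volume_nm3)


class BindingEntropyResults:
    """Fitted decomposition with unit conversions and reporting."""

    def __init__(self, model: BindingEntropyModel,
                 result: DecompositionResult) -> None:
        self.model = model
        self.result = result

    def __getattr__(self, name):
        if name in TERM_NAMES or name == "dS_total":
            return getattr(self.result, name)
        raise AttributeError(name)

    @property
    def terms_R(self) -> dict[str, float]:
        """All terms plus the total, in units of R (nats)."""
        return self.result.term_dict()

    @property
    def terms_J_per_mol_K(self) -> dict[str, float]:
        return {k: v * R_GAS for k, v in self.terms_R.items()}

    @property
    def minus_T_dS_kJ_per_mol(self) -> dict[str, float]:
        """-T * term, in kJ/mol (the free-energy convention)."""
        T = self.result.temperature
        return {k: -T * v * R_GAS / 1000.0 for k, v in self.terms_R.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        mtds = self.minus_T_dS_kJ_per_mol
        for k, v in self.terms_R.items():
            rows.append({"term": k, "value_R": v, "value_J_per_mol_K": v * R_GAS,
                         "minus_T_dS_kJ_per_mol": mtds[k],
                         "sign_in_total": TERM_SIGNS.get(k, 1)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r = self.result
        lines = [
            "Binding configurational entropy decomposition (pairwise MIST)",
            f"  frames: bound={self.model.bound.frame_count}, "
            f"A={self.model.unbound_a.frame_count}, "
            f"B={self.model.unbound_b.frame_count};  DOFs: {r.n_dofs}",
            f"  T = {r.temperature:g} K,  C° = {r.standard_concentration:g} mol/L,"
            f"  bins = {self.model.histogram.bins_1d}/"
            f"{self.model.histogram.bins_2d}",
            f"  clamped negative MI total: {r.clamped_mi_total:.3e} R",
            "",
            f"  {'term':<10}{'[R]':>12}{'[J/mol/K]':>14}{'-T*dS [kJ/mol]':>17}",
            "  " + "-" * 53,
        ]
        mtds = self.minus_T_dS_kJ_per_mol
        for k, v in self.terms_R.items():
            marker = "" if k != "dS_total" else "  (total)"
            lines.append(f"  {k:<10}{v:>12.4f}{v * R_GAS:>14.3f}"
                         f"{mtds[k]:>17.3f}{marker}")
        return "\n".join(lines)

    def convergence(self, n_blocks: int = 10, shuffled: bool = False,
                    seed: int | None = None) -> ConvergenceSeries:
        return self.model.convergence(n_blocks, shuffled, seed)


def select_root_set(candidates, bound_traj_factory,
                    spec: HistogramSpec | None = None, criterion: str = "min",
                    standard_concentration: float = 1.0,
                    reference_volume_nm3: float | None = None):
    """Pick the molecule-2 root triple by its dS1D_Y.

    ``bound_traj_factory(candidate)`` must return the complex
    BATTrajectory with Y DOFs recomputed for that root triple.  The
    default criterion selects the candidate minimizing
    ``dS1D_Y = S_1D(Y) - ln(8 pi^2 V°)`` — the least coordinate-inflated
    estimate of the rototranslational restriction; ``"max"`` gives the
    adversarial choice.  Returns ``(chosen, table)`` with the full
    per-candidate table.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one root-set candidate")
    if criterion not in ("min", "max"):
        raise ValueError("criterion must be 'min' or 'max'")
    spec = spec or HistogramSpec()
    ln8pi2v = float(external_reference_entropy(standard_concentration,
                                               reference_volume_nm3))
    rows = []
    for cand in candidates:
        traj = bound_traj_factory(cand)
        labels = traj.subsystem_labels()
        y_cols = np.flatnonzero(labels == "Y")
        s1d_y = sum(float(entropy_1d(traj.values[:, c], traj.dofs[c].kind, spec))
                    for c in y_cols)
        rows.append({"root_set": tuple(cand), "dS1D_Y": s1d_y - ln8pi2v})
    table = pd.DataFrame(rows)
    pick = table["dS1D_Y"].idxmin() if criterion == "min" else table["dS1D_Y"].idxmax()
    return table.loc[pick, "root_set"], table


def convergence_series(bound: BATTrajectory, unbound_a: BATTrajectory,
                       unbound_b: BATTrajectory, n_blocks: int = 10,
                       shuffled: bool = False, seed: int | None = None,
                       temperature: float = 300.0,
                       standard_concentration: float = 1.0,
                       spec: HistogramSpec | None = None,
                       reference_volume_nm3: float | None = None
                       ) -> ConvergenceSeries:
    """Recompute the decomposition on cumulative frame prefixes.

    With ``shuffled=True`` each trajectory's frames are first permuted
    uniformly (seeded), which removes slow conformational drift and
    leaves only the sample-size dependence of the estimators; the final
    point always equals the full-sample result exactly.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    n = min(bound.frame_count, unbound_a.frame_count, unbound_b.frame_count)
    if n < 2 * n_blocks:
        raise ValueError(
            f"too few frames ({n}) for {n_blocks} blocks of at least 2 frames")
    trajs = [bound, unbound_a, unbound_b]
    if shuffled:
        ss = np.random.SeedSequence(0 if seed is None else seed)
        rngs = [np.random.default_rng(c) for c in ss.spawn(3)]
        trajs = [BATTrajectory(t.values[r.permutation(t.frame_count)], t.dofs)
                 for t, r in zip(trajs, rngs)]
    block_ends = np.unique((n * np.arange(1, n_blocks + 1) / n_blocks
                            ).astype(int))
    series: dict[str, list[float]] = {k: [] for k in
                                      (*TERM_NAMES, "dS_total")}
    for end in block_ends:
        prefix = [BATTrajectory(t.values[:end], t.dofs) for t in trajs]
        res = binding_decomposition(
            *prefix, temperature=temperature,
            standard_concentration=standard_concentration, spec=spec,
            reference_volume_nm3=reference_volume_nm3)
        for k, v in res.term_dict().items():
            series[k].append(v)
    return ConvergenceSeries(block_ends,
                             {k: np.array(v) for k, v in series.items()},
                             shuffled, seed)


def span_table(results, normalize_by_dofs: bool = False,
               n_dofs=None) -> SpanTable:
    """Across-complex span (max - min) of every decomposition term.

    With ``normalize_by_dofs`` each complex's terms are first divided by
    its 3N-6 (taken from the results unless ``n_dofs`` is given), which
    re-weights small complexes.  Percentages are spans relative to the
    span of ``dS_total``.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least 2 decomposition results for spans")
    rows = []
    for i, r in enumerate(results):
        row = r.term_dict()
        if normalize_by_dofs:
            nd = (n_dofs[i] if n_dofs is not None else r.n_dofs)
            if not nd:
                raise ValueError(f"result {i} has no DOF count for normalization")
            row = {k: v / nd for k, v in row.items()}
        rows.append(row)
    cols = ["dS_total", *TERM_NAMES]
    per_complex = pd.DataFrame(rows)[cols]
    spans = per_complex.max() - per_complex.min()
    total_span = spans["dS_total"]
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = 100.0 * spans / total_span
    percent["dS_total"] = 100.0  # by definition, even for degenerate panels
    return SpanTable(per_complex, spans, percent, normalize_by_dofs)
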