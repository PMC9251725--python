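# Methods

## Coordinates

A molecule's bond graph is spanned by a tree grown breadth-first from
three mutually bonded *root atoms* (ties broken by atom index), giving a
deterministic ordering of the 3N−6 internal coordinates: the two root
bonds and the root angle first, then one (bond, angle, torsion) triple
per placed atom. Torsions are signed IUPAC dihedrals on [−π, π) (cis = 0,
trans = −π; π maps to −π). At a branch, the first-placed child measures
its dihedral against the ancestor chain and every later sibling against
the first-placed child — no phase-angle re-parameterization, so each
coordinate remains a plain dihedral and periodic histograms apply
unchanged.

A complex is formed by a non-physical pseudobond from molecule 1's third
root atom (the anchor) to molecule 2's first root atom. The six
coordinates along the pseudobond chain — one distance, two planar
angles, three dihedrals — are the external (Y) degrees of freedom of
molecule 2 in molecule 1's frame. Molecule 2 keeps its own 3N−6 internal
coordinates, so a complex has (3N_A−6) + (3N_B−6) + 6 DOFs.
Reconstruction (BAT → Cartesian) uses standard NeRF forward kinematics
with the anchor convention r0 at the origin, r1 on +z, r2 in the xz
half-plane; the round trip Cartesian → BAT → Cartesian → BAT is the
identity to machine precision. Input angles exactly at 0 or π make the
dependent dihedral undefined; such frames are rejected (tolerance
1e−8 rad) rather than silently fixed.

Internal units are nm, radians, atomic mass units and entropies in units
of R; conversion to J mol⁻¹ K⁻¹ and −TΔS kJ mol⁻¹ happens only when a
report is written (R = 8.314462618 J mol⁻¹ K⁻¹).

## Entropy estimators

1D and 2D spatial entropies are plain plug-in histogram estimates of
−∫p ln(p/J) with the per-DOF Jacobian reference measure J evaluated at
bin midpoints (b² for bond-type, sin θ for angle-type, 1 for torsions).
Ranges: torsions fixed [−π, π), angles fixed [0, π], bond-type DOFs the
observed [min, max] plus a 1e−9 guard — periodic coordinates need fixed
supports, bond supports vary by orders of magnitude. Defaults are 50
bins (1D) and 50×50 (2D). No finite-sample bias correction is applied by
default; a Miller–Madow correction is available behind a flag.

Mutual information is always S_i + S_j − S_ij on one shared 2D binning,
with the marginals taken from the margins of the same 2D table. Two
consequences are exact, not approximate: the Jacobian factors cancel
identically (MI with and without reference measures agrees to rounding),
and the plug-in MI is a nonnegative KL divergence before noise; any
negative rounding residual is clamped to 0 and the clamped magnitude is
accumulated into the report. All estimators share one digitization code
path, so the MI matrix, the pair estimator and the 1D marginals are
mutually consistent to the last bit.

Known estimator errors, used throughout for test design: plug-in entropy
bias ≈ (k−1)/(2n); independence MI bias ≈ (k−1)²/(2n); discretization
error ≈ Δ²·F/24 for bin width Δ and Fisher information F (so a 2D
histogram underestimates MI once the conditional width approaches the
bin width — at 50×50 bins, Gaussian MI at ρ = 0.95 is biased low by
≈ 0.03 *regardless* of the marginal scale, which is why the
high-correlation recovery check runs at 100×100 while the package
default stays 50).

The momentum entropy is the closed-form Gaussian momentum integral
S_m/R = Σᵢ (3/2)[1 + ln(2π mᵢ k_B T/h²)]; it is constant for fixed
composition and temperature, and the decomposition relies on its exact
cancellation rather than its (dimensionally ambiguous) absolute value.
The external reference term is ln(8π²V°) with V° the per-molecule volume
at standard concentration C° (default 1 mol/L ⇒ V° ≈ 1.6606 nm³); V° can
also be set directly in nm³.

## MIST and MIE

The pairwise MIST entropy is ΣS_1D minus the total MI of a
maximum-weight spanning tree of the complete pairwise MI graph (Kruskal
with lexicographic tie-break, so the tree itself — not just its weight —
is reproducible). It is an upper bound on the joint entropy and exact in
expectation when the true dependence is tree-structured. Pairwise MIE
subtracts every pair instead and over-corrects whenever correlations
form loops. For a bound complex one *global* tree is built over all
DOFs and each tree edge's MI is attributed to exactly one of the six
subsystem-pair categories {AA, BB, YY, AB, AY, BY}; the category sums
add up to the tree total exactly (partition conservation). Triplet and
higher orders are out of scope.

## The decomposition

`ΔS_1D(A/B)` difference bound-minus-unbound marginal sums; `ΔI_2D(A/B)`
difference the bound within-molecule category sums against each
molecule's own unbound MIST; `ΔS_1D(Y) = S_1D(Ỹ) − ln(8π²V°)`; the
remaining couplings exist only in the bound state. Bound/unbound DOF
correspondence is established by topology identity plus the
deterministic DOF ordering — no atom mapping heuristics. For bond-type
DOFs the bound and unbound histograms share the union of both supports,
so Δ terms are differences on one discretization and binning artifacts
cancel. `ΔS_total` is always the exact signed sum of the nine terms (an
asserted bookkeeping identity, not an independently estimated number).

Root-atom choice for molecule 2 is fundamentally arbitrary; the package
enumerates bonded candidate triples deterministically (heavy atoms
preferred, 5 sets by default) and selects the one minimizing `ΔS_1D(Y)`
(maximization available as the adversarial reading). Convergence
diagnostics recompute all terms on cumulative frame prefixes, optionally
after a seeded uniform frame permutation; the shuffled/ordered contrast
distinguishes estimator sample-size effects from genuinely slow
conformational exchange. The final point of a series always equals the
full-sample result exactly (a permutation leaves every histogram
unchanged). Span tables report max−min of each term across a panel of
complexes, as a percentage of the `ΔS_total` span, optionally after
dividing each complex's terms by its 3N−6.

## Synthetic generators and what they do (not) show

Generators produce BAT ensembles whose target values are known in
closed form; they are first-class, tested code, not fixtures.

* Gaussian ensembles carry exact marginal/joint entropies. Jacobian
  expectations E[ln J] are evaluated by 64-node Gauss–Hermite quadrature
  (exact at these widths; far-tail nodes falling outside a coordinate's
  domain carry < 1e−9 weight and are dropped, anything larger is an
  error). Pairwise MI is −½ln(1−ρ²).
* Angular wrap-around is avoided by construction, not corrected:
  specs whose boundary mass exceeds 1e−6 are rejected. This admits
  torsion σ up to ≈ 0.64 rad; the test generators use up to 0.6 where
  the discretization analysis above requires it.
* The toy binding generator imposes couplings only on torsion-type DOF
  pairs, each DOF used at most once, so the true dependence graph is a
  forest — MIST is exact in expectation and every decomposition term is
  a sum of closed-form pieces. Internal marginals default to bond
  0.15 ± 0.005 nm, angle 1.911 ± 0.15 rad, torsion 0 ± 0.5 rad.
* The free (unbound) state of the external block is sampled from the
  Jacobian-weighted reference — radius ∝ b² on [0, R], angles ∝ sin θ,
  torsions uniform — whose per-DOF entropy sum equals ln(8π² · 4πR³/3)
  *exactly*; the generator reports that matched reference volume. In
  null-binding mode (no narrowing, no couplings) every closed-form term
  is therefore exactly zero. Narrowing divides each free-state standard
  deviation by the given factor (default 10) and switches the block to
  Gaussian.
* The two-regime generator concatenates two Gaussian regimes; its 1D
  oracle is the numerically integrated mixture entropy.

What passing these tests shows: the estimators, tree machinery and
bookkeeping recover known answers at realistic DOF widths and sample
sizes. What they do not show: behavior on real ensembles with
multimodal torsions comparable to the bin width, anharmonic couplings,
or slow conformational exchange — the convergence diagnostics exist
precisely because the estimators cannot certify exhaustive sampling.

## Test tolerances and problem sizes

Tolerances were fixed from the error formulas above before the checks
were run, and sample sizes chosen so a full suite plus the acceptance
script completes in a few minutes on one CPU: closed-form recovery at
n = 10⁶; MIST chain exactness at n = 5·10⁵ within 0.05 (predicted error
≈ +0.035 at σ = 0.6, ρ = 0.8); upper-bound margin ≥ −0.05 at n = 2·10⁵
(the slack absorbs the positive sample bias of the subtracted tree MIs);
cross-subsystem MIST edges ≤ 3·(k−1)²/(2n); null-binding terms within
3·(bias bound + Gaussian-theory standard error) — the leading plug-in
bias cancels exactly between bound and unbound states, so the standard
error √(d/n) dominates; toy-binding recovery within max(0.05 R, 5%) per
term, where the 5% branch covers `ΔS_1D(Y)`'s accumulated discretization
bias (≈ +0.13 R of ≈ −13 R at the default narrowing).

## Known limitations

Plug-in histograms with fixed bin counts under-resolve distributions
much narrower than a bin (severely restricted bound-state torsions) and
saturate MI near ln k for near-deterministic dependence. Pairwise order
misses all triplet and higher couplings. The external-DOF split depends
on the root-atom choice; the root scan quantifies but cannot remove that
arbitrariness. Bond-support binning ties the discretization to the
observed sample range, so entropies from very small ensembles are
range-biased low.
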