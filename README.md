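# batropy

Configurational entropy decomposition of biomolecular binding from
conformational ensembles, in bond–angle–torsion (BAT) internal
coordinates, using histogram entropies and the pairwise
maximum-information-spanning-tree (MIST) approximation.

## The problem

When two biomolecules bind, the solute loses configurational entropy:
internal motions stiffen, and one partner's rigid-body freedom collapses
to a narrow distribution relative to the other. Given ensembles of the
complex and of each unbound partner (e.g. from MD), `batropy` estimates
the spatial entropy change ΔS and splits it into named physical terms,
all in units of the gas constant R:

```
ΔS_total = ΔS_1D(A) + ΔS_1D(B) + ΔS_1D(Y)
           − ΔI_2D(A,A) − ΔI_2D(B,B) − I_2D(Ỹ,Ỹ)
           − I_2(Ã,B̃) − I_2(Ã,Ỹ) − I_2(B̃,Ỹ)
```

* `A`, `B` — internal degrees of freedom of molecules 1 and 2
  (3N−6 BAT coordinates each, built on a spanning tree of the bond graph
  anchored at three root atoms);
* `Y` — the six external (rototranslational) degrees of freedom of
  molecule 2 in molecule 1's frame, carried by a pseudobond that joins
  the two BAT trees; tildes mark bound-state quantities;
* `ΔS_1D` — bound-minus-unbound sums of marginal (1D) entropies;
  `ΔS_1D(Y) = S_1D(Ỹ) − ln(8π²V°)` measures the rigid-body restriction
  against the free reference at standard concentration C° = 1/V°;
* `ΔI_2D`, `I_2` — pairwise mutual-information couplings within and
  between subsystems, read off **one** global maximum spanning tree of
  the pairwise MI graph whose edges are attributed to subsystem pairs.

Marginal entropies and MIs are plug-in histogram estimates (default 50
bins in 1D, 50×50 in 2D) of −∫p ln(p/J) with the BAT Jacobian reference
measure J (b² for bonds, sin θ for angles, 1 for torsions); the Jacobian
factors cancel identically inside every MI. The momentum entropy and
molecule 1's external term are composition/temperature constants and
cancel exactly in the difference. MIST is an upper bound on the true
joint entropy and is exact when the dependence structure is a tree.

## Worked example

Every estimator ships with a generator whose ground truth is known in
closed form. The toy binding system below couples one torsion of A to
one of B (ρ = 0.8), one torsion of A to an external DOF (ρ = 0.6), and
narrows each external DOF tenfold relative to the free rigid-body state:

```python
import batropy as bp

bound, ua, ub, ref = bp.toy_binding_generator(
    n_atoms_a=5, n_atoms_b=4,
    couplings=[("AB", 0.8), ("AY", 0.6)],
    y_narrow_factor=10.0, n_frames=500_000, seed=1)

model = bp.BindingEntropyModel(
    bound, ua, ub, temperature=300.0,
    reference_volume_nm3=ref["reference_volume_nm3"])
res = model.fit()
print(res.summary())
```

```
Binding configurational entropy decomposition (pairwise MIST)
  frames: bound=500000, A=500000, B=500000;  DOFs: 21
  T = 300 K,  C° = 1 mol/L,  bins = 50/50
  clamped negative MI total: 0.000e+00 R

  term               [R]     [J/mol/K]   -T*dS [kJ/mol]
  -----------------------------------------------------
  dS1D_A         -0.0016        -0.013            0.004
  dS1D_B         -0.0010        -0.009            0.003
  dS1D_Y        -12.9812      -107.931           32.379
  dI2D_AA        -0.0083        -0.069            0.021
  dI2D_BB        -0.0056        -0.047            0.014
  I2D_YY          0.0000         0.000           -0.000
  I2_AB           0.5029         4.181           -1.254
  I2_AY           0.2208         1.836           -0.551
  I2_BY           0.0068         0.057           -0.017
  dS_total      -13.7004      -113.911           34.173  (total)
```

Reading this: the rigid-body restriction (`dS1D_Y`, here ≈ −13 R,
i.e. binding costs ≈ 32 kJ/mol at 300 K in −TΔS terms) dominates; the
imposed couplings are recovered at their analytic values
(−½ln(1−0.8²) ≈ 0.511 for `I2_AB`, −½ln(1−0.6²) ≈ 0.223 for `I2_AY`),
terms that were generated uncoupled sit at estimator noise, and the
total matches the generator's closed form (−13.85 R) to ~1%.

Diagnostics hang off the same objects: `model.convergence(n_blocks=10,
shuffled=True)` recomputes every term on cumulative frame prefixes (the
shuffled/ordered contrast separates sampling-size effects from slow
conformational drift), `bp.select_root_set(...)` scans candidate root
triples for molecule 2 and picks the one minimizing `dS1D_Y`, and
`bp.span_table(results)` compares term variation across a panel of
complexes.

A `batropy` CLI mirrors the library (`synth`, `bat`, `entropy`,
`decompose`, `convergence`, `rootscan`, `spans`); `batropy --show-config`
prints all defaults.

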