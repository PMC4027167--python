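# napring

Tools for inferring the quaternary architecture of NAP-1 fold histone
chaperones — dimers that further assemble into tetramers — from pulsed
electron–electron double resonance (PELDOR/DEER) distance measurements,
small-angle X-ray scattering (SAXS) and steady-state binding data.

Histone chaperones of the NAP-1 family adopt a "headphone" fold: a long
dimerisation helix with two globular "earmuff" domains. Under physiological
salt these dimers associate into dimers-of-dimers. Three arrangements are
plausible a priori: an earmuff-mediated ring ('O'), a side-by-side extended
arrangement ('M'), and a four-helix bundle of the dimerisation helices
('X'). `napring` implements the full inference chain that discriminates
them:

1. **Spin-label ensembles.** Accessible-volume sampling of nitroxide label
   positions for single-cysteine (R1) and bifunctional bridging (RX2)
   labels; a bridged label contributes one spin per dimer.
2. **Dipolar spectroscopy.** Forward simulation of two- and four-spin
   dipolar evolution traces with the orientation-averaged kernel
   K(t,r) = ∫₀¹ cos[2π(D/r³)(1−3x²)t] dx, D = 52.04 MHz·nm³; background
   correction; Tikhonov-regularised inversion to non-negative distance
   distributions P(r) with joint modulation-depth fitting and L-curve
   selection of the regularisation weight; assignment of the
   symmetry-distinct pair classes (AB within a dimer, AC/AD across the
   tetramer interface) using the multi-spin depth law 1−(1−λ)^(n−1).
3. **Symmetric docking.** C2-exact rigid-body docking of two dimer copies
   against flat-bottom restraints on ⟨r⁻³⟩-effective inter-label distances,
   with soft-sphere clash scoring, multi-start annealed local search, and
   interface-contact prediction from the accepted models.
4. **Scattering validation.** Debye-sum model curves, Guinier analysis,
   indirect transform to p(r) with automatic Dmax, error-weighted χ fits,
   and self-avoiding dummy-residue modelling of disordered termini. The χ
   fit discriminates the docked arrangements that the distance restraints
   alone leave degenerate.
5. **Association constant.** One-site saturation fit of dimer–dimer binding
   isotherms, R(C) = Rmax·C/(Kd + C).

A synthetic-data module generates all inputs with known ground truth — toy
headphone-fold dimers, all three tetramer topologies, labelled DEER traces,
scattering curves and binding isotherms — so the entire chain is testable
end to end.

## Worked example

Run the full pipeline on a synthetic ring-topology scenario:

```python
import napring

report = napring.run_pipeline({"seed": 1})
print(report["deer"]["bridge_tetramer"]["modal_distance_nm"])  # 7.0
print(report["docking"]["selected_rmsd_to_truth_A"])           # 0.578
print(report["docking"]["selected_model_chi"])                 # 1.049
print(report["binding"]["kd_uM"])                              # 0.624
```

The scenario simulates a tetramer whose bridged central label pair sits
7.05 nm apart; the fitted distance distribution puts the mode at 7.0 nm
(one grid step). Docking against the restraints derived from the fitted
distributions, followed by scattering-guided refinement, reproduces the
generating arrangement to 0.58 Å backbone RMSD with χ = 1.05 against the
synthetic scattering curve (χ ≈ 1 means the model fits within the noise).
The binding stage recovers the 0.6 μM dissociation constant used to
generate the isotherm. The same machinery is exposed piecewise on the
command line (`napring synth`, `simulate-deer`, `fit-deer`, `assign-peaks`,
`label`, `dock-tetramer`, `saxs-curve`, `guinier`, `pofr`, `chi-fit`,
`add-tails`, `fit-kd`, `seq-mass`, `run`).

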