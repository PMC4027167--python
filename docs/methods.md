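# Methods

This note records the models implemented in `napring`, the assumptions
behind them, the defaults that matter, and the choices made where the
design was genuinely open.

## Dipolar spectroscopy

**Kernel.** A pair of nitroxide spins at distance r (nm) contributes a
dipolar oscillation at ν(r, θ) = ν⊥(1 − 3cos²θ), ν⊥ = D/r³ with
D = 52.04 MHz·nm³ (the standard nitroxide point-dipole value). Averaging
over isotropic orientations gives

    K(t, r) = ∫₀¹ cos[2π ν⊥ (1 − 3x²) t] dx,

evaluated in closed form with Fresnel integrals; tests verify agreement
with direct fine-grid quadrature to 1e-8. K(0, r) = 1 and the
orientation-averaged kernel lies in [−0.5, 1].

**Forward model.** For n coupled spins with per-spin pump efficiency
(modulation depth) λ, each observer spin's intramolecular factor is the
product over its n−1 pumped partners of (1 − λ(1 − ∫P(r)K(t,r)dr)). In a
C2 dimer-of-dimers with one label per protomer the three symmetry-distinct
pair classes are AB ≡ CD (within a dimer) and AC ≡ BD, AD ≡ BC (across the
interface), so every observer sees one pair of each class. The total trace
is the intramolecular factor times an exponential intermolecular
background exp(−kt) plus additive Gaussian noise, renormalised to V(0)=1.
The pairwise-product form reproduces the multi-spin depth law
1 − (1 − λ)^(n−1) exactly (asserted to 1e-6 by reading the trace at a
kernel zero-crossing) but ignores sum/difference-frequency ghost terms;
inverted four-spin distributions can therefore show small spurious
intermediate peaks, which the peak-assignment step flags rather than
labels.

**Background correction.** B(t) = A·exp(−k t^{d/3}) is fitted log-linearly
to the tail beginning at 35% of the window (d = 3, homogeneous
three-dimensional background, configurable). The fitted amplitude absorbs
the unmodulated fraction, so the renormalised form factor has plateau
1 − λ_total. For long distances the tail itself oscillates; traces should
cover at least one full period of the slowest component (the synthetic
study uses windows of max(15 μs, 2.2·r³/D)), mirroring the experimental
practice of extending windows for long distances.

**Inversion.** Writing q_j = λ P_j Δr, the form factor obeys
F − 1 = (K − 1)q with q ≥ 0, so a single non-negative least-squares solve
of the Tikhonov-augmented system min ‖(K−1)q − (F−1)‖² + α²‖L₂q‖² yields
the distribution and the modulation depth λ = Σq jointly. α is selected on
a 61-point log ladder (1e-3–1e3) at the L-curve corner. The corner is
located as the point of maximum perpendicular distance below the endpoint
chord in the normalised log-log (residual, seminorm) plane, restricted to
the low-residual branch (residual within the first quarter of its log
range): the heavily over-regularised arm can form a second elbow that
would otherwise capture a curvature-based criterion, and boundary-pile-up
artefacts live there. Peak detection for assignment uses 3-point smoothing,
a relative height threshold (5% default; the pipeline uses 10% because
long-window inversions of noisy multi-spin data produce small spurious
bumps), and excludes maxima within 0.3 nm of the grid ends where the data
do not determine distances.

**Pair-class assignment.** Tetramer-condition peaks within a matching
tolerance of a dimer-condition peak keep the AB label; of the new peaks the
shortest is AC and the longest AD; a single new peak yields AC plus a
tentative AD flagged as overlapping AB. The pipeline's matching tolerance
is 0.5 nm — the combined mode uncertainty of two independent inversions of
broad-label distributions — while the library default is 0.3 nm for
well-resolved cases.

## Spin-label ensembles

Labels are modelled by accessible-volume sampling, not rotamer libraries:
candidate pseudo-nitroxide positions (N–O midpoint proxies) are drawn
uniformly in a spherical shell about the anchor Cβ (R1: 4–9 Å reach) or in
a ball of radius 6 Å about the midpoint of the two anchor Cβs (RX2, whose
bridged linker holds the ring between the linked cysteines); candidates
within 3.5 Å of any host heavy atom outside the anchor residues are
rejected and survivors weighted uniformly (2000 samples, seeded). Cβ is
synthesised from the backbone for glycine. No conformer energies or
orientation selection are modelled; all downstream quantities are
distances. The ⟨r⁻³⟩-effective distance (Σ wᵢwⱼ rᵢⱼ⁻³)^(−1/3) over cross
pairs is the docking observable, matching how dipolar couplings average.

## Symmetric docking

The second dimer copy is parameterised directly as a C2 operation (axis
direction θ, φ; axis point offset u, v in the perpendicular plane through
the dimer centroid), making the symmetry exact by construction and the
search four-dimensional. The score sums flat-bottom quadratic violations
of the ⟨r⁻³⟩ restraints (nm) and a soft-sphere Cα–Cα penalty (onset 4 Å,
weight 1, so one deep clash outweighs a 0.1 nm violation). Optimisation is
multi-start Nelder–Mead (random axis orientations, starting offsets 0.6–1.5
particle radii so copies begin separated) with four annealing restarts of
decreasing kick size per start; models above the acceptance threshold
(summed violation 0.3 nm default) are discarded and near-duplicate
transforms merged. During optimisation label ensembles stay fixed in the
dimer frame; ensembles can be rebuilt with the partner copy in the clash
filter for final reporting. Restraint ensembles are subsampled to 80
points for scoring, which changes ⟨r⁻³⟩ values by well under the restraint
tolerance.

Distance restraints from two or three labelling sites generically leave a
low-dimensional family of violation-free C2 arrangements (the ring can
rotate about the axis between the bridged labels). As in the experimental
logic, scattering resolves the remainder: the pipeline computes the Debye
curve of every accepted model, takes the best few by χ against the
tetramer-condition scattering curve, and refines each by a greedy random
walk along the restraint manifold — kick the C2 parameters, re-project by
minimising the restraint score alone, keep the step if χ improves —
followed by a Powell polish of score + 0.2·χ². The χ weight keeps
restraints primary: a 0.3 nm violation costs about what a χ change of 1
gains.

Model-based predictions: inter-copy residue contacts below a cutoff
(symmetric i–i′ pairs flagged as cross-link candidates), and steric
compatibility of a partner complex superposed onto one dimer copy via
shared-chain Cα Kabsch alignment.

## Scattering

Model intensities are vacuum Debye sums I(s) = Σᵢⱼ fᵢfⱼ sinc(s·rᵢⱼ) over
coarse-grained beads (one bead per residue at the atom centroid with the
residue electron count, or per-atom electron counts); no hydration shell
or excluded-volume term is included, which biases absolute Rg comparisons
with shell-aware predictors by ~1–3%. Pair distances are binned at 0.1 Å
before the sinc sum for large models (relative error < 0.2%). s = 4π
sinθ/λ in Å⁻¹; default grid 0–0.5 Å⁻¹, 512 points.

Guinier fits iterate the window s·Rg ≤ 1.3 to self-consistency. The
truncated-window bias for a compact sphere is ≈ +1.8% at 1.3 and falls
below 1% at s·Rg ≤ 0.9; analyses of known-globular bodies should use the
tighter window, as the sphere tests do. Elongated particles carry a
percent-level bias of opposite sign.

The indirect transform solves min ‖I_model − I‖²_σ + α‖p″‖² with p ≥ 0 and
p(0) = p(Dmax) = 0 by NNLS (α = 1.0 default, matched to percent-level
noise; use smaller α for noiseless curves). Auto-Dmax scans a ladder up to
4 Guinier radii and keeps the smallest Dmax whose residual is within 5% of
the best; Dmax from noisy curves is determined only to roughly the ladder
spacing. Discrete few-bead models produce a legitimate r ≈ 0 self-term
peak in p(r).

χ = sqrt((1/N) Σ[(c·I_model − I_exp)/σ]²) with the scalar c minimising the
sum and the model interpolated onto the experimental grid.

Disordered termini are modelled as self-avoiding walks of one dummy bead
per residue (step 3.8 Å, 3 Å excluded volume against host and self,
seeded, up to 100 regeneration retries); the ensemble reproduces the Flory
end-to-end scaling exponent ≈ 0.59.

## Binding and masses

Dimer–dimer association is fitted as one-site saturation
R(C) = Rmax·C/(Kd + C) by least squares with asymptotic standard errors;
kinetic phases are not modelled. Masses are average (not monoisotopic)
residue masses plus one water per chain.

## Synthetic data

The toy dimer is a geometric stand-in for the headphone fold: a rod of
Cα-like beads (virtual-bond spacing 3.8 Å, rod span 56 Å per protomer, ±3 Å
lateral offset) and an earmuff shell of 60 beads (radius 13 Å, centre 9 Å
beyond the rod end, 8 Å lateral, 22 Å below the rod plane), with an exact
internal C2 and a CB atom 1.5 Å outward of every bead so labels can
anchor. The scale was chosen once so that the ring assembly's inter-label
distances fall in the 5–10 nm regime the method addresses. Topologies: 'O'
(earmuff–earmuff ring, global C2, earmuff centres 30 Å apart at the
interface), 'M' (side-by-side, in-plane two-fold), 'X' (rod bundle, 7.9 Å
rod separation). Canonical sites: a bridged RX2-style site at the rod
centre (ring-distance reporter, truth ≈ 7.05 nm across the ring), and two
R1 sites per earmuff (top and outer rim) whose AB/AC/AD classes differ —
two independent sites are required to pin the dimer–dimer orientation,
exactly as multiple labelling positions are in practice.

Default study conditions: λ = 0.3 per pumped spin, background 0.05 μs⁻¹,
additive trace noise sd 0.01, 20 μs windows at 16 ns steps; SAXS curves
carry 2% multiplicative Gaussian noise with the σ column reported; binding
isotherms are 8-point 3-fold dilutions from 10·Kd with Gaussian response
noise (5% of Rmax) in triplicate, Kd = 0.6 μM. Every generator is a pure
function of (parameters, seed) and outputs carry a scenario hash.

What the toys do not emulate: real side-chain packing and label–surface
interactions, orientation selection, ESEEM and detector artefacts, beam
smearing, hydration scattering, and concentration effects. Passing tests
therefore demonstrate the correctness and internal consistency of the
inference chain under its stated noise models, not instrument-level
robustness.

## Numerical choices and limitations

- Distance grid 1.5–12 nm at 0.05 nm (synthesis uses 13 nm to cover the
  longest ensemble tails); kernel constant fixed at 52.04 MHz·nm³.
- NNLS via the active-set solver; non-convergence raises with α reported.
- Modal distances break ties toward smaller r; flat distributions warn.
- The four-spin inversion uses the two-spin kernel on the product form
  factor, a linearisation that is standard practice but biases component
  amplitudes when λ is large.
- Auto-Dmax and the L-curve corner are heuristics; both report their
  chosen parameter so results can be re-run with fixed values.
- Docking explores only C2 arrangements (the observed assembly symmetry);
  asymmetric tetramers are out of scope, as are flexible docking and
  side-chain repacking.
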