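"""Synthetic ground-truth generators for every pipeline input.

The toy dimer is a geometric stand-in for the NAP-1 "headphone" fold: each
protomer is a rigid rod of Cα-like beads (the long dimerisation helix) plus
a spherical shell of beads (the earmuff domain) hanging below the rod plane,
and the two protomers are related by an exact C2. Three tetramer topologies
place a second dimer copy: an earmuff-mediated ring ('O'), a side-by-side
extended arrangement ('M'), and a four-helix-bundle-like rod stack ('X').
The geometry is scaled so the 'O' assembly's inter-label distances fall in
the 6–10 nm regime where pulsed dipolar spectroscopy operates, making the
default distance grid and kernel realistic.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import deer as deer_mod
from .binding import BindingIsotherm
from .deer import (DeerTrace, DistanceDistribution, SpinTopology,
                   default_r_grid, default_t_grid, simulate_trace)
from .labels import LabelEnsemble, LabelSite, build_label_ensemble, \
    ensemble_distance_distribution
from .saxs import ScatteringCurve, coarse_grain, debye_curve, default_s_grid
from .structure import Atom, RigidTransform, Structure, pair_distance_histogram

__all__ = [
    "SyntheticScenario", "make_toy_dimer", "make_tetramer_geometry",
    "toy_label_sites", "synth_deer_dataset", "synth_saxs_dataset",
    "synth_binding_dataset", "SynthDeerData", "SynthSaxsData",
]

DEFAULT_DIMER_PARAMS = dict(
    rod_length=56.0,      # Å, dimerisation-helix rod span per protomer
    rod_spacing=3.8,      # Å between rod beads (Cα virtual-bond length)
    rod_offset=3.0,       # Å lateral offset of each rod from the C2 axis
    ear_radius=13.0,      # Å earmuff shell radius
    ear_beads=60,         # beads on the earmuff shell
    ear_overhang=9.0,     # Å earmuff centre beyond the rod end
    ear_offset_y=8.0,     # Å lateral earmuff displacement
    ear_drop=22.0,        # Å earmuff centre below the rod plane
)

DEFAULT_TETRAMER_PARAMS = dict(
    contact=30.0,         # Å earmuff centre–centre distance at the interface
    bundle_gap=7.9,       # Å rod–rod distance in the 'X' stack
)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic even point placement on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z ** 2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_toy_dimer(params: dict | None = None, seed: int = 0) -> Structure:
    """Two-protomer headphone-fold stand-in with an exact internal C2 (z axis).

    Chains A and B; each bead residue carries a CA atom and a CB atom 1.5 Å
    outward so labelling sites can be anchored. Deterministic for fixed
    parameters (the seed is accepted for interface uniformity).
    """
    p = dict(DEFAULT_DIMER_PARAMS, **(params or {}))
    n_rod = int(round(p["rod_length"] / p["rod_spacing"])) + 1
    xs = (np.arange(n_rod) - (n_rod - 1) / 2.0) * p["rod_spacing"]
    rod = np.column_stack([xs, np.full(n_rod, p["rod_offset"]), np.zeros(n_rod)])

    ear_center = np.array([p["rod_length"] / 2.0 + p["ear_overhang"],
                           p["ear_offset_y"], -p["ear_drop"]])
    shell = ear_center + p["ear_radius"] * _fibonacci_sphere(int(p["ear_beads"]))
    protomer = np.vstack([rod, shell])
    centroid = protomer.mean(axis=0)

    atoms = []
    c2z = np.diag([-1.0, -1.0, 1.0])
    for chain, flip in (("A", False), ("B", True)):
        pos = protomer @ c2z.T if flip else protomer
        cen = centroid @ c2z.T if flip else centroid
        for i, ca in enumerate(pos):
            outward = ca - cen
            nrm = np.linalg.norm(outward)
            outward = outward / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
            cb = ca + 1.5 * outward
            atoms.append(Atom("CA", "C", i + 1, "ALA", chain, ca, 12.011))
            atoms.append(Atom("CB", "C", i + 1, "ALA", chain, cb, 12.011))
    return Structure(atoms)


def toy_label_sites(params: dict | None = None) -> dict:
    """Canonical labelling sites on the toy dimer.

    ``bridge``: an RX2-style site bridging the two central rod residues (one
    label per dimer, anchored near the dimer centre — the ring-distance
    reporter). ``ear``: an R1 site on the top bead of each earmuff (long
    intra-dimer AB reporter). ``rim``: an R1 site on the outer rim
    bead of each earmuff, whose interface distances differ from the ear
    site's — two independent sites are needed to pin the dimer–dimer
    orientation, just as multiple labelling positions are in practice.
    """
    p = dict(DEFAULT_DIMER_PARAMS, **(params or {}))
    n_rod = int(round(p["rod_length"] / p["rod_spacing"])) + 1
    center_res = (n_rod + 1) // 2
    shell = _fibonacci_sphere(int(p["ear_beads"]))
    ear_res = n_rod + int(np.argmax(shell[:, 2])) + 1   # top bead
    rim_res = n_rod + int(np.argmax(shell[:, 1])) + 1   # outer-rim (+y) bead
    return {
        "bridge": LabelSite("RX2", (f"A:{center_res}", f"B:{center_res}")),
        "ear_A": LabelSite("R1", (f"A:{ear_res}",)),
        "ear_B": LabelSite("R1", (f"B:{ear_res}",)),
        "rim_A": LabelSite("R1", (f"A:{rim_res}",)),
        "rim_B": LabelSite("R1", (f"B:{rim_res}",)),
    }


def make_tetramer_geometry(topology: str, dimer: Structure,
                           params: dict | None = None):
    """Assemble a tetramer of the requested topology.

    Returns ``(assembly, transform)`` where ``transform`` maps dimer copy 1
    onto copy 2 (an exact involution for 'O' and 'X'; also for 'M', whose
    in-plane two-fold keeps the arrangement side-by-side and extended).
    Copy-2 chains are renamed A→C, B→D.
    """
    p = dict(DEFAULT_DIMER_PARAMS)
    p.update(DEFAULT_TETRAMER_PARAMS)
    p.update(params or {})
    ear_x = p["rod_length"] / 2.0 + p["ear_overhang"]
    ear_c = np.array([ear_x, p["ear_offset_y"], -p["ear_drop"]])
    contact = p["contact"]
    dy = 2.0 * p["ear_offset_y"]
    if contact <= dy:
        raise ValueError("contact distance must exceed the lateral offset")
    dz = np.sqrt(contact ** 2 - dy ** 2)

    if topology == "O":
        # π rotation about the x axis at height z = c: earmuffs meet pairwise
        c = -(2.0 * p["ear_drop"] + dz) / 2.0
        T = RigidTransform.from_rotvec_point(np.array([1.0, 0.0, 0.0]), np.pi,
                                             np.array([0.0, 0.0, c]))
    elif topology == "M":
        # π rotation about a vertical axis beyond one earmuff: side-by-side
        x0 = ear_x + np.sqrt(max(contact ** 2 - dy ** 2, 0.0)) / 2.0
        T = RigidTransform.from_rotvec_point(np.array([0.0, 0.0, 1.0]), np.pi,
                                             np.array([x0, 0.0, 0.0]))
    elif topology == "X":
        # rods stacked into a bundle: π rotation about x at small depth
        dy_rod = 2.0 * p["rod_offset"]
        gap = p["bundle_gap"]
        dz_rod = np.sqrt(max(gap ** 2 - dy_rod ** 2, 1.0))
        T = RigidTransform.from_rotvec_point(np.array([1.0, 0.0, 0.0]), np.pi,
                                             np.array([0.0, 0.0, -dz_rod / 2.0]))
    else:
        raise ValueError(f"unknown topology {topology!r}; expected O, M or X")

    copy2 = dimer.transformed(T).with_chain_ids({"A": "C", "B": "D"})
    return dimer.merge(copy2), T


@dataclass
class SyntheticScenario:
    """All knobs of one synthetic study condition, with its seed."""

    topology: str = "O"
    dimer_params: dict = field(default_factory=dict)
    tetramer_params: dict = field(default_factory=dict)
    mod_depth: float = 0.3           # λ per pumped spin
    background_rate: float = 0.05    # μs⁻¹ exponential background
    deer_noise_sd: float = 0.01      # additive Gaussian on V(t)
    saxs_noise: float = 0.02         # multiplicative Gaussian on I(s)
    t_max: float = 20.0              # μs
    t_step: float = 0.016            # μs
    seed: int = 0

    def __post_init__(self):
        if self.topology not in ("O", "M", "X"):
            raise ValueError(f"unknown topology {self.topology!r}")
        for name in ("mod_depth", "background_rate", "t_max", "t_step"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def scenario_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"scenario topology={self.topology} seed={self.seed} " \
               f"hash={self.scenario_hash()}"


@dataclass
class SynthDeerData:
    scenario: SyntheticScenario
    dimer: Structure
    assembly: Structure
    transform: RigidTransform
    ensembles: dict          # name -> LabelEnsemble (copy-1 frame)
    truth: dict              # e.g. "ear.AB", "bridge.ring" -> DistanceDistribution
    traces: dict             # condition name -> DeerTrace


def synth_deer_dataset(scenario: SyntheticScenario,
                       r_grid: np.ndarray | None = None) -> SynthDeerData:
    """Build toy ensembles, derive true P(r) per pair class, simulate traces.

    Conditions emitted: ``ear_dimer`` (2-spin, AB only, the high-salt dimer
    analogue), ``ear_tetramer`` (4-spin AB/AC/AD), and ``bridge_tetramer``
    (2-spin between the two bridged labels of the assembly).
    """
    r = default_r_grid(1.5, 13.0) if r_grid is None else r_grid
    sc = scenario
    dimer = make_toy_dimer(sc.dimer_params, sc.seed)
    assembly, T = make_tetramer_geometry(sc.topology, dimer, sc.tetramer_params)
    sites = toy_label_sites(sc.dimer_params)

    ens = {
        "bridge": build_label_ensemble(dimer, sites["bridge"], seed=sc.seed),
        "ear_A": build_label_ensemble(dimer, sites["ear_A"], seed=sc.seed + 1),
        "ear_B": build_label_ensemble(dimer, sites["ear_B"], seed=sc.seed + 2),
        "rim_A": build_label_ensemble(dimer, sites["rim_A"], seed=sc.seed + 3),
        "rim_B": build_label_ensemble(dimer, sites["rim_B"], seed=sc.seed + 4),
    }
    truth = {"bridge.ring": ensemble_distance_distribution(
        ens["bridge"], ens["bridge"].transformed(T), r)}
    for stem in ("ear", "rim"):
        truth[f"{stem}.AB"] = ensemble_distance_distribution(
            ens[f"{stem}_A"], ens[f"{stem}_B"], r)
        truth[f"{stem}.AC"] = ensemble_distance_distribution(
            ens[f"{stem}_A"], ens[f"{stem}_A"].transformed(T), r)
        truth[f"{stem}.AD"] = ensemble_distance_distribution(
            ens[f"{stem}_A"], ens[f"{stem}_B"].transformed(T), r)
    t_grid = default_t_grid(sc.t_max, sc.t_step)
    traces = {"bridge_tetramer": simulate_trace(
        {"AB": truth["bridge.ring"]}, SpinTopology(2), sc.mod_depth,
        sc.background_rate, sc.deer_noise_sd, sc.seed + 12, t_grid)}
    for i, stem in enumerate(("ear", "rim")):
        traces[f"{stem}_dimer"] = simulate_trace(
            {"AB": truth[f"{stem}.AB"]}, SpinTopology(2), sc.mod_depth,
            sc.background_rate, sc.deer_noise_sd, sc.seed + 10 + 10 * i, t_grid)
        traces[f"{stem}_tetramer"] = simulate_trace(
            {"AB": truth[f"{stem}.AB"], "AC": truth[f"{stem}.AC"],
             "AD": truth[f"{stem}.AD"]}, SpinTopology(4), sc.mod_depth,
            sc.background_rate, sc.deer_noise_sd, sc.seed + 11 + 10 * i, t_grid)
    return SynthDeerData(scenario=sc, dimer=dimer, assembly=assembly,
                         transform=T, ensembles=ens, truth=truth, traces=traces)


@dataclass
class SynthSaxsData:
    scenario: SyntheticScenario
    curves: dict             # "dimer" | topology -> noisy ScatteringCurve
    ideal: dict              # same keys, noiseless curves
    truth: dict              # "rg.dimer", "dmax.O", ... -> float


def synth_saxs_dataset(scenario: SyntheticScenario,
                       s_grid: np.ndarray | None = None,
                       topologies=("O", "M", "X")) -> SynthSaxsData:
    """Debye curves of the dimer and each topology with multiplicative noise."""
    s = default_s_grid() if s_grid is None else s_grid
    sc = scenario
    rng = np.random.default_rng(sc.seed + 100)
    dimer = make_toy_dimer(sc.dimer_params, sc.seed)
    bodies = {"dimer": dimer}
    for topo in topologies:
        bodies[topo], _ = make_tetramer_geometry(topo, dimer, sc.tetramer_params)

    curves, ideal, truth = {}, {}, {}
    for name, body in bodies.items():
        model = coarse_grain(body, level="residue")
        clean = debye_curve(model, s)
        sigma = np.maximum(sc.saxs_noise * clean.I, 1e-12)
        noisy_I = clean.I * (1.0 + sc.saxs_noise * rng.normal(size=s.size)) \
            if sc.saxs_noise > 0 else clean.I.copy()
        curves[name] = ScatteringCurve(s, np.maximum(noisy_I, 1e-12), sigma)
        ideal[name] = clean
        # truth Rg from the same bead representation the curves come from
        cen = (model.positions * model.weights[:, None]).sum(0) / model.weights.sum()
        truth[f"rg.{name}"] = float(np.sqrt(
            (model.weights * ((model.positions - cen) ** 2).sum(1)).sum()
            / model.weights.sum()))
        truth[f"dmax.{name}"] = pair_distance_histogram(body, 1.0).dmax
    return SynthSaxsData(scenario=sc, curves=curves, ideal=ideal, truth=truth)


def synth_binding_dataset(kd: float = 0.6, rmax: float = 1.0,
                          noise_sd: float = 0.0,
                          concentrations: np.ndarray | None = None,
                          n_replicates: int = 1, seed: int = 0) -> BindingIsotherm:
    """One-site saturation responses with additive Gaussian noise.

    The default design is an 8-point 3-fold dilution series from 10·Kd down,
    mirroring a typical biosensor titration; ``noise_sd`` is in response
    units (e.g. 0.05·Rmax for 5% noise).
    """
    if kd <= 0 or rmax <= 0:
        raise ValueError("Kd and Rmax must be positive")
    if concentrations is None:
        concentrations = 10.0 * kd * 3.0 ** -np.arange(8, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if not np.any(conc > 0):
        raise ValueError("need at least one positive concentration")
    rng = np.random.default_rng(seed)
    concs, resps, reps = [], [], []
    for rep in range(n_replicates):
        resp = rmax * conc / (kd + conc)
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=conc.size)
        concs.append(conc)
        resps.append(resp)
        reps.append(np.full(conc.size, rep))
    return BindingIsotherm(np.concatenate(concs), np.concatenate(resps),
                           np.concatenate(reps))
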