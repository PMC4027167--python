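"""Distance-restrained symmetric rigid-body docking of a dimer-of-dimers.

The tetramer is parameterised directly as a C2 operation — a two-fold
rotation about an axis with direction (θ, φ) passing through a point offset
(u, v) in the plane perpendicular to the axis through the dimer centroid —
so the dimer-of-dimers symmetry is exact by construction (4 degrees of
freedom instead of 6). The score combines flat-bottom quadratic penalties on
⟨r⁻³⟩-effective inter-label distances with a soft-sphere Cα clash term, and
is minimised by multi-start Nelder–Mead; no gradients are used because the
clash-filtered label ensembles make the score only piecewise smooth.

During optimisation label ensembles are kept fixed in the dimer frame (copy
2 uses the transformed copy-1 ensemble); accepted candidates are re-filtered
against both copies for final reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import AlignmentError, DockingFailure
from .labels import (LabelEnsemble, LabelSite, build_label_ensemble,
                     effective_r3_distance)
from .structure import (RigidTransform, Structure, kabsch_superpose)

__all__ = [
    "RestraintR3", "TetramerModel", "DockResult",
    "c2_transform", "dock_symmetric_tetramer", "restraint_violation",
    "clash_score", "soft_clash_penalty", "predict_interface_contacts",
    "superpose_and_clash", "tetramer_rmsd",
]

CLASH_CUTOFF = 4.0     # Å, Cα–Cα soft-sphere onset
CLASH_WEIGHT = 1.0     # one deep clash (penalty ~1) outweighs 0.1 nm violation
ACCEPT_VIOLATION = 0.3  # nm, summed flat-bottom violation threshold


@dataclass
class RestraintR3:
    """Flat-bottom restraint on the ⟨r⁻³⟩ distance between two label ensembles.

    ``ensemble_a`` lives on dimer copy 1; ``ensemble_b`` is given in the
    copy-1 frame and is mapped by the candidate C2 transform onto copy 2.
    """

    ensemble_a: LabelEnsemble
    ensemble_b: LabelEnsemble
    target: float       # nm
    tolerance: float = 0.1  # nm
    label: str = ""

    def __post_init__(self):
        if self.target <= 0:
            raise ValueError("restraint target must be positive")
        if self.tolerance < 0:
            raise ValueError("restraint tolerance must be non-negative")


@dataclass
class TetramerModel:
    """Two dimer copies related by a C2 transform, with quality scores."""

    dimer: Structure
    transform: RigidTransform
    violations: np.ndarray = field(default_factory=lambda: np.zeros(0))
    clash_count: int = 0
    score: float = np.inf

    def __post_init__(self):
        # C2 check: applying the transform twice must be the identity
        TT = self.transform.compose(self.transform)
        if not (np.allclose(TT.rotation, np.eye(3), atol=1e-3)
                and np.allclose(TT.translation, 0.0, atol=1e-3)):
            raise ValueError("tetramer transform is not a C2 involution")
        self.violations = np.asarray(self.violations, dtype=float)
        if np.any(self.violations < 0):
            raise ValueError("violations must be non-negative")

    @property
    def total_violation(self) -> float:
        return float(self.violations.sum())

    def copy2(self) -> Structure:
        return self.dimer.transformed(self.transform)

    def assembly(self, chain_map: dict | None = None) -> Structure:
        """Full tetramer; copy-2 chains renamed via ``chain_map`` (default
        appends a prime-style suffix by mapping A→C, B→D, ...)."""
        copy2 = self.copy2()
        if chain_map is None:
            used = list(self.dimer.chains)
            alphabet = [c for c in "CDEFGHIJKLMNOPQRSTUVWXYZ" if c not in used]
            chain_map = {c: alphabet[i] for i, c in enumerate(used)}
        return self.dimer.merge(copy2.with_chain_ids(chain_map))


@dataclass
class DockResult:
    models: list            # accepted, sorted by score
    rejected: int
    n_starts: int
    seed: int
    best_score: float

    @property
    def best(self) -> TetramerModel:
        if not self.models:
            raise DockingFailure("no accepted models", best_score=self.best_score)
        return self.models[0]


def c2_transform(axis_theta: float, axis_phi: float, offset_u: float,
                 offset_v: float, origin: np.ndarray | None = None) -> RigidTransform:
    """C2 operation: π rotation about the axis with polar direction
    (θ, φ) through the point origin + u·e₁ + v·e₂, with e₁, e₂ spanning the
    plane perpendicular to the axis."""
    st, ct = np.sin(axis_theta), np.cos(axis_theta)
    sp, cp = np.sin(axis_phi), np.cos(axis_phi)
    u = np.array([st * cp, st * sp, ct])
    # orthonormal frame perpendicular to u
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    point = (np.zeros(3) if origin is None else np.asarray(origin, float)) \
        + offset_u * e1 + offset_v * e2
    R = 2.0 * np.outer(u, u) - np.eye(3)
    return RigidTransform(R, point - R @ point)


def params_from_transform(T: RigidTransform,
                          origin: np.ndarray | None = None) -> np.ndarray:
    """Invert :func:`c2_transform`: recover (θ, φ, u, v) from a C2 operation."""
    w, V = np.linalg.eigh(T.rotation)
    u = V[:, np.argmax(w)]          # eigenvector with eigenvalue +1
    theta = float(np.arccos(np.clip(u[2], -1.0, 1.0)))
    phi = float(np.arctan2(u[1], u[0]))
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    p_perp = T.translation / 2.0
    o = np.zeros(3) if origin is None else np.asarray(origin, float)
    o_perp = o - u * (u @ o)
    rel = p_perp - o_perp
    x = np.array([theta, phi, rel @ e1, rel @ e2])
    # the eigenvector sign is arbitrary; both give the same operation
    return x


def soft_clash_penalty(ca1: np.ndarray, ca2: np.ndarray,
                       cutoff: float = CLASH_CUTOFF) -> float:
    """Σ ((cutoff − d)/cutoff)² over inter-copy Cα pairs with d < cutoff."""
    tree = cKDTree(ca2)
    pairs = tree.query_ball_point(ca1, cutoff)
    penalty = 0.0
    for i, js in enumerate(pairs):
        if js:
            d = np.linalg.norm(ca2[js] - ca1[i], axis=1)
            penalty += (((cutoff - d) / cutoff) ** 2).sum()
    return float(penalty)


def _flat_bottom(r_eff: float, target: float, tol: float) -> float:
    return max(0.0, abs(r_eff - target) - tol)


def _score_transform(T: RigidTransform, restraints, ca: np.ndarray,
                     clash_cutoff: float, clash_weight: float) -> float:
    total = 0.0
    for res in restraints:
        r_eff = effective_r3_distance(res.ensemble_a,
                                      res.ensemble_b.transformed(T))
        total += _flat_bottom(r_eff, res.target, res.tolerance) ** 2
    total += clash_weight * soft_clash_penalty(ca, T.apply(ca), clash_cutoff)
    return total


def dock_symmetric_tetramer(dimer: Structure, restraints,
                            n_starts: int = 32, seed: int = 0,
                            clash_cutoff: float = CLASH_CUTOFF,
                            clash_weight: float = CLASH_WEIGHT,
                            accept_viol: float = ACCEPT_VIOLATION,
                            sites: list | None = None,
                            refilter_ensembles: bool = True,
                            maxiter: int = 600, n_anneal: int = 4) -> DockResult:
    """Multi-start C2 docking of two dimer copies against R⁻³ restraints.

    Starts are random axis orientations with the axis point offset so the two
    copies begin well separated; each start is locally minimised with
    Nelder–Mead. Models whose summed flat-bottom violation exceeds
    ``accept_viol`` (nm) are discarded. ``sites`` (optional) lists the
    LabelSites of the restraint ensembles so they can be rebuilt with the
    partner copy in the clash filter for final reporting.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    restraints = list(restraints)
    ca_mask = dimer.mask(atom_name="CA", include_het=False)
    ca = dimer.positions[ca_mask]
    centroid = dimer.centroid("uniform")
    extent = float(np.linalg.norm(dimer.positions - centroid, axis=1).max())

    rng = np.random.default_rng(seed)
    candidates = []
    best_score = np.inf
    for _ in range(n_starts):
        theta = np.arccos(1.0 - 2.0 * rng.random())
        phi = 2.0 * np.pi * rng.random()
        # offset magnitude ~ particle radius: copies start separated
        mag = extent * (0.6 + 0.9 * rng.random())
        ang = 2.0 * np.pi * rng.random()
        x0 = np.array([theta, phi, mag * np.cos(ang), mag * np.sin(ang)])

        def objective(x):
            T = c2_transform(*x, origin=centroid)
            return _score_transform(T, restraints, ca, clash_cutoff, clash_weight)

        res = minimize(objective, x0, method="Nelder-Mead",
                       options=dict(maxiter=maxiter, xatol=1e-4, fatol=1e-10))
        # simulated-annealing-style restarts: perturb the minimum and re-refine
        temp = 1.0
        for _ in range(n_anneal):
            if res.fun < 1e-8:
                break
            kick = rng.normal(size=4) * temp * np.array([0.4, 0.4, 8.0, 8.0])
            res2 = minimize(objective, res.x + kick, method="Nelder-Mead",
                            options=dict(maxiter=maxiter, xatol=1e-4, fatol=1e-10))
            if res2.fun < res.fun:
                res = res2
            temp *= 0.5
        T = c2_transform(*res.x, origin=centroid)
        score = float(res.fun)
        best_score = min(best_score, score)
        candidates.append((score, T))

    accepted, rejected = [], 0
    for score, T in sorted(candidates, key=lambda c: c[0]):
        model_restraints = restraints
        if refilter_ensembles and sites is not None:
            copy2 = dimer.transformed(T)
            model_restraints = []
            for res, site in zip(restraints, sites):
                try:
                    ens = build_label_ensemble(dimer, site, seed=seed,
                                               extra_host=copy2)
                except Exception:
                    ens = res.ensemble_a
                model_restraints.append(RestraintR3(
                    ens, ens, res.target, res.tolerance, res.label))
        viols = np.array([
            _flat_bottom(effective_r3_distance(r.ensemble_a,
                                               r.ensemble_b.transformed(T)),
                         r.target, r.tolerance)
            for r in model_restraints])
        if viols.sum() > accept_viol:
            rejected += 1
            continue
        model = TetramerModel(dimer=dimer, transform=T, violations=viols,
                              clash_count=clash_score_positions(ca, T.apply(ca),
                                                                clash_cutoff),
                              score=score)
        accepted.append(model)
    accepted.sort(key=lambda m: m.score)
    # deduplicate near-identical solutions by transform distance
    unique = []
    for m in accepted:
        if all(np.linalg.norm(m.transform.translation - u.transform.translation) > 1.0
               or np.linalg.norm(m.transform.rotation - u.transform.rotation) > 0.05
               for u in unique):
            unique.append(m)
    return DockResult(models=unique, rejected=rejected, n_starts=n_starts,
                      seed=seed, best_score=best_score)


def restraint_violation(model: TetramerModel, r: RestraintR3) -> float:
    """Flat-bottom violation (nm) of one restraint, recomputed from scratch."""
    r_eff = effective_r3_distance(r.ensemble_a,
                                  r.ensemble_b.transformed(model.transform))
    return _flat_bottom(r_eff, r.target, r.tolerance)


def clash_score_positions(ca1: np.ndarray, ca2: np.ndarray,
                          cutoff: float = CLASH_CUTOFF) -> int:
    tree = cKDTree(ca2)
    return int(sum(len(js) for js in tree.query_ball_point(ca1, cutoff)))


def clash_score(model: TetramerModel, cutoff: float = CLASH_CUTOFF) -> int:
    """Number of inter-copy Cα–Cα pairs closer than ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca_mask = model.dimer.mask(atom_name="CA", include_het=False)
    ca = model.dimer.positions[ca_mask]
    return clash_score_positions(ca, model.transform.apply(ca), cutoff)


def predict_interface_contacts(model: TetramerModel, cutoff: float = 5.0):
    """Inter-copy residue pairs with any-atom distance below ``cutoff`` Å.

    Returns a list of ``(residue_1, residue_2, distance, symmetric)`` sorted
    by distance, where residues are ``(chain, resnum, resname)`` tuples and
    ``symmetric`` flags i–i′ self pairs (cross-link candidates).
    """
    dimer = model.dimer
    copy2_pos = model.transform.apply(dimer.positions)
    tree = cKDTree(copy2_pos)
    pairs = {}
    neighbours = tree.query_ball_point(dimer.positions, cutoff)
    for i, js in enumerate(neighbours):
        for j in js:
            d = float(np.linalg.norm(copy2_pos[j] - dimer.positions[i]))
            key = ((dimer.chain_ids[i], int(dimer.residue_numbers[i]),
                    dimer.residue_names[i]),
                   (dimer.chain_ids[j], int(dimer.residue_numbers[j]),
                    dimer.residue_names[j]))
            if key not in pairs or d < pairs[key]:
                pairs[key] = d
    out = []
    for (r1, r2), d in sorted(pairs.items(), key=lambda kv: kv[1]):
        symmetric = r1[1] == r2[1] and r1[2] == r2[2]
        out.append((r1, r2, d, symmetric))
    return out


def superpose_and_clash(model: TetramerModel, partner_complex: Structure,
                        align_map: dict, cutoff: float = 3.0) -> int:
    """Superpose a partner complex onto one dimer copy and count clashes.

    ``align_map`` maps a chain id of ``partner_complex`` (the shared
    component) to a chain id of the dimer. The optimal rigid superposition is
    computed over shared Cα atoms matched by residue number; the return value
    counts atom pairs closer than ``cutoff`` Å between the *non-shared*
    partner chains and the other dimer copy.
    """
    mob_pts, tgt_pts = [], []
    for p_chain, d_chain in align_map.items():
        pm = partner_complex.mask(chain=p_chain, atom_name="CA")
        for i in np.flatnonzero(pm):
            resnum = int(partner_complex.residue_numbers[i])
            tgt = model.dimer.atom_position(d_chain, resnum, "CA")
            if tgt is not None:
                mob_pts.append(partner_complex.positions[i])
                tgt_pts.append(tgt)
    if len(mob_pts) < 3:
        raise AlignmentError(
            f"only {len(mob_pts)} paired CA atoms; need >= 3")
    T = kabsch_superpose(np.array(mob_pts), np.array(tgt_pts))
    shared = set(align_map.keys())
    other_mask = ~np.isin(partner_complex.chain_ids, sorted(shared))
    if not other_mask.any():
        return 0
    partner_pos = T.apply(partner_complex.positions[other_mask])
    copy2_pos = model.transform.apply(model.dimer.positions)
    tree = cKDTree(copy2_pos)
    return int(sum(len(js) for js in tree.query_ball_point(partner_pos, cutoff)))


def tetramer_rmsd(model: TetramerModel, truth_transform: RigidTransform,
                  truth_dimer: Structure | None = None) -> float:
    """Backbone (Cα) RMSD of the model assembly to a reference assembly.

    The reference is ``truth_dimer`` (default: the model's dimer) plus its
    image under ``truth_transform``. Copy order and the dimer's own internal
    C2 make the labelling ambiguous, so the minimum over copy-swap is taken.
    """
    dimer = model.dimer if truth_dimer is None else truth_dimer
    ca = dimer.positions[dimer.mask(atom_name="CA", include_het=False)]
    truth = np.vstack([ca, truth_transform.apply(ca)])
    model_ca = np.vstack([ca, model.transform.apply(ca)])
    swapped = np.vstack([model.transform.apply(ca), ca])
    from .structure import kabsch_rmsd
    return min(kabsch_rmsd(model_ca, truth), kabsch_rmsd(swapped, truth))
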