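"""Spin-label ensembles and inter-label distance observables.

Labels are modelled by accessible-volume sampling: pseudo-nitroxide positions
(N–O midpoint proxies) are drawn in a spherical shell about the anchor Cβ
(single-cysteine R1 labels) or about the midpoint of the two anchor Cβs
(bifunctional RX2 labels that bridge two cysteines, one spin per bridge), and
candidates clashing with host heavy atoms are rejected. No rotamer energies
or orientation effects are modelled; distances, not chemistry, drive the
downstream restraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import BuriedSiteError, RangeError, SingularRestraintError
from .structure import RigidTransform, Structure

__all__ = [
    "LabelSite", "LabelEnsemble", "build_label_ensemble",
    "ensemble_distance_distribution", "effective_r3_distance",
    "parse_site", "write_ensemble", "read_ensemble",
]

R1_DEFAULTS = dict(min_reach=4.0, max_reach=9.0)
RX2_DEFAULTS = dict(min_reach=0.0, max_reach=6.0)
CLASH_CUTOFF = 3.5  # Å, pseudo-nitroxide vs host heavy atom
N_SAMPLES = 2000


def parse_site(token: str) -> tuple:
    """Parse a ``chain:resnum`` residue reference."""
    chain, _, num = token.partition(":")
    if not chain or not num:
        raise ValueError(f"bad site reference {token!r}; expected chain:resnum")
    return chain, int(num)


@dataclass(frozen=True)
class LabelSite:
    """A labelling site: R1 on one residue or RX2 bridging two."""

    chemistry: str  # "R1" | "RX2"
    anchors: tuple

    def __post_init__(self):
        if self.chemistry not in ("R1", "RX2"):
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        anchors = tuple(self.anchors)
        expected = 1 if self.chemistry == "R1" else 2
        if len(anchors) != expected:
            raise ValueError(
                f"{self.chemistry} requires {expected} anchor(s), got {len(anchors)}")
        if self.chemistry == "RX2" and anchors[0] == anchors[1]:
            raise ValueError("RX2 anchors must be distinct residues")
        object.__setattr__(self, "anchors", anchors)

    def __str__(self):
        return f"{'+'.join(self.anchors)}{self.chemistry}"


@dataclass
class LabelEnsemble:
    """Weighted cloud of pseudo-nitroxide positions (Å) for one site."""

    positions: np.ndarray
    weights: np.ndarray
    site: LabelSite | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.positions.shape[0] < 1:
            raise ValueError("ensemble needs at least one position")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total

    def __len__(self):
        return self.positions.shape[0]

    def transformed(self, T: RigidTransform) -> "LabelEnsemble":
        return LabelEnsemble(T.apply(self.positions), self.weights.copy(), self.site)

    def centroid(self) -> np.ndarray:
        return (self.positions * self.weights[:, None]).sum(axis=0)

    def subsample(self, n: int, seed: int = 0) -> "LabelEnsemble":
        """Weighted random subset of at most ``n`` positions (for fast scoring)."""
        if len(self) <= n:
            return self
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self), size=n, replace=False, p=self.weights)
        w = np.full(n, 1.0 / n)
        return LabelEnsemble(self.positions[idx], w, self.site)


def _synth_cbeta(n, ca, c):
    """Place an idealised Cβ from backbone N, CA, C (glycine case)."""
    b1 = n - ca
    b2 = c - ca
    b1 /= np.linalg.norm(b1)
    b2 /= np.linalg.norm(b2)
    bisector = -(b1 + b2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b2, b1)
    perp /= np.linalg.norm(perp)
    # tetrahedral direction, 1.53 Å bond
    direction = bisector * np.cos(0.9599) + perp * np.sin(0.9599)
    return ca + 1.53 * direction


def _anchor_point(s: Structure, token: str) -> np.ndarray:
    chain, resnum = parse_site(token)
    cb = s.atom_position(chain, resnum, "CB")
    if cb is not None:
        return cb
    ca = s.atom_position(chain, resnum, "CA")
    if ca is None:
        raise ValueError(f"anchor residue {token} has no CA atom")
    n = s.atom_position(chain, resnum, "N")
    c = s.atom_position(chain, resnum, "C")
    if n is not None and c is not None:
        return _synth_cbeta(n, ca, c)
    return ca


def build_label_ensemble(s: Structure, site: LabelSite, *,
                         max_reach: float | None = None,
                         min_reach: float | None = None,
                         clash_cutoff: float = CLASH_CUTOFF,
                         n_samples: int = N_SAMPLES,
                         seed: int = 0,
                         extra_host: Structure | None = None) -> LabelEnsemble:
    """Accessible-volume sampling of label positions for ``site``.

    Candidates are drawn uniformly in the shell [min_reach, max_reach] about
    the anchor point (Cβ for R1; Cβ-midpoint for RX2); points within
    ``clash_cutoff`` of any host heavy atom outside the anchor residues are
    discarded and survivors weighted uniformly. ``extra_host`` adds another
    structure (e.g. the partner copy of an assembly) to the clash filter.
    """
    defaults = R1_DEFAULTS if site.chemistry == "R1" else RX2_DEFAULTS
    lo = defaults["min_reach"] if min_reach is None else min_reach
    hi = defaults["max_reach"] if max_reach is None else max_reach
    if hi <= 0 or hi < lo:
        raise ValueError("require 0 < max_reach and min_reach <= max_reach")

    anchors = [_anchor_point(s, a) for a in site.anchors]
    center = np.mean(anchors, axis=0)

    # heavy atoms excluding the anchor residues themselves
    mask = s.heavy_mask()
    for token in site.anchors:
        chain, resnum = parse_site(token)
        mask &= ~(s.mask(chain=chain, residue_number=resnum))
    host = s.positions[mask]
    if extra_host is not None:
        host = np.vstack([host, extra_host.positions[extra_host.heavy_mask()]])
    tree = cKDTree(host) if host.shape[0] else None

    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_samples, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = (rng.random(n_samples) * (hi ** 3 - lo ** 3) + lo ** 3) ** (1.0 / 3.0)
    candidates = center + u * radii[:, None]
    if tree is not None:
        dist, _ = tree.query(candidates)
        candidates = candidates[dist >= clash_cutoff]
    if candidates.shape[0] == 0:
        raise BuriedSiteError(f"site {site} is buried: no unclashed label positions")
    w = np.full(candidates.shape[0], 1.0 / candidates.shape[0])
    return LabelEnsemble(candidates, w, site)


def ensemble_distance_distribution(a: LabelEnsemble, b: LabelEnsemble,
                                   r_grid_nm: np.ndarray):
    """Weighted cross-pair distance histogram of two ensembles as P(r) in nm."""
    from .deer import DistanceDistribution

    r = np.asarray(r_grid_nm, dtype=float)
    dr = np.diff(r)
    if np.any(dr <= 0) or not np.allclose(dr, dr[0], rtol=1e-6):
        raise ValueError("r-grid must be uniform and increasing")
    d_nm = cdist(a.positions, b.positions) / 10.0
    w = np.outer(a.weights, b.weights)
    step = dr[0]
    edges = np.concatenate([r - step / 2, [r[-1] + step / 2]])
    if d_nm.min() < edges[0] or d_nm.max() >= edges[-1]:
        raise RangeError(
            f"distance {d_nm.min():.3f}–{d_nm.max():.3f} nm outside grid "
            f"[{edges[0]:.3f}, {edges[-1]:.3f}) nm")
    hist, _ = np.histogram(d_nm.ravel(), bins=edges, weights=w.ravel())
    P = hist / (hist.sum() * step)
    return DistanceDistribution(r=r, P=P)


def effective_r3_distance(a: LabelEnsemble, b: LabelEnsemble) -> float:
    """⟨r⁻³⟩-averaged effective distance in nm: (Σᵢⱼ wᵢwⱼ rᵢⱼ⁻³)^(−1/3)."""
    d_nm = cdist(a.positions, b.positions) / 10.0
    if np.any(d_nm < 1e-9):
        raise SingularRestraintError("coincident label positions (r = 0)")
    w = np.outer(a.weights, b.weights)
    mean_inv_cube = float((w * d_nm ** -3).sum())
    return mean_inv_cube ** (-1.0 / 3.0)


def write_ensemble(e: LabelEnsemble, path) -> None:
    """Serialise as an ASCII table ``x y z weight`` (Å) with a site header."""
    header = f"label ensemble site={e.site}\nx_A  y_A  z_A  weight"
    np.savetxt(path, np.column_stack([e.positions, e.weights]),
               header=header, comments="# ")


def read_ensemble(path) -> LabelEnsemble:
    data = np.loadtxt(path, comments="#", ndmin=2)
    return LabelEnsemble(data[:, :3], data[:, 3])
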