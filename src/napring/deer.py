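"""Pulsed electron–electron double resonance (PELDOR/DEER) forward models
and Tikhonov inversion for two- and four-spin systems.

The dipolar evolution of a spin pair at distance r (nm) oscillates at the
orientation-dependent frequency ν(r, θ) = ν⊥(r)(1 − 3cos²θ) with
ν⊥ = D/r³ and D = 52.04 MHz·nm³ for a nitroxide pair. Orientation averaging
gives the kernel

    K(t, r) = ∫₀¹ cos[2π ν⊥(r) (1 − 3x²) t] dx ,

evaluated here in closed form with Fresnel integrals. A dimer-of-dimers with
one label per protomer is a four-spin system: each observer spin couples to
three pumped partners, one from each symmetry-distinct pair class (AB within
a dimer, AC and AD across the tetramer interface), and the intramolecular
form factor is the product of the per-pair factors. This pairwise-product
forward model reproduces the multi-spin modulation-depth law
1 − (1 − λ)^(n−1) but ignores ghost-peak harmonics — a known limitation.

Inversion follows the standard workflow: an exponential background is fitted
to the trace tail and divided out, then the form factor is inverted to a
non-negative distance distribution P(r) by Tikhonov-regularised NNLS with
L-curve selection of the regularisation weight. The modulation depth λ is
fitted jointly with P(r) (the NNLS unknown is q = λ P Δr, so λ = Σq).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks
from scipy.special import fresnel

from .errors import (InsufficientTailError, RangeError, SolverError,
                     TopologyError)

__all__ = [
    "DIPOLAR_CONSTANT_MHZ_NM3",
    "DeerTrace", "DistanceDistribution", "SpinTopology", "DeerFitResult",
    "BackgroundFit", "PeakAssignment",
    "dipolar_kernel", "simulate_trace", "modulation_depth",
    "fit_background", "tikhonov_invert", "fit_deer",
    "modal_distance", "find_distribution_peaks", "assign_symmetric_distances",
    "default_r_grid", "default_t_grid", "read_trace", "write_trace",
    "read_distribution", "write_distribution",
]

DIPOLAR_CONSTANT_MHZ_NM3 = 52.04

# pair-class symmetry of a C2 dimer-of-dimers with one spin per protomer:
# AB ≡ CD (within a dimer), AC ≡ BD and AD ≡ BC (across the interface)
FOUR_SPIN_CLASSES = ("AB", "AC", "AD")
_EQUIVALENT = {"CD": "AB", "BD": "AC", "BC": "AD",
               "AB": "AB", "AC": "AC", "AD": "AD"}


def default_r_grid(r_min: float = 1.5, r_max: float = 12.0,
                   step: float = 0.05) -> np.ndarray:
    """Distance grid in nm covering the long-range regime of the method."""
    return np.round(np.arange(r_min, r_max + step / 2, step), 10)


def default_t_grid(t_max: float = 15.0, step: float = 0.008) -> np.ndarray:
    """Time grid in μs; 8 ns steps out to 15 μs."""
    return np.arange(0.0, t_max + step / 2, step)


@dataclass
class DeerTrace:
    """Normalised dipolar evolution V(t), t in μs from zero."""

    t: np.ndarray
    V: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.V)):
            raise ValueError("trace values must be finite")
        if abs(self.V[0] - 1.0) > 1e-6:
            raise ValueError("trace must be normalised to V(0)=1")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


@dataclass
class DistanceDistribution:
    """Non-negative distance distribution P(r) on a uniform nm grid, unit area."""

    r: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        dr = np.diff(self.r)
        if np.any(dr <= 0) or not np.allclose(dr, dr[0], rtol=1e-6):
            raise ValueError("r-grid must be uniform and increasing")
        if np.any(self.P < -1e-12):
            raise ValueError("P must be non-negative")
        self.P = np.clip(self.P, 0.0, None)
        area = np.trapezoid(self.P, self.r)
        if area <= 0:
            raise ValueError("P must have positive area")
        if abs(area - 1.0) > 1e-6:
            self.P = self.P / area

    @classmethod
    def delta(cls, r0: float, r_grid: np.ndarray) -> "DistanceDistribution":
        """Unit mass in the grid bin nearest r0."""
        P = np.zeros_like(r_grid, dtype=float)
        P[int(np.argmin(np.abs(r_grid - r0)))] = 1.0
        return cls(r_grid, P)

    @classmethod
    def gaussian(cls, mean: float, sd: float,
                 r_grid: np.ndarray) -> "DistanceDistribution":
        P = np.exp(-0.5 * ((r_grid - mean) / sd) ** 2)
        return cls(r_grid, P)

    def mean(self) -> float:
        return float(np.trapezoid(self.r * self.P, self.r))

    def effective_r3(self) -> float:
        """(⟨r⁻³⟩)^(−1/3) of the distribution, nm — the docking restraint scale."""
        inv3 = float(np.trapezoid(self.P * self.r ** -3, self.r))
        return inv3 ** (-1.0 / 3.0)


@dataclass(frozen=True)
class SpinTopology:
    """Number of coupled spins and the symmetry-distinct pair classes."""

    n_spins: int

    def __post_init__(self):
        if self.n_spins not in (2, 4):
            raise TopologyError("supported topologies have 2 or 4 spins")

    @property
    def pair_classes(self):
        return ("AB",) if self.n_spins == 2 else FOUR_SPIN_CLASSES

    @property
    def pairs_per_observer(self) -> int:
        return self.n_spins - 1


@dataclass
class BackgroundFit:
    rate: float           # k, μs⁻¹
    dimension: float      # stretch exponent d in exp(−k t^{d/3})
    amplitude: float      # fitted tail intercept (absorbs 1−λ_total)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-self.rate * np.asarray(t) ** (self.dimension / 3.0))


@dataclass
class DeerFitResult:
    P: DistanceDistribution
    alpha: float
    background: BackgroundFit | None
    mod_depth: float
    residual_norm: float

    def __post_init__(self):
        if not 0.0 < self.mod_depth < 1.0:
            raise ValueError("modulation depth must lie in (0, 1)")


def dipolar_kernel(t_us: np.ndarray, r_nm: np.ndarray,
                   dipolar_constant: float = DIPOLAR_CONSTANT_MHZ_NM3) -> np.ndarray:
    """Orientation-averaged dipolar kernel K[t, r]; K(0, r) = 1.

    Closed form via Fresnel integrals of the integral
    ∫₀¹ cos[2π(D/r³)(1−3x²)t] dx.
    """
    t = np.atleast_1d(np.asarray(t_us, dtype=float))
    r = np.atleast_1d(np.asarray(r_nm, dtype=float))
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    nu = dipolar_constant / r ** 3  # MHz
    phi = 2.0 * np.pi * np.outer(np.abs(t), nu)  # radians
    K = np.ones_like(phi)
    nz = phi > 1e-9
    p = phi[nz]
    q = np.sqrt(6.0 * p / np.pi)
    S, C = fresnel(q)
    K[nz] = np.sqrt(np.pi / (6.0 * p)) * (np.cos(p) * C + np.sin(p) * S)
    return K


def modulation_depth(n_spins: int, lam: float) -> float:
    """Total echo modulation depth of an n-spin system: 1 − (1−λ)^(n−1)."""
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return 1.0 - (1.0 - lam) ** (n_spins - 1)


def simulate_trace(components: dict, topology: SpinTopology, lam: float,
                   background_rate: float = 0.0, noise_sd: float = 0.0,
                   seed: int = 0, t_grid: np.ndarray | None = None) -> DeerTrace:
    """Forward-simulate a dipolar trace.

    ``components`` maps pair-class labels to :class:`DistanceDistribution`;
    equivalent labels (CD→AB, BD→AC, BC→AD) are accepted. Per observer spin
    the intramolecular factor is Π over its pairs of (1 − λ(1 − ∫P K dr));
    the trace is that factor times exp(−k t), plus Gaussian noise, then
    renormalised to V(0)=1.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("modulation depth λ must lie in (0, 1)")
    t = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    canon = {}
    for label, P in components.items():
        if label not in _EQUIVALENT:
            raise TopologyError(f"unknown pair label {label!r}")
        canon[_EQUIVALENT[label]] = P
    missing = [c for c in topology.pair_classes if c not in canon]
    if missing:
        raise TopologyError(f"missing distance component(s) for pair(s) {missing}")

    factor = np.ones_like(t)
    for cls_label in topology.pair_classes:
        P = canon[cls_label]
        K = dipolar_kernel(t, P.r)
        S = np.trapezoid(K * P.P[None, :], P.r, axis=1)
        factor *= 1.0 - lam * (1.0 - S)
    V = factor * np.exp(-background_rate * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        V = V + rng.normal(0.0, noise_sd, size=V.shape)
    V = V / V[0]
    sigma = np.full_like(V, noise_sd) if noise_sd > 0 else None
    return DeerTrace(t=t, V=V, sigma=sigma)


def fit_background(trace: DeerTrace, fit_start_fraction: float = 0.35,
                   dimension: float = 3.0):
    """Fit B(t) = A·exp(−k t^{d/3}) to the trace tail and divide it out.

    Returns ``(BackgroundFit, form_factor_trace)`` with the form factor
    renormalised to F(0) = 1. The fitted amplitude absorbs the unmodulated
    fraction, so the form factor's tail plateau estimates 1 − λ_total.
    """
    if not 0.0 < fit_start_fraction < 1.0:
        raise ValueError("fit_start_fraction must lie in (0, 1)")
    t, V = trace.t, trace.V
    tail = t >= fit_start_fraction * t[-1]
    tail &= V > 0
    if tail.sum() < 5:
        raise InsufficientTailError(
            f"background tail has {int(tail.sum())} points; need >= 5")
    x = t[tail] ** (dimension / 3.0)
    y = np.log(V[tail])
    slope, intercept = np.polyfit(x, y, 1)
    k = max(-slope, 0.0)
    bg = BackgroundFit(rate=float(k), dimension=float(dimension),
                       amplitude=float(np.exp(intercept)))
    decay = np.exp(-k * t ** (dimension / 3.0))
    F = V / decay
    F = F / F[0]
    sigma = None
    if trace.sigma is not None:
        sigma = trace.sigma / decay / F[0]
    return bg, DeerTrace(t=t, V=F, sigma=sigma)


def _second_difference(m: int) -> np.ndarray:
    L = np.zeros((m - 2, m))
    for i in range(m - 2):
        L[i, i:i + 3] = (1.0, -2.0, 1.0)
    return L


def _alpha_ladder(n: int = 61, lo: float = 1e-3, hi: float = 1e3) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _lcurve_corner(residuals: np.ndarray, seminorms: np.ndarray) -> int:
    """Corner of the log-log (residual, seminorm) L-curve.

    The corner is located as the point of maximum perpendicular distance
    below the chord joining the curve's endpoints in the normalised log-log
    plane — a robust surrogate for the maximum-curvature point that does not
    require numerical second derivatives.
    """
    x = np.log10(np.maximum(residuals, 1e-14))
    y = np.log10(np.maximum(seminorms, 1e-14))
    # keep only the low-residual branch: the heavily over-regularised arm can
    # form a second elbow that would otherwise capture the chord criterion
    cap = x.min() + 0.25 * (x.max() - x.min())
    last = max(int(np.flatnonzero(x <= cap)[-1]), 2)
    x, y = x[:last + 1], y[:last + 1]
    x = (x - x.min()) / max(x.max() - x.min(), 1e-12)
    y = (y - y.min()) / max(y.max() - y.min(), 1e-12)
    p0 = np.array([x[0], y[0]])
    chord = np.array([x[-1], y[-1]]) - p0
    chord /= max(np.linalg.norm(chord), 1e-12)
    rel = np.column_stack([x, y]) - p0
    perp = rel[:, 0] * chord[1] - rel[:, 1] * chord[0]
    return int(np.argmax(perp))


def oscillation_period(r_nm: float,
                       dipolar_constant: float = DIPOLAR_CONSTANT_MHZ_NM3) -> float:
    """Period (μs) of the perpendicular dipolar oscillation at distance r.

    A trace window should cover at least one full period for the distance to
    be well determined; windows are commonly extended for long distances.
    """
    return r_nm ** 3 / dipolar_constant


def tikhonov_invert(F: DeerTrace, r_grid: np.ndarray | None = None,
                    alpha="auto", background: BackgroundFit | None = None) -> DeerFitResult:
    """Invert a background-corrected form factor to P(r).

    Solves min ‖(K−1)q − (F−1)‖² + α²‖L₂q‖² with q ≥ 0 where q = λ·P·Δr, so
    the modulation depth λ = Σq is fitted jointly with the distribution.
    ``alpha="auto"`` picks the L-curve corner over a log-spaced ladder.
    """
    r = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    t, V = F.t, F.V
    K = dipolar_kernel(t, r)
    A = K - 1.0
    b = V - 1.0
    m = r.size
    L = _second_difference(m)
    l_scale = np.linalg.norm(A) / np.linalg.norm(L)

    def solve(a):
        aug = np.vstack([A, a * l_scale * L])
        rhs = np.concatenate([b, np.zeros(m - 2)])
        try:
            q, _ = nnls(aug, rhs, maxiter=100 * m)
        except RuntimeError as exc:
            raise SolverError(f"NNLS failed to converge at alpha={a:g}") from exc
        resid = float(np.linalg.norm(A @ q - b))
        semi = float(np.linalg.norm(L @ q))
        return q, resid, semi

    if alpha == "auto":
        ladder = _alpha_ladder()
        sols = [solve(a) for a in ladder]
        idx = _lcurve_corner(np.array([s[1] for s in sols]),
                             np.array([s[2] for s in sols]))
        alpha_used = float(ladder[idx])
        q, resid, _ = sols[idx]
    else:
        alpha_used = float(alpha)
        q, resid, _ = solve(alpha_used)

    lam = float(q.sum())
    if not 0.0 < lam < 1.0:
        raise SolverError(
            f"fitted modulation depth {lam:.3g} outside (0,1) at alpha={alpha_used:g}")
    if q.max() <= 0:
        raise SolverError("inversion returned an empty distribution")
    P = DistanceDistribution(r=r, P=q / (lam * (r[1] - r[0])))
    return DeerFitResult(P=P, alpha=alpha_used, background=background,
                         mod_depth=lam, residual_norm=resid)


def fit_deer(trace: DeerTrace, r_grid: np.ndarray | None = None,
             alpha="auto", fit_start_fraction: float = 0.35,
             dimension: float = 3.0) -> DeerFitResult:
    """Full analysis chain: background correction then Tikhonov inversion."""
    bg, F = fit_background(trace, fit_start_fraction, dimension)
    return tikhonov_invert(F, r_grid, alpha, background=bg)


def modal_distance(P: DistanceDistribution) -> float:
    """Distance at the global maximum of P; ties resolve to the smaller r."""
    if np.allclose(P.P, P.P[0]):
        warnings.warn("flat distance distribution; returning smallest maximiser")
    return float(P.r[int(np.argmax(P.P))])


def find_distribution_peaks(P: DistanceDistribution,
                            rel_height: float = 0.05,
                            edge_exclude: float = 0.3) -> np.ndarray:
    """Positions of local maxima above ``rel_height`` of the global maximum,
    after light 3-point smoothing.

    Maxima within ``edge_exclude`` nm of either grid end are dropped:
    background misfit tends to pile spurious mass against the grid
    boundaries, where distances are not determined by the data.
    """
    kern = np.ones(3) / 3.0
    sm = np.convolve(P.P, kern, mode="same")
    idx, _ = find_peaks(sm, height=rel_height * sm.max())
    if edge_exclude > 0 and idx.size:
        keep = (P.r[idx] >= P.r[0] + edge_exclude) & \
               (P.r[idx] <= P.r[-1] - edge_exclude)
        idx = idx[keep]
    if idx.size == 0:
        idx = np.array([int(np.argmax(sm))])
    return P.r[idx]


@dataclass
class PeakAssignment:
    r: float          # nm
    label: str        # AB | AC | AD | ?
    tentative: bool = False
    note: str = ""


def assign_symmetric_distances(P_dimer: DistanceDistribution,
                               P_tetramer: DistanceDistribution,
                               match_tol: float = 0.3,
                               rel_height: float = 0.05):
    """Label tetramer-condition peaks as AB (intra-dimer) or AC/AD (interface).

    Tetramer peaks within ``match_tol`` nm of a dimer-condition peak keep the
    AB label; of the remaining new peaks the shortest is AC and the longest
    AD. If only one new peak appears, AD is flagged as tentatively
    overlapping AB rather than guessed.
    """
    dimer_peaks = find_distribution_peaks(P_dimer, rel_height)
    tet_peaks = np.sort(find_distribution_peaks(P_tetramer, rel_height))
    matched = np.array([np.min(np.abs(dimer_peaks - p)) <= match_tol
                        for p in tet_peaks])
    assignments = []
    if not matched.any():
        for p in tet_peaks:
            assignments.append(PeakAssignment(
                float(p), "?", True,
                "no tetramer peak matches the dimer AB peak; AB may have shifted"))
        return assignments
    for p in tet_peaks[matched]:
        assignments.append(PeakAssignment(float(p), "AB"))
    new = tet_peaks[~matched]
    if new.size == 0:
        return assignments
    if new.size == 1:
        assignments.append(PeakAssignment(float(new[0]), "AC"))
        ab_ref = float(tet_peaks[matched][np.argmax(
            [P_tetramer.P[np.argmin(np.abs(P_tetramer.r - p))]
             for p in tet_peaks[matched]])])
        assignments.append(PeakAssignment(
            ab_ref, "AD", True, "AD unresolved; most likely overlaps AB"))
        return assignments
    assignments.append(PeakAssignment(float(new[0]), "AC"))
    assignments.append(PeakAssignment(float(new[-1]), "AD"))
    for p in new[1:-1]:
        assignments.append(PeakAssignment(
            float(p), "?", True, "extra interface peak; assignment ambiguous"))
    return assignments


# -- ASCII interchange --------------------------------------------------------

def read_trace(path) -> DeerTrace:
    """Read ``t_us V [sigma]`` columns with '#' comment lines."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    sigma = data[:, 2] if data.shape[1] > 2 else None
    return DeerTrace(data[:, 0], data[:, 1], sigma)


def write_trace(trace: DeerTrace, path, header: str = "") -> None:
    cols = [trace.t, trace.V] + ([trace.sigma] if trace.sigma is not None else [])
    np.savetxt(path, np.column_stack(cols),
               header=header + "\nt_us  V  [sigma]", comments="# ")


def read_distribution(path) -> DistanceDistribution:
    data = np.loadtxt(path, comments="#", ndmin=2)
    return DistanceDistribution(data[:, 0], data[:, 1])


def write_distribution(P: DistanceDistribution, path, header: str = "") -> None:
    np.savetxt(path, np.column_stack([P.r, P.P]),
               header=header + "\nr_nm  P", comments="# ")
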