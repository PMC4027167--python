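"""One-site saturation binding fits and sequence-based average masses.

The dimer–dimer self-association is treated as simple one-site saturation,
R(C) = Rmax·C/(Kd + C), fitted to steady-state biosensor responses; kinetic
phases are not modelled. Masses use average (not monoisotopic) residue
masses, matching solution mass measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import AlphabetError, DegenerateInputError, FitQualityError

__all__ = ["BindingIsotherm", "BindingFit", "fit_one_site", "sequence_mass",
           "read_isotherm", "write_isotherm"]


@dataclass
class BindingIsotherm:
    """Steady-state responses vs analyte concentration (μM)."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.replicates is None:
            self.replicates = np.zeros_like(self.concentrations, dtype=int)
        else:
            self.replicates = np.asarray(self.replicates, dtype=int)


@dataclass
class BindingFit:
    Kd: float                 # μM
    Rmax: float
    Kd_stderr: float
    Rmax_stderr: float
    rss: float

    def __post_init__(self):
        if not (self.Kd > 0 and self.Rmax > 0):
            raise ValueError("Kd and Rmax must be positive")

    def evaluate(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.Rmax * conc / (self.Kd + conc)


def one_site(conc, rmax, kd):
    return rmax * conc / (kd + conc)


def fit_one_site(iso: BindingIsotherm) -> BindingFit:
    """Least-squares one-site saturation fit with asymptotic standard errors.

    Starting values: Rmax = max response; Kd = concentration nearest the
    half-maximal response.
    """
    conc, resp = iso.concentrations, iso.responses
    if np.unique(conc[conc > 0]).size < 4:
        raise DegenerateInputError("need >= 4 distinct non-zero concentrations")
    rmax0 = float(resp.max())
    if rmax0 <= 0:
        raise FitQualityError("responses are non-positive; nothing to fit")
    kd0 = float(conc[np.argmin(np.abs(resp - rmax0 / 2.0))])
    kd0 = max(kd0, 1e-6)
    upper_kd = 1e4 * conc[conc > 0].max()
    try:
        popt, pcov = curve_fit(one_site, conc, resp, p0=[rmax0, kd0],
                               bounds=([1e-12, 1e-12], [np.inf, upper_kd]),
                               maxfev=10000)
    except RuntimeError as exc:
        raise FitQualityError(f"one-site fit did not converge: {exc}") from exc
    rmax, kd = popt
    if kd >= 0.99 * upper_kd:
        raise FitQualityError("Kd hit the upper bound; no saturation in data")
    perr = np.sqrt(np.diag(pcov))
    rss = float(((one_site(conc, *popt) - resp) ** 2).sum())
    return BindingFit(Kd=float(kd), Rmax=float(rmax),
                      Kd_stderr=float(perr[1]), Rmax_stderr=float(perr[0]),
                      rss=rss)


# average residue masses, Da (residue = amino acid minus water)
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153


def sequence_mass(sequence: str, n_chains: int = 1) -> float:
    """Average molecular mass in kDa of ``n_chains`` copies of ``sequence``.

    Each chain gains one water for its termini; the empty chain is a single
    water.
    """
    total = 0.0
    for letter in sequence.upper():
        if letter not in AVERAGE_RESIDUE_MASS:
            raise AlphabetError(f"unknown amino-acid letter {letter!r}")
        total += AVERAGE_RESIDUE_MASS[letter]
    return n_chains * (total + WATER_MASS) / 1000.0


def read_isotherm(path) -> BindingIsotherm:
    """Read CSV-like ASCII ``conc_uM, response, replicate`` rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line[0].isalpha():
                continue
            parts = [p.strip() for p in line.replace(",", " ").split()]
            rows.append([float(parts[0]), float(parts[1]),
                         int(float(parts[2])) if len(parts) > 2 else 0])
    arr = np.array(rows)
    return BindingIsotherm(arr[:, 0], arr[:, 1], arr[:, 2].astype(int))


def write_isotherm(iso: BindingIsotherm, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("conc_uM, response, replicate\n")
        for c, r, rep in zip(iso.concentrations, iso.responses, iso.replicates):
            fh.write(f"{c:.6g}, {r:.6g}, {int(rep)}\n")
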