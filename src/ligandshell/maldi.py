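"""Experimental MALDI-MS side: fragment masses, peak integration, synthetic
spectra, and the ligand-exchange volume calculator.

The Au4L4 fragment family of a PEG/DDT monolayer appears as five peaks,
Au4(PEG)_i(DDT)_(4-i) for i = 0..4, separated by the constant mass
difference of the two thiolates (96.22 Da with average masses).  Peak areas
integrate to the fragment distribution theta that the simulation side
produces directly, closing the experiment-simulation comparison loop.

Average atomic masses are the default: a linear-mode TOF at 5000 FWHM does
not resolve isotope structure near m/z 1600.  Ligand masses are thiolate
(M - H) masses; no cation adduct is added by default (configurable offset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "FragmentMassTable",
    "ExchangeRecipe",
    "AVERAGE_MASSES",
    "MONOISOTOPIC_MASSES",
    "AVOGADRO",
    "fragment_masses",
    "integrate_family_peaks",
    "synthesize_spectrum",
    "peg_exchange_volume",
    "analyze_spectrum",
    "read_spectrum_csv",
]

AVERAGE_MASSES = {"Au": 196.96657, "C": 12.011, "H": 1.008, "O": 15.999, "S": 32.06}
MONOISOTOPIC_MASSES = {"Au": 196.966570, "C": 12.0, "H": 1.007825,
                       "O": 15.994915, "S": 31.972071}
AVOGADRO = 6.02214076e23  # 1/mol

#: Formulae of the two thiolates (ligand minus the thiol H).
_THIOLATE_FORMULA = {
    "PEG": {"C": 4, "H": 9, "O": 1, "S": 1},   # 2-ethoxyethane-1-thiolate
    "DDT": {"C": 12, "H": 25, "S": 1},          # dodecanethiolate
}


def _formula_mass(formula: dict, masses: dict) -> float:
    return sum(n * masses[el] for el, n in formula.items())


@dataclass
class Spectrum:
    """A simple mass spectrum: strictly increasing m/z, non-negative
    intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class FragmentMassTable:
    """Masses of Au4(PEG)_i(DDT)_(4-i), i = 0..4 (Da)."""

    masses: np.ndarray  # index i = PEG count; strictly decreasing
    m_peg_thiolate: float
    m_ddt_thiolate: float
    convention: str
    adduct_offset: float = 0.0

    @property
    def spacing(self) -> float:
        """Uniform inter-peak spacing (Da)."""
        return self.m_ddt_thiolate - self.m_peg_thiolate


def fragment_masses(mass_convention: str = "average",
                    n_gold: int = 4, n_ligands: int = 4,
                    adduct_offset: float = 0.0) -> FragmentMassTable:
    """Mass table of the AuN LN binary fragment family.

    ``mass(i) = N_Au * m_Au + i * m_PEGthiolate + (N_L - i) * m_DDTthiolate``
    with thiolate = ligand molecular mass minus one hydrogen.  An optional
    adduct offset (e.g. +1.008 for [M+H]+, +22.990 for [M+Na]+) shifts every
    family mass uniformly.
    """
    masses_tbl = {"average": AVERAGE_MASSES,
                  "monoisotopic": MONOISOTOPIC_MASSES}[mass_convention]
    m_peg = _formula_mass(_THIOLATE_FORMULA["PEG"], masses_tbl)
    m_ddt = _formula_mass(_THIOLATE_FORMULA["DDT"], masses_tbl)
    i = np.arange(n_ligands + 1)
    fam = (n_gold * masses_tbl["Au"] + i * m_peg + (n_ligands - i) * m_ddt
           + adduct_offset)
    fam.setflags(write=False)
    return FragmentMassTable(fam, m_peg, m_ddt, mass_convention, adduct_offset)


def integrate_family_peaks(spectrum: Spectrum, mass_table: FragmentMassTable,
                           window: float = 10.0,
                           baseline: str | None = "median") -> np.ndarray:
    """Trapezoidal peak areas C_i in +-window/2 around each family mass.

    With ``baseline="median"`` the per-window median intensity is subtracted
    as a constant baseline (clipped at zero) before integration, the default
    for noisy experimental spectra; ``baseline=None`` integrates raw
    intensity.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window > mass_table.spacing:
        raise ValueError(
            f"window {window} Da overlaps adjacent family peaks "
            f"(spacing {mass_table.spacing:.2f} Da)")
    areas = np.zeros(len(mass_table.masses))
    for i, m0 in enumerate(mass_table.masses):
        sel = (spectrum.mz >= m0 - window / 2) & (spectrum.mz <= m0 + window / 2)
        if sel.sum() < 2:
            continue  # empty window -> area 0
        y = spectrum.intensity[sel]
        if baseline == "median":
            y = np.clip(y - np.median(y), 0.0, None)
        areas[i] = np.trapezoid(y, spectrum.mz[sel])
    return areas


def synthesize_spectrum(theta, total_area: float = 1e5,
                        resolution_fwhm: float = 5000.0,
                        noise_level: float = 0.0, seed: int | None = None,
                        mass_table: FragmentMassTable | None = None,
                        pad: float = 30.0, points_per_sigma: float = 8.0,
                        ) -> Spectrum:
    """Synthetic Au4L4 family spectrum: Gaussian peaks with areas
    proportional to theta.

    Peak widths follow the instrument resolution model
    ``FWHM_peak = m / resolution_fwhm`` (5000 FWHM by default, a linear TOF).
    ``noise_level`` adds white Gaussian noise with that standard deviation
    in absolute intensity units (a detector noise floor, so the attainable
    accuracy grows with total_area; intensities are clipped at zero).  The
    round-trip ``integrate -> normalize`` recovers theta up to
    quadrature/noise error.
    """
    from .fragments import FragmentDistribution

    th = theta.theta if isinstance(theta, FragmentDistribution) else np.asarray(theta, float)
    table = mass_table or fragment_masses()
    sigmas = table.masses / resolution_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    step = sigmas.min() / points_per_sigma
    mz = np.arange(table.masses.min() - pad, table.masses.max() + pad, step)
    intensity = np.zeros_like(mz)
    for frac, m0, s in zip(th, table.masses, sigmas):
        if frac > 0:
            intensity += (total_area * frac / (s * math.sqrt(2.0 * math.pi))
                          * np.exp(-0.5 * ((mz - m0) / s) ** 2))
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(
            intensity + rng.normal(0.0, noise_level, mz.shape), 0.0, None)
    return Spectrum(mz, intensity, {"synthetic": True,
                                    "resolution_fwhm": resolution_fwhm,
                                    "noise_level": noise_level, "seed": seed})


# ---------------------------------------------------------------------------
# Ligand-exchange volume (mole-balance interpretation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExchangeRecipe:
    """Inputs of the PEG ligand-exchange volume calculation.

    ``gamma_ddt`` is the DDT surface number density (ligands/nm^2) used in
    the per-particle mole balance; ``rho_ddt`` is retained for completeness
    but unused on the default route (see docs/methods.md).
    """

    m_dry: float  # g, dry mass of DDT-capped particles
    d_core: float  # nm, core diameter
    excess_ratio: float  # R, desired excess of added PEG per attached DDT
    m_peg: float = 106.19  # g/mol, PEG thiol
    m_ddt: float = 202.40  # g/mol, DDT thiol
    rho_peg: float = 0.93  # g/cm^3
    rho_ddt: float = 0.845  # g/cm^3 (unused by default)
    rho_au: float = 19.3  # g/cm^3
    gamma_ddt: float = 4.70  # ligands/nm^2
    n_avogadro: float = AVOGADRO

    def __post_init__(self):
        for name in ("m_dry", "d_core", "m_peg", "m_ddt", "rho_peg",
                     "rho_au", "gamma_ddt", "n_avogadro"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.excess_ratio < 0:
            raise ValueError("excess_ratio must be non-negative")

    @property
    def area_np(self) -> float:
        """Particle surface area (nm^2), spherical convention."""
        return math.pi * self.d_core**2

    @property
    def volume_np(self) -> float:
        """Particle volume (nm^3)."""
        return math.pi * self.d_core**3 / 6.0


def peg_exchange_volume(recipe: ExchangeRecipe) -> float:
    """Volume of neat PEG thiol to add for the desired exchange excess (cm^3).

    Mole balance per particle: the dry sample mass splits into gold cores
    (``V_NP * rho_Au``) and DDT shells (``A_NP * Gamma_DDT`` ligands of mass
    ``M_DDT / N_A`` each), giving the number of attached DDT in the sample;
    the added PEG volume provides ``2 R`` PEG molecules per attached DDT:

        V_PEG = 2 R * N_DDT * M_PEG / (N_A * rho_PEG)

    Linear in both R and the dry mass.
    """
    nm3_to_cm3 = 1e-21
    ddt_per_np = recipe.area_np * recipe.gamma_ddt
    mass_per_np = (recipe.volume_np * nm3_to_cm3 * recipe.rho_au
                   + ddt_per_np * recipe.m_ddt / recipe.n_avogadro)
    n_np = recipe.m_dry / mass_per_np
    n_ddt = n_np * ddt_per_np
    return (2.0 * recipe.excess_ratio * n_ddt * recipe.m_peg
            / (recipe.n_avogadro * recipe.rho_peg))


# ---------------------------------------------------------------------------
# Convenience pipeline pieces
# ---------------------------------------------------------------------------

def read_spectrum_csv(path) -> Spectrum:
    """Two-column CSV (m/z, intensity); a non-numeric header row is allowed."""
    data = np.genfromtxt(path, delimiter=",", comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    data = data[~np.isnan(data).any(axis=1)]
    order = np.argsort(data[:, 0])
    return Spectrum(data[order, 0], data[order, 1], {"path": str(path)})


def analyze_spectrum(spectrum: Spectrum, window: float = 10.0,
                     mass_convention: str = "average",
                     baseline: str | None = "median",
                     theta_sim=None) -> dict:
    """Full experimental analysis of one Au4L4 family spectrum.

    Returns peak areas, theta, the PEG surface fraction, the SSR against the
    binomial reference at that fraction and, when a simulated distribution
    is supplied, the direct experiment-simulation SSR.
    """
    from .fragments import binomial_reference, ssr, surface_fraction, theta_from_areas

    table = fragment_masses(mass_convention)
    areas = integrate_family_peaks(spectrum, table, window, baseline)
    dist = theta_from_areas(areas)
    x = surface_fraction(dist)
    out = {
        "areas": areas.tolist(),
        "theta": dist.theta.tolist(),
        "x_peg": x,
        "ssr_exp": ssr(dist, binomial_reference(x)).ssr,
    }
    if theta_sim is not None:
        out["ssr_exp_sim"] = ssr(dist, theta_sim).ssr
    return out
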