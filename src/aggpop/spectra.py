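"""Population-weighted IR band synthesis.

Per-isomer stick spectra are broadened into molar absorption curves
ε_i(ω); a lineshape is picked per mode by its *scaled* center: modes
landing in the O–H stretching window (default 3200–3650 cm⁻¹) get a
wide Gaussian (HWHM 60 cm⁻¹, standing in for the inhomogeneous
broadening of flexible aggregates), all others a Lorentzian (HWHM
10 cm⁻¹).  Harmonic intensities I (km mol⁻¹) convert to decadic molar
absorptivity through the unit-area-lineshape constant
c = 10⁵/(ln 10·10³) ≈ 43.43 L mol⁻¹ cm⁻² per km mol⁻¹.

Conformer bands are Boltzmann averages of their isomers' curves;
the total absorbance follows Beer–Lambert additivity,

    A(ω) = l Σ_n C_n Σ_α P_nα ε̄_nα(ω),

and converts to transmittance as T = 10^(−A).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KM_MOL_TO_LMOLCM2
from .core_model import IsomerRecord, PopulationTable, ThermoContext

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BroadeningConfig:
    """Lineshape selection: Gaussian inside the special region,
    Lorentzian outside (HWHMs in cm⁻¹)."""

    region: tuple[float, float] = (3200.0, 3650.0)
    gaussian_hwhm: float = 60.0
    lorentzian_hwhm: float = 10.0

    def __post_init__(self):
        if self.region[0] >= self.region[1]:
            raise ValueError("special-region bounds must be ordered")
        if self.gaussian_hwhm <= 0 or self.lorentzian_hwhm <= 0:
            raise ValueError("HWHMs must be positive")


@dataclass
class SpectrumGrid:
    """Uniform wavenumber axis with values and provenance metadata."""

    wavenumbers: np.ndarray
    values: np.ndarray
    path_length: float = 0.05  # cm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if len(self.wavenumbers) != len(self.values):
            raise ValueError("axis/value length mismatch")


def default_axis(start: float = 2800.0, stop: float = 3800.0,
                 step: float = 1.0) -> np.ndarray:
    return np.arange(start, stop + 0.5 * step, step)


def _gaussian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    sigma = hwhm / np.sqrt(2.0 * np.log(2.0))
    return np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def _lorentzian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    return hwhm / (np.pi * ((x - center) ** 2 + hwhm ** 2))


def isomer_spectrum(record: IsomerRecord, ctx: ThermoContext,
                    bc: BroadeningConfig | None = None,
                    axis: np.ndarray | None = None) -> SpectrumGrid:
    """Broadened molar absorption curve ε_i(ω) of one isomer.

    Frequencies are scaled by the spectral scale factor before band
    placement; each mode keeps a single lineshape chosen by its scaled
    center.  Modes whose band extends beyond the grid by more than
    5×HWHM trigger a truncated-area warning.
    """
    bc = bc or BroadeningConfig()
    x = default_axis() if axis is None else np.asarray(axis, dtype=float)
    eps = np.zeros_like(x)
    for nu, inten in zip(record.frequencies, record.intensities):
        if inten == 0:
            continue
        center = ctx.scale_spectra * nu
        in_region = bc.region[0] <= center <= bc.region[1]
        hwhm = bc.gaussian_hwhm if in_region else bc.lorentzian_hwhm
        if center - 5 * hwhm < x[0] or center + 5 * hwhm > x[-1]:
            if x[0] - 5 * hwhm < center < x[-1] + 5 * hwhm:
                warnings.warn(
                    f"{record.label}: band at {center:.0f} cm⁻¹ truncated by the grid",
                    stacklevel=2)
            # bands entirely outside the padded grid contribute nothing
        shape = _gaussian(x, center, hwhm) if in_region else _lorentzian(x, center, hwhm)
        eps += KM_MOL_TO_LMOLCM2 * inten * shape
    return SpectrumGrid(x, eps, metadata={
        "kind": "molar_absorption", "isomer": record.label,
        "broadening": f"G{bc.gaussian_hwhm}/{bc.region}/L{bc.lorentzian_hwhm}",
    })


def conformer_average_spectrum(spectra: list[SpectrumGrid],
                               g_values: list[float],
                               ctx: ThermoContext) -> SpectrumGrid:
    """Boltzmann-averaged conformer band ε̄_nα = Σ_i w_i ε_i with
    w_i ∝ exp(−G_i/RT), computed shift-stably."""
    if not spectra:
        raise ValueError("at least one member spectrum required")
    g = np.asarray(g_values, dtype=float)
    if len(g) != len(spectra):
        raise ValueError("one free energy per member spectrum required")
    w = np.exp(-(g - g.min()) / ctx.RT)
    w /= w.sum()
    vals = sum(wi * s.values for wi, s in zip(w, spectra))
    return SpectrumGrid(spectra[0].wavenumbers.copy(), vals,
                        metadata={"kind": "conformer_average",
                                  "weights": [float(x) for x in w]})


def total_absorbance(conformer_spectra: dict[tuple[int, str], SpectrumGrid],
                     populations: PopulationTable,
                     concentrations: dict[int, float],
                     path_length: float = 0.05) -> SpectrumGrid:
    """Beer–Lambert total: A(ω) = l Σ_n C_n Σ_α P_nα ε̄_nα(ω).

    Works with either route's PopulationTable; every populated (n, α)
    needs a matching conformer spectrum.
    """
    missing = [
        (n, a) for n, pops in populations.populations.items()
        for a in pops if (n, a) not in conformer_spectra
    ]
    if missing:
        raise KeyError(f"no conformer spectrum for patterns: {missing}")
    axis = None
    total = None
    for (n, a), grid in conformer_spectra.items():
        p = populations.populations.get(n, {}).get(a, 0.0)
        c = concentrations.get(n, 0.0)
        if axis is None:
            axis = grid.wavenumbers
            total = np.zeros_like(axis)
        total += path_length * c * p * grid.values
    return SpectrumGrid(axis, total, path_length,
                        metadata={"kind": "absorbance",
                                  "provenance": populations.provenance,
                                  "path_length_cm": path_length})


def to_transmittance(grid: SpectrumGrid) -> SpectrumGrid:
    """Decadic transmittance T = 10^(−A)."""
    if np.any(grid.values < 0):
        raise ValueError("absorbance must be nonnegative")
    meta = dict(grid.metadata)
    meta["kind"] = "transmittance"
    return SpectrumGrid(grid.wavenumbers.copy(), 10.0 ** (-grid.values),
                        grid.path_length, meta)


def spectra_route(records: list[IsomerRecord], populations: PopulationTable,
                  concentrations: dict[int, float],
                  ctx: ThermoContext | None = None,
                  bc: BroadeningConfig | None = None,
                  axis: np.ndarray | None = None,
                  path_length: float = 0.05):
    """End-to-end band synthesis from an isomer table.

    Returns (absorbance grid, transmittance grid, conformer spectra).
    Monomer records enter as the pattern "monomer" with population 1.
    """
    from .qs_thermo import isomer_free_energy

    ctx = ctx or ThermoContext()
    by_pattern: dict[tuple[int, str], list[IsomerRecord]] = {}
    for r in records:
        by_pattern.setdefault((r.size, r.pattern or "monomer"), []).append(r)
    conformers = {}
    for key, members in by_pattern.items():
        specs = [isomer_spectrum(r, ctx, bc, axis) for r in members]
        gs = [isomer_free_energy(r, ctx) for r in members]
        conformers[key] = conformer_average_spectrum(specs, gs, ctx)
    # fold the monomer in as its own "pattern" of population one
    pops = {n: dict(p) for n, p in populations.populations.items()}
    if (1, "monomer") in conformers:
        pops[1] = {"monomer": 1.0}
    table = PopulationTable(populations.provenance, pops,
                            populations.concentrations, populations.c_total)
    absorb = total_absorbance(conformers, table, concentrations, path_length)
    return absorb, to_transmittance(absorb), conformers
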