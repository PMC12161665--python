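"""Quantum/static route: quasi-RRHO thermochemistry, multi-well
conformer free energies, Boltzmann populations and self-association
constants.

The standard-state solution free energy of one optimized isomer is

    G*_i = E_elec + ΔG_solv + δG*_VRT + RT ln(M_solv C° / 1000 ρ_solv)

with δG*_VRT = δG°_VRT + RT ln(RT/p°) — the vibrational–rotational–
translational gas-phase contribution (referenced to the ground state,
i.e. including the ZPE) shifted from the ideal-gas p° reference to the
1 mol L⁻¹ standard state.  Low-frequency vibrational entropy follows
Grimme's damped rigid-rotor interpolation: each mode's entropy is
w·S_HO + (1−w)·S_FR with w(ν) = 1/(1 + (ν₀/ν)⁴); ZPE and thermal
energy stay harmonic.

A conformer (interaction pattern) collecting several isomers gets the
multi-well free energy

    G({X}) = G(X_ref) − RT ln Σ_i m_i exp(−ΔG(X_i)/RT),

independent of the reference choice; pattern populations are the
Boltzmann fractions of these G's within one aggregate size, and the
size-n self-association constant is K_n = exp(−(G_n − n·G₁)/RT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AMU_KG, C_CM, H_PLANCK, HC_KCAL_CM, K_B, R_KCAL, R_LBAR
from .core_model import IsomerRecord, PopulationTable, ThermoContext


def _theta(freqs_cm: np.ndarray, T: float) -> np.ndarray:
    """hcν/kT, dimensionless."""
    return HC_KCAL_CM * freqs_cm / (R_KCAL * T)


def vib_thermo(frequencies: np.ndarray, ctx: ThermoContext,
               scaled: bool = False) -> tuple[float, float, float]:
    """(ZPE, vibrational free-energy contribution, entropy) of a mode set.

    Returns kcal mol⁻¹ for the energies and cal mol⁻¹ K⁻¹ for the
    entropy.  The thermal scale factor is applied here unless the
    caller passes ``scaled=True``.  The free-energy contribution is
    ZPE + E_thermal − T·S with the quasi-RRHO entropy, so it reduces to
    the harmonic ZPE + RT Σ ln(1−e^(−hcν/kT)) when every ν ≫ ν₀.
    """
    nu = np.asarray(frequencies, dtype=float)
    if nu.size == 0:
        return 0.0, 0.0, 0.0
    if np.any(nu <= 0):
        raise ValueError("vibrational frequencies must be positive")
    if not scaled:
        nu = nu * ctx.scale_thermal
    T = ctx.temperature
    th = _theta(nu, T)
    zpe = float(np.sum(HC_KCAL_CM * nu / 2.0))
    expm = np.expm1(th)           # e^θ − 1
    e_thermal = R_KCAL * T * np.sum(th / expm)
    # harmonic-oscillator entropy per mode (cal/mol/K via R in kcal)
    s_ho = R_KCAL * (th / expm - np.log1p(-np.exp(-th)))
    # free-rotor entropy of the mode's effective rotor (Grimme)
    mu = H_PLANCK / (8.0 * np.pi ** 2 * C_CM * nu)           # kg m²
    b_av = 1e-44
    mu_p = mu * b_av / (mu + b_av)
    q_fr = np.sqrt(8.0 * np.pi ** 3 * mu_p * K_B * T) / H_PLANCK
    s_fr = R_KCAL * (0.5 + np.log(q_fr))
    w = 1.0 / (1.0 + (ctx.nu0_rrho / nu) ** 4)
    s = w * s_ho + (1.0 - w) * s_fr                          # kcal/mol/K
    s_total = float(np.sum(s))
    g_vib = zpe + float(e_thermal) - T * s_total
    return zpe, g_vib, s_total * 1000.0  # entropy in cal/mol/K


def principal_moments(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Principal moments of inertia (amu Å²) from geometry and masses."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * coords).sum(0) / masses.sum()
    r = coords - com
    r2 = (r ** 2).sum(1)
    inertia = np.zeros((3, 3))
    for k in range(3):
        inertia[k, k] = np.sum(masses * (r2 - r[:, k] ** 2))
    for a in range(3):
        for b in range(a + 1, 3):
            inertia[a, b] = inertia[b, a] = -np.sum(masses * r[:, a] * r[:, b])
    return np.sort(np.linalg.eigvalsh(inertia))


def rot_trans_thermo(record: IsomerRecord, ctx: ThermoContext) -> tuple[float, float]:
    """(G_rot, G_trans) in kcal mol⁻¹ at T and p°.

    Classical rigid rotor with symmetry number σ (linear species use
    the single nonzero moment); ideal-gas translation, for which
    G = −RT ln q with q = (2πmkT/h²)^{3/2} kT/p°.
    """
    T = ctx.temperature
    RT = ctx.RT
    if record.mass <= 0:
        raise ValueError(f"{record.label}: positive mass required")
    m_kg = record.mass * AMU_KG
    p_pa = ctx.p_standard * 1e5
    q_trans = (2.0 * np.pi * m_kg * K_B * T / H_PLANCK ** 2) ** 1.5 * K_B * T / p_pa
    g_trans = -RT * np.log(q_trans)

    if record.inertia is None:
        if record.size > 1:
            raise ValueError(f"{record.label}: moments of inertia required")
        return 0.0, float(g_trans)
    mom = np.asarray(record.inertia, dtype=float) * AMU_KG * 1e-20  # kg m²
    nonzero = mom[mom > 1e-60]
    if nonzero.size == 0:
        if record.size > 1:
            raise ValueError(f"{record.label}: zero inertia for an aggregate")
        return 0.0, float(g_trans)
    if nonzero.size == 1:  # linear rotor
        q_rot = 8.0 * np.pi ** 2 * nonzero[0] * K_B * T / (record.sigma * H_PLANCK ** 2)
    else:
        prod = np.prod(nonzero[-3:]) if nonzero.size >= 3 else np.prod(nonzero)
        q_rot = (np.sqrt(np.pi) / record.sigma
                 * (8.0 * np.pi ** 2 * K_B * T / H_PLANCK ** 2) ** 1.5
                 * np.sqrt(prod))
    g_rot = -RT * np.log(q_rot)
    return float(g_rot), float(g_trans)


def standard_state_terms(ctx: ThermoContext) -> tuple[float, float]:
    """(gas→1 M correction, solvent density term) in kcal mol⁻¹.

    The first is RT ln(RT·C°/p°) with R in L·bar mol⁻¹ K⁻¹ — the free
    energy of compressing the ideal-gas reference at p° to 1 mol L⁻¹;
    1.89 kcal mol⁻¹ under the defaults at 298.15 K.  The second is
    RT ln(M_solv C° / 1000 ρ_solv) with M in g mol⁻¹ and ρ in g cm⁻³.
    """
    if ctx.rho_solvent <= 0:
        raise ValueError("solvent density must be positive")
    RT = ctx.RT
    corr1 = RT * np.log(R_LBAR * ctx.temperature * ctx.c_standard / ctx.p_standard)
    corr2 = RT * np.log(ctx.m_solvent * ctx.c_standard / (1000.0 * ctx.rho_solvent))
    return float(corr1), float(corr2)


def isomer_free_energy(record: IsomerRecord, ctx: ThermoContext) -> float:
    """Standard-state (1 mol L⁻¹) solution free energy G*_i of one isomer."""
    zpe, g_vib, _ = vib_thermo(record.frequencies, ctx)
    g_rot, g_trans = rot_trans_thermo(record, ctx) if record.mass > 0 else (0.0, 0.0)
    corr1, corr2 = standard_state_terms(ctx)
    return record.e_elec + record.dg_solv + g_vib + g_rot + g_trans + corr1 + corr2


@dataclass
class PatternFreeEnergy:
    """Multi-well free energy of one interaction pattern."""

    size: int
    pattern: str
    members: tuple[str, ...]
    g: float            # kcal/mol
    x_ref: str

    def __post_init__(self):
        if not self.members:
            raise ValueError("a pattern needs at least one member isomer")


def multiwell_free_energy(members: list[IsomerRecord], ctx: ThermoContext,
                          g_values: dict[str, float] | None = None,
                          x_ref: str | None = None) -> PatternFreeEnergy:
    """Free energy of the equilibrated mixture of a pattern's isomers.

    G = G(X_ref) − RT ln Σ_i m_i exp(−(G_i − G(X_ref))/RT); the choice
    of X_ref cancels identically.  Per-isomer G*_i are computed via
    :func:`isomer_free_energy` unless supplied in ``g_values``.
    """
    if not members:
        raise ValueError("empty member set")
    gs = {r.label: (g_values[r.label] if g_values else isomer_free_energy(r, ctx))
          for r in members}
    if x_ref is None:
        x_ref = min(gs, key=gs.get)
    RT = ctx.RT
    g_ref = gs[x_ref]
    z = sum(r.degeneracy * np.exp(-(gs[r.label] - g_ref) / RT) for r in members)
    g = g_ref - RT * np.log(z)
    sizes = {r.size for r in members}
    if len(sizes) != 1:
        raise ValueError("members span several aggregate sizes")
    pattern = members[0].pattern or "?"
    return PatternFreeEnergy(sizes.pop(), pattern,
                             tuple(r.label for r in members), float(g), x_ref)


def qs_pattern_populations(free_energies: list[PatternFreeEnergy],
                           ctx: ThermoContext) -> PopulationTable:
    """Boltzmann pattern populations P_nα within each aggregate size.

    Computed shift-stably (minimum G subtracted before
    exponentiation).
    """
    RT = ctx.RT
    by_size: dict[int, list[PatternFreeEnergy]] = {}
    for pfe in free_energies:
        by_size.setdefault(pfe.size, []).append(pfe)
    pops: dict[int, dict[str, float]] = {}
    for n, group in sorted(by_size.items()):
        gs = np.array([p.g for p in group])
        w = np.exp(-(gs - gs.min()) / RT)
        w /= w.sum()
        pops[n] = {p.pattern: float(x) for p, x in zip(group, w)}
    return PopulationTable("Q/s", pops)


def qs_equilibrium_constant(g_n: float, g_1: float, n: int,
                            ctx: ThermoContext) -> float:
    """K_n = exp(−ΔG_n/RT) with ΔG_n = G_n − n·G₁ (1 mol L⁻¹ state)."""
    dg = g_n - n * g_1
    return float(np.exp(-dg / ctx.RT))


def qs_route(records: list[IsomerRecord], ctx: ThermoContext | None = None):
    """Full Q/s pipeline from an isomer table.

    Groups isomers by (size, pattern), evaluates the multi-well G per
    pattern and per size (all size-n isomers pooled), and returns
    (PopulationTable, {n: K_n}, list of PatternFreeEnergy).
    """
    ctx = ctx or ThermoContext()
    by_pattern: dict[tuple[int, str], list[IsomerRecord]] = {}
    by_size: dict[int, list[IsomerRecord]] = {}
    for r in records:
        if r.pattern is None and r.size > 1:
            raise ValueError(f"{r.label}: pattern label required for aggregates")
        by_pattern.setdefault((r.size, r.pattern or "monomer"), []).append(r)
        by_size.setdefault(r.size, []).append(r)
    pattern_fes = [multiwell_free_energy(m, ctx)
                   for (n, _), m in sorted(by_pattern.items()) if n > 1]
    table = qs_pattern_populations(pattern_fes, ctx)
    if 1 not in by_size:
        raise ValueError("monomer records required for equilibrium constants")
    g_size = {n: multiwell_free_energy(m, ctx).g for n, m in by_size.items()}
    ks = {n: qs_equilibrium_constant(g_size[n], g_size[1], n, ctx)
          for n in sorted(g_size) if n > 1}
    return table, ks, pattern_fes
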