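"""Classical/dynamic route: populations and equilibria from snapshot
counting.

Per-frame aggregate counts N_nαj in a box of volume V_j give mean
concentrations

    ⟨C_nα⟩ = (1/N_steps) Σ_j N_nαj / (V_j N_A),

pattern populations P_nα = ⟨C_nα⟩ / Σ_α ⟨C_nα⟩, and self-association
constants K_n = ⟨C_n⟩ (C°)^(n−1) / ⟨C₁⟩ⁿ at the 1 mol L⁻¹ standard
state.  The reported species concentrations are then re-derived from
the monomer–dimer–trimer–tetramer equilibrium model: the monomer
concentration is the unique positive root of

    C₁ + 2K₂C₁² + 3K₃C₁³ + 4K₄C₁⁴ = C₀,

with C_n = K_n C₁ⁿ, so that mass balance Σ n·C_n = C₀ holds exactly.
Uncertainties use block averaging over frames (default 10 blocks) to
respect trajectory autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import N_AVOGADRO
from .core_model import PopulationTable, ThermoContext


@dataclass
class FrameCounts:
    """Per-frame (size, pattern) aggregate counts and frame volumes.

    ``counts[j]`` maps (n, pattern) → N_nαj for frame j; ``volumes``
    are the frame volumes V_j in litres.  ``oversize`` counts
    aggregates beyond n_max per frame (tallied, excluded from the
    model).
    """

    counts: list[dict[tuple[int, str], int]]
    volumes: np.ndarray
    oversize: list[int] = field(default_factory=list)
    n_max: int = 4

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.counts) != len(self.volumes):
            raise ValueError("one volume per frame required")
        if len(self.counts) < 1:
            raise ValueError("at least one frame required")
        if np.any(self.volumes <= 0):
            raise ValueError("frame volumes must be positive")
        if not self.oversize:
            self.oversize = [0] * len(self.counts)

    @property
    def n_steps(self) -> int:
        return len(self.counts)

    @classmethod
    def from_frames(cls, frames, specs, criteria=None, catalog=None,
                    n_max: int = 4) -> "FrameCounts":
        """Run the detection/classification pipeline over frames."""
        from .aggregate_graphs import classify_frame

        counts, vols, over = [], [], []
        for fr in frames:
            aggs, _ = classify_frame(fr, specs, criteria, catalog)
            c: dict[tuple[int, str], int] = {}
            ov = 0
            for _, n, pattern in aggs:
                if n > n_max:
                    ov += 1
                    continue
                key = (n, pattern if pattern is not None else "monomer")
                c[key] = c.get(key, 0) + 1
            counts.append(c)
            vols.append(fr.volume_L)
            over.append(ov)
        return cls(counts, np.array(vols), over, n_max)

    def per_frame_concentrations(self) -> tuple[list[tuple[int, str]], np.ndarray]:
        """(keys, matrix) with matrix[j, k] = N_nαj/(V_j N_A) in mol/L."""
        keys = sorted({k for c in self.counts for k in c})
        mat = np.zeros((self.n_steps, len(keys)))
        for j, c in enumerate(self.counts):
            for k, v in c.items():
                mat[j, keys.index(k)] = v / (self.volumes[j] * N_AVOGADRO)
        return keys, mat


def average_concentrations(counts: FrameCounts):
    """Mean concentrations ⟨C_nα⟩ over frames, with per-size totals and
    block-averaged standard errors.

    Returns (mean_by_key, size_totals, se_by_key) where mean_by_key maps
    (n, pattern) → ⟨C_nα⟩ in mol/L and size_totals maps n → ⟨C_n⟩.
    """
    keys, mat = counts.per_frame_concentrations()
    means = mat.mean(axis=0)
    se = standard_error_blocks(mat)
    mean_by_key = {k: float(m) for k, m in zip(keys, means)}
    se_by_key = {k: float(s) for k, s in zip(keys, se)}
    size_totals: dict[int, float] = {}
    for (n, _), m in mean_by_key.items():
        size_totals[n] = size_totals.get(n, 0.0) + m
    return mean_by_key, size_totals, se_by_key


def standard_error_blocks(series: np.ndarray, n_blocks: int = 10) -> np.ndarray:
    """Standard error of the mean via block averaging along axis 0."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.ndim == 1:
        series = series[:, None]
    n = series.shape[0]
    nb = min(n_blocks, n)
    edges = np.linspace(0, n, nb + 1, dtype=int)
    blocks = np.array([series[a:b].mean(axis=0) for a, b in zip(edges, edges[1:])])
    if nb < 2:
        return np.zeros(series.shape[1])
    return blocks.std(axis=0, ddof=1) / np.sqrt(nb)


def cd_pattern_populations(mean_by_key: dict[tuple[int, str], float],
                           concentrations: dict[int, float] | None = None,
                           c_total: float | None = None) -> PopulationTable:
    """Pattern populations P_nα = ⟨C_nα⟩ / Σ_α ⟨C_nα⟩ per size.

    Sizes with zero total concentration are absent from the result (the
    population is undefined there, not zero).  Monomers carry no
    pattern and are skipped.
    """
    pops: dict[int, dict[str, float]] = {}
    totals: dict[int, float] = {}
    for (n, _), m in mean_by_key.items():
        totals[n] = totals.get(n, 0.0) + m
    for (n, a), m in mean_by_key.items():
        if n == 1 or totals[n] <= 0:
            continue
        pops.setdefault(n, {})[a] = m / totals[n]
    return PopulationTable("C/d", {n: pops[n] for n in sorted(pops)},
                           concentrations or {}, c_total)


def cd_equilibrium_constants(size_totals: dict[int, float],
                             ctx: ThermoContext | None = None,
                             n_max: int = 4) -> dict[int, float]:
    """Self-association constants K_n = ⟨C_n⟩ (C°)^(n−1) / ⟨C₁⟩ⁿ.

    Dimensionless under the C° = 1 mol L⁻¹ convention.  Requires a
    nonzero monomer concentration.
    """
    c_std = (ctx or ThermoContext()).c_standard
    c1 = size_totals.get(1, 0.0)
    if c1 <= 0:
        raise ValueError("no monomer observed; K_n undefined")
    return {n: size_totals.get(n, 0.0) * c_std ** (n - 1) / c1 ** n
            for n in range(2, n_max + 1)}


@dataclass
class EquilibriumModel:
    """Solved monomer–…–n_max-mer self-association equilibrium."""

    constants: dict[int, float]     # K_n, n = 2..n_max
    c_total: float                  # C₀, mol/L
    concentrations: dict[int, float]  # C_1..C_nmax, mol/L

    def __post_init__(self):
        if any(k < 0 for k in self.constants.values()):
            raise ValueError("K_n must be nonnegative")
        balance = sum(n * c for n, c in self.concentrations.items())
        if abs(balance - self.c_total) > 1e-9 * max(self.c_total, 1e-300):
            raise ValueError(
                f"mass balance violated: Σ n·C_n = {balance}, C₀ = {self.c_total}")


def solve_equilibrium(constants: dict[int, float], c_total: float) -> EquilibriumModel:
    """Solve mass balance + self-association equilibria for C₁..C_nmax.

    f(C₁) = Σ_n n K_n C₁ⁿ − C₀ is strictly increasing on [0, C₀] with
    f(0) < 0 ≤ f(C₀), so the bracketed root is unique; C_n = K_n C₁ⁿ.
    """
    if c_total <= 0:
        raise ValueError("C₀ must be positive")
    ks = dict(constants)
    n_max = max(ks) if ks else 1

    def f(c1):
        return c1 + sum(n * ks.get(n, 0.0) * c1 ** n for n in range(2, n_max + 1)) - c_total

    if all(v == 0 for v in ks.values()):
        c1 = c_total
    else:
        c1 = brentq(f, 0.0, c_total, xtol=1e-300, rtol=1e-15, maxiter=200)
        # polish with one Newton step for the 1e-10 relative residual contract
        for _ in range(3):
            fp = 1 + sum(n * n * ks.get(n, 0.0) * c1 ** (n - 1)
                         for n in range(2, n_max + 1))
            c1 -= f(c1) / fp
    conc = {1: c1}
    for n in range(2, n_max + 1):
        conc[n] = ks.get(n, 0.0) * c1 ** n
    # absorb the residual rounding into the monomer so Σ n·C_n = C₀ holds
    conc[1] += c_total - sum(n * c for n, c in conc.items())
    return EquilibriumModel(ks, c_total, conc)


def cd_route(counts: FrameCounts, c_total: float | None = None,
             ctx: ThermoContext | None = None):
    """Full C/d pipeline: averages → populations → K_n → equilibrium
    re-solve.

    When ``c_total`` is omitted it is taken from the observed mass
    Σ n ⟨C_n⟩ (the ≤ n_max truncation of the stoichiometric loading).
    Returns (PopulationTable, EquilibriumModel, raw size averages).
    """
    mean_by_key, size_totals, _ = average_concentrations(counts)
    ks = cd_equilibrium_constants(size_totals, ctx, counts.n_max)
    if c_total is None:
        c_total = sum(n * c for n, c in size_totals.items())
    model = solve_equilibrium(ks, c_total)
    table = cd_pattern_populations(mean_by_key, model.concentrations, c_total)
    return table, model, size_totals
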