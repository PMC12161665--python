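"""Synthetic inputs with known ground truth.

Three generators make every pipeline stage testable without external
data:

* :func:`generate_scene` — snapshots containing rigid phenol-like
  aggregates planted from validated geometric templates (one per
  catalog pattern), plus monomers and inert solvent particles.  The
  detection/classification pipeline applied to a generated scene
  recovers exactly the planted composition.
* :func:`generate_isomer_table` — thermochemistry records whose
  Boltzmann populations equal a closed-form expression of the
  configured free-energy offsets and degeneracies.
* :func:`generate_equilibrium_trajectory` — frame sequences whose
  per-frame aggregate counts are Poisson draws around the
  concentrations of a prescribed self-association equilibrium, for
  end-to-end recovery of the K_n.

Templates are idealized rigid placements (not energy minima): designed
H-bond contacts sit at O···H ≈ 2.0 Å / 180°, π stacks at 3.5 Å and
O–H···π approaches at 2.8 Å / 150°, with every *non*-planted contact
clearing its cutoff by a safety margin so the default 0.05 Å jitter
cannot change the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .aggregate_graphs import OHPI_LABEL, PIPI_LABEL, PatternCatalog, classify_frame
from .constants import N_AVOGADRO
from .core_model import Frame, IsomerRecord, MoleculeSpec, phenol_spec, solvent_spec

# ---------------------------------------------------------------------------
# Rigid phenol geometry (local frame: ring in xy-plane, centroid at origin)

_RING_R = 1.39      # C radius, Å
_RINGH_R = 2.47     # ring-H radius, Å
_CO = 1.36          # C-O bond, Å
_OH = 0.98          # O-H bond, Å
_COH_ANGLE = 109.5  # deg

_HB_OO = 3.0        # designed O(donor)–O(acceptor) separation → O···H ≈ 2.02 Å
_PI_STACK = 3.5     # ring-centroid stacking distance, Å
_OHPI_D = 2.8       # H···centroid approach, Å
_OHPI_ANGLE = 150.0  # O–H···centroid angle, deg


def phenol_template() -> np.ndarray:
    """Local-frame coordinates, atom order matching :func:`phenol_spec`."""
    ang = np.radians(60.0 * np.arange(6))
    carbons = np.stack([_RING_R * np.cos(ang), _RING_R * np.sin(ang),
                        np.zeros(6)], axis=1)
    ring_h = np.stack([_RINGH_R * np.cos(ang[1:]), _RINGH_R * np.sin(ang[1:]),
                       np.zeros(5)], axis=1)
    o = np.array([_RING_R + _CO, 0.0, 0.0])
    a = np.radians(180.0 - _COH_ANGLE)
    h = o + _OH * np.array([np.cos(a), np.sin(a), 0.0])
    return np.vstack([carbons, ring_h, o, h])


_LOCAL = phenol_template()
_LOCAL_O = _LOCAL[11]
_LOCAL_H = _LOCAL[12]
_LOCAL_U = (_LOCAL_H - _LOCAL_O) / np.linalg.norm(_LOCAL_H - _LOCAL_O)  # O→H dir
_LOCAL_OC = -_LOCAL_O / np.linalg.norm(_LOCAL_O)                        # O→centroid


def _frame_from_pair(e1, e2_hint):
    """Right-handed orthonormal frame with first axis e1."""
    e1 = np.asarray(e1, float) / np.linalg.norm(e1)
    h = np.asarray(e2_hint, float)
    e2 = h - np.dot(h, e1) * e1
    n = np.linalg.norm(e2)
    if n < 1e-8:
        raise ValueError("orientation hint parallel to the primary axis")
    e2 /= n
    return np.stack([e1, e2, np.cross(e1, e2)])


def place_molecule(o_pos, oh_dir, ring_hint) -> np.ndarray:
    """Rigid phenol with its O at ``o_pos``, O–H bond along ``oh_dir``
    and the ring body on the ``ring_hint`` side of the hydroxyl."""
    local = _frame_from_pair(_LOCAL_U, _LOCAL_OC)
    target = _frame_from_pair(oh_dir, ring_hint)
    rot = target.T @ local
    return (_LOCAL - _LOCAL_O) @ rot.T + np.asarray(o_pos, float)


def _molecule_from_ring(centroid, normal, o_dir) -> np.ndarray:
    """Rigid phenol by ring placement: centroid, plane normal and the
    in-plane centroid→O direction."""
    local = _frame_from_pair(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    target = _frame_from_pair(normal, o_dir)
    rot = target.T @ local
    return _LOCAL @ rot.T + np.asarray(centroid, float)


class _Mol:
    """Bookkeeping for one placed molecule while building a template."""

    __slots__ = ("coords",)

    def __init__(self, coords):
        self.coords = coords

    @property
    def o(self):
        return self.coords[11]

    @property
    def h(self):
        return self.coords[12]

    @property
    def u(self):
        return (self.h - self.o) / np.linalg.norm(self.h - self.o)

    @property
    def centroid(self):
        return self.coords[:6].mean(0)

    @property
    def normal(self):
        v1 = self.coords[1] - self.coords[0]
        v2 = self.coords[2] - self.coords[0]
        n = np.cross(v1, v2)
        return n / np.linalg.norm(n)


def _hb_network(o_positions, donations, free_dirs, hints):
    """Molecules from an O-position layout.

    ``donations`` maps donor index → acceptor index (each hydroxyl
    donates at most once); non-donors aim their free O–H along
    ``free_dirs``; ``hints`` set the ring side per molecule.
    """
    mols = []
    for m, o in enumerate(o_positions):
        if m in donations:
            acc = o_positions[donations[m]]
            oh = (np.asarray(acc) - np.asarray(o))
            oh = oh / np.linalg.norm(oh)
        else:
            oh = np.asarray(free_dirs[m], float)
            oh = oh / np.linalg.norm(oh)
        mols.append(_Mol(place_molecule(o, oh, hints[m])))
    return mols


def _stack_on(mol: _Mol, direction: float = 1.0) -> _Mol:
    """π-stacked translated copy along the ring normal."""
    return _Mol(mol.coords + direction * _PI_STACK * mol.normal)


def _ohpi_attach(mol: _Mol) -> _Mol:
    """Acceptor ring placed against the donor's free hydroxyl proton."""
    u, n = mol.u, mol.normal
    a = np.radians(180.0 - _OHPI_ANGLE)
    w = np.cos(a) * u + np.sin(a) * n
    centroid = mol.h + _OHPI_D * w
    away = centroid - mol.centroid
    away = away - np.dot(away, w) * w
    away = away / np.linalg.norm(away)
    return _Mol(_molecule_from_ring(centroid, w, away))


_Z = np.array([0.0, 0.0, 1.0])


def _template_molecules(size: int, pattern: str) -> list[_Mol]:  # noqa: C901
    """Rigid template for one catalog pattern."""
    alt = [_Z, -_Z, _Z, -_Z]

    if size == 1:
        return [_Mol(_LOCAL.copy())]

    if pattern == PIPI_LABEL:
        base = _Mol(_LOCAL.copy())
        mols = [base]
        for k in range(1, size):
            mols.append(_Mol(base.coords - k * _PI_STACK * base.normal))
        return mols

    if pattern == OHPI_LABEL:
        base = _Mol(_LOCAL.copy())
        mols = [base]
        for k in range(1, size - 1):
            mols.append(_Mol(base.coords - k * _PI_STACK * base.normal))
        mols.append(_ohpi_attach(base))
        return mols

    def O(*xyz):
        return np.array(xyz, float)

    if size == 2:  # "OH-bonded"
        return _hb_network(
            [O(0, 0, 0), O(_HB_OO, 0, 0)], {0: 1},
            {1: O(0.333, 0.943, 0)}, [O(0, 0, -1), O(0, 0, 1)])

    if size == 3:
        if pattern == "dimer-like":
            mols = _hb_network(
                [O(0, 0, 0), O(_HB_OO, 0, 0)], {0: 1},
                {1: O(0.333, 0.943, 0)}, [_Z, -_Z])
            return mols + [_stack_on(mols[0], -1.0)]
        if pattern == "linear":
            return _hb_network(
                [O(0, 0, 0), O(_HB_OO, 0, 0), O(1.5 * _HB_OO, 0.866 * _HB_OO, 0)],
                {0: 1, 1: 2}, {2: O(0.5, 0.866, 0)}, alt)
        if pattern == "cyclic":
            tri = [O(0, 0, 0), O(_HB_OO, 0, 0), O(0.5 * _HB_OO, 0.866 * _HB_OO, 0)]
            return _hb_network(tri, {0: 1, 1: 2, 2: 0}, {}, alt)

    if size == 4:
        s = _HB_OO
        if pattern == "dimer-like":
            mols = _hb_network(
                [O(0, 0, 0), O(s, 0, 0)], {0: 1},
                {1: O(0.333, 0.943, 0)}, [_Z, -_Z])
            third = _stack_on(mols[0], -1.0)
            return mols + [third, _stack_on(third, -1.0)]
        if pattern == "two-dimers":
            mols = _hb_network(
                [O(0, 0, 0), O(s, 0, 0)], {0: 1},
                {1: O(0.333, 0.943, 0)}, [_Z, -_Z])
            m2 = _stack_on(mols[1], 1.0)
            u2 = m2.u
            o3 = m2.h + (_HB_OO - _OH) * u2
            m3 = _Mol(place_molecule(o3, u2, m2.normal))
            return mols + [m2, m3]
        if pattern == "trimer-like":
            mols = _hb_network(
                [O(0, 0, 0), O(s, 0, 0), O(1.5 * s, 0.866 * s, 0)],
                {0: 1, 1: 2}, {2: O(0.5, 0.866, 0)}, alt)
            return mols + [_stack_on(mols[0], 1.0)]
        if pattern == "linear":
            return _hb_network(
                [O(0, 0, 0), O(s, 0, 0), O(1.5 * s, 0.866 * s, 0),
                 O(2.5 * s, 0.866 * s, 0)],
                {0: 1, 1: 2, 2: 3}, {3: O(0.5, 0.866, 0)}, alt)
        if pattern == "branched":
            return _hb_network(
                [O(0, 0, 0), O(s, 0, 0), O(-0.5 * s, 0.866 * s, 0),
                 O(-0.5 * s, -0.866 * s, 0)],
                {1: 0, 2: 0, 3: 0}, {0: _Z},
                [O(-1, 0, 0), -_Z, -_Z, -_Z])
        if pattern == "cyclic-trimer":
            tri = [O(0, 0, 0), O(s, 0, 0), O(0.5 * s, 0.866 * s, 0)]
            mols = _hb_network(tri, {0: 1, 1: 2, 2: 0}, {}, alt)
            return mols + [_stack_on(mols[0], 1.0)]
        if pattern == "cyclic":
            sq = [O(0, 0, 0), O(s, 0, 0), O(s, s, 0), O(0, s, 0)]
            return _hb_network(sq, {0: 1, 1: 2, 2: 3, 3: 0}, {}, alt)
        if pattern == "tadpole":
            tri = [O(0, 0, 0), O(s, 0, 0), O(0.5 * s, 0.866 * s, 0)]
            center = O(0.5 * s, 0.289 * s, 0)
            away = (tri[0] - center) / np.linalg.norm(tri[0] - center)
            w = away + O(0, 0, 0.8)
            w /= np.linalg.norm(w)
            o3 = tri[0] + s * w
            mols = _hb_network(tri, {0: 1, 1: 2, 2: 0}, {}, alt)
            mols.append(_Mol(place_molecule(o3, -w, _Z)))
            return mols

    raise KeyError(f"no template for size {size} pattern {pattern!r}")


def template_coordinates(size: int, pattern: str | None) -> np.ndarray:
    """(size·13, 3) coordinate block of one planted aggregate, centered."""
    mols = _template_molecules(size, pattern or "monomer")
    coords = np.vstack([m.coords for m in mols])
    return coords - coords.mean(0)


@lru_cache(maxsize=None)
def _validated(size: int, pattern: str | None) -> bool:
    """Build-time check: the template alone classifies as designed."""
    coords = template_coordinates(size, pattern)
    spec = phenol_spec()
    box = np.full(3, 200.0)
    frame = Frame(0, coords + 100.0, box,
                  np.repeat(np.arange(size), 13), ["phenol"] * size)
    aggs, hist = classify_frame(frame, {"phenol": spec})
    if hist != {size: 1}:
        raise AssertionError(
            f"template ({size}, {pattern}): pipeline found sizes {hist}")
    got = aggs[0][2]
    want = None if size == 1 else pattern
    if got != want:
        raise AssertionError(
            f"template ({size}, {pattern}): classified as {got!r}")
    return True


# ---------------------------------------------------------------------------
# Scene generation


@dataclass
class SceneConfig:
    """What to plant: counts per (size, pattern), monomers, solvent."""

    box: tuple[float, float, float] = (60.0, 60.0, 60.0)   # Å
    aggregates: dict[tuple[int, str], int] = field(default_factory=dict)
    n_monomers: int = 0
    n_solvent: int = 0
    jitter: float = 0.05          # Å, uniform per coordinate
    min_separation: float = 8.0   # Å between atoms of different aggregates
    seed: int = 0
    n_frames: int = 1

    def __post_init__(self):
        if self.min_separation <= 4.0:
            raise ValueError(
                "separation must exceed the largest interaction cutoff (4 Å)")
        if self.jitter < 0 or self.jitter > 0.15:
            raise ValueError("jitter must stay small enough to keep planted "
                             "contacts inside the criteria (≤ 0.15 Å)")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _mic_dist2(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return (d ** 2).sum(-1)


def _pack(blocks, box, min_sep, rng, max_tries=4000):
    """Place coordinate blocks at random poses with a minimum-image
    atom-separation constraint between blocks."""
    placed: list[np.ndarray] = []
    occupied = np.empty((0, 3))
    for coords in blocks:
        for attempt in range(max_tries):
            rot = _random_rotation(rng)
            pos = rng.uniform(0, 1, 3) * box
            cand = coords @ rot.T + pos
            if occupied.size == 0 or _mic_dist2(cand, occupied, box).min() >= min_sep ** 2:
                placed.append(cand)
                occupied = np.vstack([occupied, cand])
                break
        else:
            raise RuntimeError(
                "packing failed; use a larger box or fewer aggregates")
    return placed


def generate_scene(cfg: SceneConfig):
    """Frames with planted aggregates plus a ground-truth table.

    Returns (frames, truth) where truth is a list (one entry per frame)
    of lists of (size, pattern) in placement order; monomers appear as
    (1, None).  Identical config and seed reproduce identical
    coordinates.
    """
    spec = phenol_spec()
    solv = solvent_spec()
    specs = {"phenol": spec, solv.name: solv}
    box = np.asarray(cfg.box, float)
    rng = np.random.default_rng(cfg.seed)

    plan: list[tuple[int, str | None]] = []
    for (n, pattern), count in sorted(cfg.aggregates.items()):
        _validated(n, pattern)
        plan.extend([(n, pattern)] * count)
    plan.extend([(1, None)] * cfg.n_monomers)

    frames, truths = [], []
    for fidx in range(cfg.n_frames):
        blocks = [template_coordinates(n, p) for n, p in plan]
        placed = _pack(blocks, box, cfg.min_separation, rng)
        if cfg.jitter > 0:
            placed = [c + rng.uniform(-cfg.jitter, cfg.jitter, c.shape)
                      for c in placed]
        solvent = rng.uniform(0, 1, (cfg.n_solvent, 3)) * box
        coords = np.vstack(placed + [solvent]) if placed or cfg.n_solvent \
            else np.empty((0, 3))
        n_phenols = sum(n for n, _ in plan)
        mol_index = np.concatenate([
            np.repeat(np.arange(n_phenols), 13),
            n_phenols + np.arange(cfg.n_solvent)]).astype(int)
        species = ["phenol"] * n_phenols + [solv.name] * cfg.n_solvent
        frames.append(Frame(fidx, coords, box, mol_index, species))
        truths.append(list(plan))
    return frames, truths, specs


# ---------------------------------------------------------------------------
# Synthetic thermochemistry


@dataclass
class SynthThermoConfig:
    """Controlled free-energy structure for isomer tables.

    ``patterns[n]`` maps pattern label → list of (offset kcal/mol,
    degeneracy) member isomers; offsets are relative within the size.
    ``base_g[n]`` shifts a whole size (sets the K_n scale).  O–H
    stretch band positions/intensities are drawn uniformly from the
    configured ranges.
    """

    patterns: dict[int, dict[str, list[tuple[float, int]]]] = field(default_factory=dict)
    base_g: dict[int, float] = field(default_factory=dict)
    oh_band: tuple[float, float] = (3350.0, 3620.0)   # cm⁻¹ (unscaled ≈ /0.96)
    ch_band: tuple[float, float] = (3050.0, 3150.0)
    oh_intensity: tuple[float, float] = (100.0, 600.0)  # km/mol
    ch_intensity: tuple[float, float] = (5.0, 40.0)
    seed: int = 0


def generate_isomer_table(cfg: SynthThermoConfig):
    """IsomerRecords plus their closed-form ground-truth populations.

    Free energies are planted through the electronic energy (all other
    terms held identical within a size), so the analytic populations

        P_nα ∝ Σ_i m_i exp(−ΔG_i/RT)

    follow directly from the configured offsets and degeneracies.
    Returns (records, truth) with truth[n] mapping pattern → P_nα at
    298.15 K.
    """
    from .core_model import ThermoContext

    rng = np.random.default_rng(cfg.seed)
    ctx = ThermoContext()
    records: list[IsomerRecord] = []
    truth: dict[int, dict[str, float]] = {}
    for n, pats in sorted(cfg.patterns.items()):
        # one frequency set per size: vibrational terms cancel within a
        # size, so the planted offsets are exactly the pairwise ΔG of
        # the Boltzmann weights (intensities still vary per isomer)
        freqs = np.concatenate([
            rng.uniform(*cfg.ch_band, size=2 * n),
            rng.uniform(*cfg.oh_band, size=n) / 0.96,
        ])
        weights = {}
        for pattern, members in pats.items():
            z = 0.0
            for k, (offset, m) in enumerate(members):
                intens = np.concatenate([
                    rng.uniform(*cfg.ch_intensity, size=2 * n),
                    rng.uniform(*cfg.oh_intensity, size=n),
                ])
                records.append(IsomerRecord(
                    label=f"n{n}_{pattern}_{k}", size=n,
                    e_elec=cfg.base_g.get(n, 0.0) + offset, dg_solv=0.0,
                    frequencies=freqs, intensities=intens,
                    degeneracy=m, sigma=1, mass=94.11 * n,
                    inertia=np.array([90.0, 200.0, 290.0]) * n,
                    pattern=None if n == 1 else pattern,
                ))
                z += m * np.exp(-offset / ctx.RT)
            weights[pattern] = z
        total = sum(weights.values())
        if n > 1:
            truth[n] = {p: w / total for p, w in weights.items()}
    return records, truth


# ---------------------------------------------------------------------------
# Equilibrium trajectories


_DEFAULT_PATTERN = {2: "OH-bonded", 3: "linear", 4: "linear"}


def generate_equilibrium_trajectory(constants: dict[int, float], c_total: float,
                                    box: tuple[float, float, float],
                                    n_frames: int, seed: int = 0,
                                    jitter: float = 0.05):
    """Frames whose per-frame aggregate counts are independent Poisson
    draws with means C_n·V·N_A from the prescribed equilibrium.

    Returns (frames, specs, model, truth) where truth[j] maps size →
    planted count in frame j.  Species with expected counts below 0.01
    per frame trigger a noisy-recovery warning.
    """
    import warnings

    from .cd_populations import solve_equilibrium

    model = solve_equilibrium(constants, c_total)
    box = np.asarray(box, float)
    vol_L = float(np.prod(box)) * 1e-27
    lam = {n: c * vol_L * N_AVOGADRO for n, c in model.concentrations.items()}
    for n, l in lam.items():
        if 0 < model.concentrations[n] and l < 0.01:
            warnings.warn(f"expected count for size {n} is {l:.2g} per frame; "
                          "recovery will be noisy", stacklevel=2)

    spec = phenol_spec()
    specs = {"phenol": spec}
    rng = np.random.default_rng(seed)
    for n in lam:
        if lam[n] > 0 and n > 1:
            _validated(n, _DEFAULT_PATTERN[n])

    frames = []
    truth: list[dict[int, int]] = []
    for fidx in range(n_frames):
        plan: list[tuple[int, str | None]] = []
        planted: dict[int, int] = {}
        for n in sorted(lam):
            cnt = int(rng.poisson(lam[n]))
            planted[n] = cnt
            pattern = None if n == 1 else _DEFAULT_PATTERN[n]
            plan.extend([(n, pattern)] * cnt)
        truth.append(planted)
        blocks = [template_coordinates(n, p) for n, p in plan]
        # 5.5 Å inter-aggregate atom separation: comfortably above the
        # largest interaction cutoff (4.0 Å ring-centroid) yet loose
        # enough to pack molar-scale loadings by random insertion.
        # Retrying poses at fixed counts keeps the Poisson draw unbiased.
        for retry in range(6):
            try:
                placed = _pack(blocks, box, 5.5, rng)
                break
            except RuntimeError:
                if retry == 5:
                    raise
        if jitter > 0:
            placed = [c + rng.uniform(-jitter, jitter, c.shape) for c in placed]
        coords = np.vstack(placed) if placed else np.empty((0, 3))
        n_mols = sum(n for n, _ in plan)
        mol_index = np.repeat(np.arange(n_mols), 13)
        species = ["phenol"] * n_mols
        frames.append(Frame(fidx, coords, box, mol_index, species))
    return frames, specs, model, truth
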