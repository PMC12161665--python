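"""Domain types shared by every module, plus readers/writers for the
external formats.

The central objects are :class:`MoleculeSpec` (what a solute molecule is
made of and which functional groups it carries), :class:`Frame` (one
trajectory snapshot with an orthorhombic box), :class:`IsomerRecord`
(the full thermochemical input for one optimized minimum) and
:class:`PopulationTable` (interaction-pattern populations per aggregate
size, tagged with their provenance route).

Internal units: Å, amu, cm⁻¹, kcal mol⁻¹, mol L⁻¹, K.  GRO files carry
nm and are converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .constants import A3_TO_L, ATM_BAR, R_KCAL

logger = logging.getLogger(__name__)

# Standard atomic masses (amu) for the elements the synthetic scenes use.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "X": 1.0,
}


@dataclass(frozen=True)
class FunctionalGroup:
    """A named atom-index set with a role tag."""

    name: str
    role: str  # "hydroxyl" | "aromatic-ring"
    atom_indices: tuple[int, ...]


@dataclass(frozen=True)
class MoleculeSpec:
    """Species definition: atoms, masses and functional groups.

    Parameters
    ----------
    name
        Species label ("phenol", "ccl4", ...).
    elements
        Per-atom element symbols, in file order.
    groups
        Functional-group definitions.  A hydroxyl group contains exactly
        one O and its bonded H; an aromatic-ring group contains the six
        ring carbons (ring hydrogens are listed separately as π-donor
        hydrogens).
    donor_hydrogens
        Indices of H atoms that can donate: the hydroxyl H and the ring
        H atoms bonded to C.
    acceptor_atoms
        Indices of acceptor atoms (the hydroxyl O).
    masses
        Per-atom masses in amu; looked up from the element table when
        omitted.
    """

    name: str
    elements: tuple[str, ...]
    groups: tuple[FunctionalGroup, ...] = ()
    donor_hydrogens: tuple[int, ...] = ()
    acceptor_atoms: tuple[int, ...] = ()
    masses: tuple[float, ...] = ()

    def __post_init__(self):
        n = len(self.elements)
        if not self.masses:
            object.__setattr__(
                self, "masses",
                tuple(ATOMIC_MASSES[e] for e in self.elements))
        if len(self.masses) != n:
            raise ValueError(f"{self.name}: {len(self.masses)} masses for {n} atoms")
        for g in self.groups:
            if any(i >= n or i < 0 for i in g.atom_indices):
                raise ValueError(f"{self.name}: group {g.name} index out of range")
            if g.role == "hydroxyl":
                elems = sorted(self.elements[i] for i in g.atom_indices)
                if elems != ["H", "O"]:
                    raise ValueError(
                        f"{self.name}: hydroxyl group must be one O plus its bonded H")
            elif g.role == "aromatic-ring":
                if [self.elements[i] for i in g.atom_indices] != ["C"] * 6:
                    raise ValueError(
                        f"{self.name}: aromatic-ring group must contain six C")
            else:
                raise ValueError(f"{self.name}: unknown group role {g.role!r}")
        for i in self.donor_hydrogens:
            if self.elements[i] != "H":
                raise ValueError(f"{self.name}: donor hydrogen {i} is not H")
        for i in self.acceptor_atoms:
            if self.elements[i] != "O":
                raise ValueError(f"{self.name}: acceptor atom {i} is not O")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def group(self, role: str) -> FunctionalGroup:
        for g in self.groups:
            if g.role == role:
                return g
        raise KeyError(f"{self.name}: no group with role {role!r}")

    def has_group(self, role: str) -> bool:
        return any(g.role == role for g in self.groups)


@dataclass
class Frame:
    """One snapshot: coordinates, orthorhombic box and molecule map.

    ``coords`` is (n_atoms, 3) in Å; ``box`` the three edge lengths in
    Å.  ``mol_index`` maps every atom to its molecule; ``mol_species``
    names the species of each molecule.
    """

    index: int
    coords: np.ndarray
    box: np.ndarray
    mol_index: np.ndarray
    mol_species: list[str]
    time_ps: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError(f"frame {self.index}: box edges must be three positive lengths")
        if len(self.mol_index) != len(self.coords):
            raise ValueError(f"frame {self.index}: molecule map length mismatch")

    @property
    def n_molecules(self) -> int:
        return len(self.mol_species)

    @property
    def volume_L(self) -> float:
        """Box volume in litres (Å³ × 10⁻²⁷)."""
        return float(np.prod(self.box)) * A3_TO_L

    def molecule_atoms(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.mol_index == m)


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic context for the statistical-thermo route.

    The standard pressure defaults to 1 atm (1.01325 bar): the classic
    ideal-gas → 1 mol L⁻¹ correction RT ln(RT/p°) then equals
    1.89 kcal mol⁻¹ at 298.15 K.  Solvent defaults are carbon
    tetrachloride (M = 153.82 g mol⁻¹, ρ = 1.5867 g cm⁻³ at 25 °C).
    """

    temperature: float = 298.15          # K
    p_standard: float = ATM_BAR          # bar
    c_standard: float = 1.0              # mol L⁻¹
    m_solvent: float = 153.82            # g mol⁻¹
    rho_solvent: float = 1.5867          # g cm⁻³
    scale_spectra: float = 0.96          # frequency scale factor for band positions
    scale_thermal: float = 0.96          # frequency scale factor for thermal corrections
    nu0_rrho: float = 100.0              # cm⁻¹, quasi-RRHO rotor cutoff

    def __post_init__(self):
        if self.temperature <= 0 or self.p_standard <= 0 or self.c_standard <= 0:
            raise ValueError("T, p° and C° must be positive")
        for s in (self.scale_spectra, self.scale_thermal):
            if not (0.8 < s <= 1.05):
                raise ValueError(f"frequency scale factor {s} outside (0.8, 1.05]")
        if self.nu0_rrho < 0:
            raise ValueError("quasi-RRHO cutoff must be nonnegative")

    @property
    def RT(self) -> float:
        """R·T in kcal mol⁻¹."""
        return R_KCAL * self.temperature


@dataclass
class IsomerRecord:
    """Thermochemical inputs for one optimized minimum.

    Energies in kcal mol⁻¹ (electronic energy counterpoise-corrected
    upstream), frequencies in cm⁻¹ (all real), intensities in km mol⁻¹,
    mass in amu, principal moments of inertia in amu Å².  ``degeneracy``
    is the PES degeneracy m_i — the number of equivalent wells
    (rotamers / monomer permutations) this optimized structure stands
    for.
    """

    label: str
    size: int
    e_elec: float
    dg_solv: float
    frequencies: np.ndarray
    intensities: np.ndarray
    degeneracy: int = 1
    sigma: int = 1
    mass: float = 0.0
    inertia: np.ndarray | None = None
    pattern: str | None = None

    def __post_init__(self):
        self.frequencies = np.sort(np.asarray(self.frequencies, dtype=float))
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not (1 <= self.size <= 4):
            raise ValueError(f"{self.label}: aggregate size {self.size} outside 1..4")
        if len(self.frequencies) != len(self.intensities):
            raise ValueError(
                f"{self.label}: {len(self.frequencies)} frequencies vs "
                f"{len(self.intensities)} intensities")
        if len(self.frequencies) and np.any(self.frequencies <= 0):
            raise ValueError(f"{self.label}: imaginary/zero frequency rejected")
        if self.degeneracy < 1 or self.sigma < 1:
            raise ValueError(f"{self.label}: degeneracy and symmetry number must be >= 1")
        if self.inertia is not None:
            self.inertia = np.asarray(self.inertia, dtype=float)
            if self.inertia.shape != (3,):
                raise ValueError(f"{self.label}: need three principal moments")


@dataclass
class PopulationTable:
    """P_nα per aggregate size and interaction pattern.

    ``provenance`` is "C/d" (snapshot counting) or "Q/s" (free-energy
    Boltzmann weighting).  ``populations[n]`` maps pattern label → P_nα
    (each size sums to one); ``concentrations[n]`` is the aggregate
    concentration C_n in mol L⁻¹ where available.
    """

    provenance: str
    populations: dict[int, dict[str, float]]
    concentrations: dict[int, float] = field(default_factory=dict)
    c_total: float | None = None

    def __post_init__(self):
        for n, pops in self.populations.items():
            s = sum(pops.values())
            if abs(s - 1.0) > 1e-10:
                raise ValueError(f"size {n}: populations sum to {s}, not 1")
            if any(p < -1e-15 or p > 1 + 1e-12 for p in pops.values()):
                raise ValueError(f"size {n}: population outside [0, 1]")

    def as_frame(self):
        """Long-form pandas DataFrame (size, pattern, population, provenance)."""
        import pandas as pd

        rows = [
            {"size": n, "pattern": a, "population": p, "provenance": self.provenance}
            for n, pops in sorted(self.populations.items())
            for a, p in pops.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Frame readers


def _parse_xyz_comment_box(comment: str, index: int) -> np.ndarray:
    """Box from an XYZ comment line: extended 'Lattice="..."' or three floats."""
    m = re.search(r'Lattice="([^"]+)"', comment)
    if m:
        vals = [float(x) for x in m.group(1).split()]
        if len(vals) != 9:
            raise ValueError(f"frame {index}: Lattice needs 9 numbers")
        latt = np.array(vals).reshape(3, 3)
        off = latt - np.diag(np.diag(latt))
        if np.any(np.abs(off) > 1e-8):
            raise ValueError(f"frame {index}: only orthorhombic boxes supported")
        return np.diag(latt).copy()
    floats = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", comment)
    if len(floats) >= 3:
        return np.array([float(x) for x in floats[:3]])
    raise ValueError(
        f"frame {index}: no box on the comment line (volume is required)")


def _assign_molecules(
    n_atoms: int, layout: Sequence[tuple[str, int]],
    specs: Mapping[str, MoleculeSpec], index: int,
) -> tuple[np.ndarray, list[str]]:
    """Molecule map from a declared (species, count) layout of contiguous blocks."""
    mol_index = np.empty(n_atoms, dtype=int)
    mol_species: list[str] = []
    pos = 0
    for species, count in layout:
        na = specs[species].n_atoms
        for _ in range(count):
            if pos + na > n_atoms:
                raise ValueError(
                    f"frame {index}: layout requires more atoms than present "
                    f"({pos + na} > {n_atoms})")
            mol_index[pos:pos + na] = len(mol_species)
            mol_species.append(species)
            pos += na
    if pos != n_atoms:
        raise ValueError(
            f"frame {index}: layout covers {pos} atoms, file has {n_atoms}")
    return mol_index, mol_species


def read_frames(
    path: str | Path,
    fmt: str,
    specs: Mapping[str, MoleculeSpec],
    layout: Sequence[tuple[str, int]],
) -> list[Frame]:
    """Read an XYZ (extended comment-line box) or GRO file into Frames.

    ``layout`` declares the molecule composition as an ordered list of
    (species, count) pairs of contiguous atom blocks; atom counts are
    validated per frame against each species' :class:`MoleculeSpec`.
    GRO coordinates and box (nm) are converted to Å.
    """
    path = Path(path)
    if fmt == "xyz":
        return _read_xyz(path, specs, layout)
    if fmt == "gro":
        return _read_gro(path, specs, layout)
    raise ValueError(f"unknown frame format {fmt!r}")


def _read_xyz(path, specs, layout) -> list[Frame]:
    frames: list[Frame] = []
    lines = path.read_text().splitlines()
    i, fidx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].split()[0])
        except ValueError as e:
            raise ValueError(f"frame {fidx}: bad atom-count line {lines[i]!r}") from e
        if i + 2 + n_atoms > len(lines):
            raise ValueError(
                f"frame {fidx}: expected {n_atoms} atoms, file truncated at "
                f"{max(0, len(lines) - i - 2)}")
        comment = lines[i + 1]
        box = _parse_xyz_comment_box(comment, fidx)
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise ValueError(f"frame {fidx}: malformed atom line {a}")
            coords[a] = [float(x) for x in parts[1:4]]
        mol_index, mol_species = _assign_molecules(n_atoms, layout, specs, fidx)
        m = re.search(r"time\s*=\s*([-\d.eE+]+)", comment)
        frames.append(Frame(fidx, coords, box, mol_index, mol_species,
                            time_ps=float(m.group(1)) if m else None))
        i += 2 + n_atoms
        fidx += 1
    return frames


def _read_gro(path, specs, layout) -> list[Frame]:
    """GRO fixed-format reader (nm → Å); supports concatenated frames."""
    frames: list[Frame] = []
    lines = path.read_text().splitlines()
    i, fidx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        n_atoms = int(lines[i + 1])
        if i + 2 + n_atoms + 1 > len(lines):
            raise ValueError(f"frame {fidx}: truncated GRO frame")
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            ln = lines[i + 2 + a]
            # columns 21-44: x, y, z in nm, 8.3f each
            coords[a] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        box_vals = [float(x) for x in lines[i + 2 + n_atoms].split()]
        if len(box_vals) < 3:
            raise ValueError(f"frame {fidx}: GRO box line needs three edges")
        if len(box_vals) > 3 and any(abs(v) > 1e-8 for v in box_vals[3:]):
            raise ValueError(f"frame {fidx}: only orthorhombic boxes supported")
        mol_index, mol_species = _assign_molecules(n_atoms, layout, specs, fidx)
        m = re.search(r"t=\s*([-\d.eE+]+)", title)
        frames.append(Frame(fidx, coords * 10.0, np.array(box_vals[:3]) * 10.0,
                            mol_index, mol_species,
                            time_ps=float(m.group(1)) if m else None))
        i += 3 + n_atoms
        fidx += 1
    return frames


def write_xyz(frames: Iterable[Frame], specs: Mapping[str, MoleculeSpec],
              path: str | Path) -> None:
    """Write frames as extended XYZ with a Lattice comment-line box."""
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{len(fr.coords)}\n")
            lx, ly, lz = fr.box
            t = f" time={fr.time_ps}" if fr.time_ps is not None else ""
            fh.write(f'Lattice="{lx:.6f} 0.0 0.0 0.0 {ly:.6f} 0.0 0.0 0.0 {lz:.6f}"{t}\n')
            elements = np.concatenate(
                [list(specs[s].elements) for s in fr.mol_species])
            for el, (x, y, z) in zip(elements, fr.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Isomer table I/O


def read_isomer_table(path: str | Path) -> list[IsomerRecord]:
    """Read isomer thermochemistry records from a YAML document.

    Schema: a mapping with key ``isomers`` (or a bare list) of records
    with keys label, size, e_elec, dg_solv, frequencies, intensities and
    optional degeneracy (default 1, warning logged when absent), sigma,
    mass, inertia, pattern.  Energies may be given in hartree by setting
    the top-level key ``energy_unit: hartree``.
    """
    from .constants import HARTREE_KCAL

    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, dict):
        unit = data.get("energy_unit", "kcal/mol")
        entries = data["isomers"]
    else:
        unit, entries = "kcal/mol", data
    conv = HARTREE_KCAL if unit == "hartree" else 1.0
    records = []
    for e in entries:
        if "degeneracy" not in e:
            logger.warning("isomer %s: degeneracy m_i missing, defaulting to 1",
                           e.get("label"))
        records.append(IsomerRecord(
            label=str(e["label"]),
            size=int(e["size"]),
            e_elec=float(e["e_elec"]) * conv,
            dg_solv=float(e["dg_solv"]) * conv,
            frequencies=np.asarray(e.get("frequencies", []), dtype=float),
            intensities=np.asarray(e.get("intensities", []), dtype=float),
            degeneracy=int(e.get("degeneracy", 1)),
            sigma=int(e.get("sigma", 1)),
            mass=float(e.get("mass", 0.0)),
            inertia=e.get("inertia"),
            pattern=e.get("pattern"),
        ))
    return records


def write_spectrum(grid, path: str | Path, mode: str = "absorbance") -> None:
    """Write a spectrum as two-column text (wavenumber, value).

    ``mode`` selects absorbance (written as stored) or transmittance
    (T = 10^−A applied on the way out).  Header lines record the
    broadening configuration and population provenance.
    """
    from .spectra import SpectrumGrid  # local import to avoid a cycle

    if not isinstance(grid, SpectrumGrid):
        raise TypeError("write_spectrum needs a SpectrumGrid")
    values = grid.values
    if mode == "transmittance":
        if np.any(values < 0):
            raise ValueError("negative absorbance cannot become transmittance")
        values = 10.0 ** (-values)
    elif mode != "absorbance":
        raise ValueError(f"unknown spectrum mode {mode!r}")
    with open(path, "w") as fh:
        fh.write(f"# mode: {mode}\n")
        for k, v in grid.metadata.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# wavenumber_cm-1  value\n")
        for w, v in zip(grid.wavenumbers, values):
            fh.write(f"{w:.6g} {v:.6g}\n")


def read_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a two-column spectrum written by :func:`write_spectrum`."""
    meta: dict[str, str] = {}
    ws, vs = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if ":" in line:
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
            continue
        if line.strip():
            w, v = line.split()
            ws.append(float(w))
            vs.append(float(v))
    return np.array(ws), np.array(vs), meta


# ---------------------------------------------------------------------------
# The built-in phenol-like species used throughout the synthetic fixtures.


def phenol_spec() -> MoleculeSpec:
    """A rigid phenol: six ring C, five ring H, hydroxyl O and H.

    Atom order: C0..C5 (ring, C0 bears the OH), H1..H5 (ring H on
    C1..C5), O (index 11), H_O (index 12).
    """
    elements = ("C",) * 6 + ("H",) * 5 + ("O", "H")
    groups = (
        FunctionalGroup("ring", "aromatic-ring", tuple(range(6))),
        FunctionalGroup("hydroxyl", "hydroxyl", (11, 12)),
    )
    return MoleculeSpec(
        name="phenol", elements=elements, groups=groups,
        donor_hydrogens=(6, 7, 8, 9, 10, 12), acceptor_atoms=(11,),
    )


def solvent_spec(name: str = "solvent") -> MoleculeSpec:
    """Inert single-site solvent placeholder (invisible to detection)."""
    return MoleculeSpec(name=name, elements=("Ar",))
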