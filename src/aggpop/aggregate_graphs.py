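"""Aggregate extraction and interaction-pattern classification.

Molecules linked by any detected contact form the system adjacency
matrix; its connected blocks are the aggregates.  Each aggregate of
size 2–4 is reduced to a functional-group graph whose edges carry one
of three classes — HB (hydroxyl–hydroxyl hydrogen bond), ππ
(ring–ring: π-stacking or C–H···π) and OHπ (hydroxyl–ring: O–H···π or
aromatic C–H···O) — and classified by the topology of its H-bonds:

* at least one HB edge → the canonical form of the molecule-level
  H-bond graph selects the pattern label from the catalog;
* no HB edge → "OHπ" when some molecule touches its partners solely
  through hydroxyl–ring contacts, otherwise "ππ".

The default catalog carries 3 dimer, 5 trimer and 10 tetramer classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx
import numpy as np

from .interactions import CHO, CHPI, HB, OHPI, PIPI, InteractionRecord

logger = logging.getLogger(__name__)

#: interaction class → group-graph edge class
EDGE_CLASS = {HB: "HB", PIPI: "pipi", CHPI: "pipi", OHPI: "ohpi", CHO: "ohpi"}

PIPI_LABEL = "ππ"
OHPI_LABEL = "OHπ"
OVERSIZE_LABEL = "n>4"


def canonical_code(n: int, edges: set[tuple[int, int]] | list[tuple[int, int]]) -> str:
    """Canonical adjacency bit-string of a simple graph on ≤4 vertices.

    Two graphs get the same code iff they are isomorphic; computed by
    exhaustive minimisation over all vertex permutations (≤ 24).
    """
    if n > 4:
        raise ValueError(f"canonical_code supports at most 4 vertices, got {n}")
    eset = {(min(u, v), max(u, v)) for u, v in edges}
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = None
    for perm in permutations(range(n)):
        bits = "".join(
            "1" if (min(perm[i], perm[j]), max(perm[i], perm[j])) in eset else "0"
            for i, j in pairs)
        if best is None or bits < best:
            best = bits
    return f"{n}:{best or ''}"


@dataclass
class GroupGraph:
    """Functional-group graph of one aggregate.

    Nodes are (molecule, role) pairs; parallel edges of identical class
    are collapsed.  ``hbond_edges`` is the derived molecule-level
    simple H-bond graph.
    """

    molecules: tuple[int, ...]
    edges: set[tuple[int, int, str]]  # (mol_i < mol_j, class)

    @property
    def size(self) -> int:
        return len(self.molecules)

    @property
    def hbond_edges(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, c in self.edges if c == "HB"}

    @classmethod
    def from_records(cls, molecules, records: list[InteractionRecord]) -> "GroupGraph":
        mols = tuple(sorted(molecules))
        mset = set(mols)
        edges = set()
        for r in records:
            if r.i in mset and r.j in mset:
                i, j = min(r.i, r.j), max(r.i, r.j)
                edges.add((i, j, EDGE_CLASS[r.kind]))
        gg = cls(mols, edges)
        if len(gg.hbond_edges) > gg.size:
            logger.warning(
                "aggregate %s: %d H-bond edges for %d molecules (each hydroxyl "
                "should donate at most once)", mols, len(gg.hbond_edges), gg.size)
        return gg


def _default_catalog_entries() -> dict[int, dict[str, str]]:
    """Canonical-code → label tables for the default pattern taxonomy."""
    def code(n, edges):
        return canonical_code(n, edges)

    dimer = {code(2, [(0, 1)]): "OH-bonded"}
    trimer = {
        code(3, [(0, 1)]): "dimer-like",
        code(3, [(0, 1), (1, 2)]): "linear",
        code(3, [(0, 1), (1, 2), (0, 2)]): "cyclic",
    }
    tetramer = {
        code(4, [(0, 1)]): "dimer-like",
        code(4, [(0, 1), (2, 3)]): "two-dimers",
        code(4, [(0, 1), (1, 2)]): "trimer-like",
        code(4, [(0, 1), (1, 2), (2, 3)]): "linear",
        code(4, [(0, 1), (0, 2), (0, 3)]): "branched",
        code(4, [(0, 1), (1, 2), (0, 2)]): "cyclic-trimer",
        code(4, [(0, 1), (1, 2), (2, 3), (0, 3)]): "cyclic",
        code(4, [(0, 1), (1, 2), (0, 2), (2, 3)]): "tadpole",
    }
    return {2: dimer, 3: trimer, 4: tetramer}


@dataclass
class PatternCatalog:
    """Pattern taxonomy: H-bond-topology codes plus the two no-H-bond
    fallbacks per size.

    Default sizes: 3 dimer patterns, 5 trimer patterns, 10 tetramer
    patterns.  User-extensible via :meth:`add_pattern`.
    """

    entries: dict[int, dict[str, str]] = field(default_factory=_default_catalog_entries)

    def labels(self, n: int) -> list[str]:
        return list(self.entries.get(n, {}).values()) + [PIPI_LABEL, OHPI_LABEL]

    def add_pattern(self, n: int, edges, label: str) -> None:
        self.entries.setdefault(n, {})[canonical_code(n, edges)] = label

    def lookup(self, n: int, code: str) -> str:
        try:
            return self.entries[n][code]
        except KeyError:
            raise KeyError(
                f"H-bond topology {code!r} (size {n}) not in catalog; "
                f"extend it with add_pattern") from None


def build_system_adjacency(records: list[InteractionRecord],
                           n_molecules: int) -> np.ndarray:
    """Symmetric boolean molecule adjacency: (i,j) true iff some record
    links i and j; diagonal false."""
    adj = np.zeros((n_molecules, n_molecules), dtype=bool)
    for r in records:
        if r.i >= n_molecules or r.j >= n_molecules:
            raise IndexError(f"record references molecule {max(r.i, r.j)}")
        if r.i != r.j:
            adj[r.i, r.j] = adj[r.j, r.i] = True
    return adj


def extract_aggregates(adjacency: np.ndarray) -> tuple[list[tuple[int, ...]], dict[int, int]]:
    """Connected components of the molecule adjacency and their size
    histogram.

    Returns (components, histogram) where components are sorted tuples
    of molecule indices (singletons are monomers) and histogram maps
    aggregate size → count.
    """
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    g = nx.from_numpy_array(adjacency)
    comps = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(g)),
        key=lambda c: c[0])
    hist: dict[int, int] = {}
    for c in comps:
        hist[len(c)] = hist.get(len(c), 0) + 1
    return comps, hist


def classify_pattern(gg: GroupGraph, catalog: PatternCatalog | None = None) -> str:
    """Interaction-pattern label of one aggregate.

    H-bond topology takes precedence; aggregates larger than 4
    molecules get the reserved "n>4" label (tallied, never classified).
    """
    catalog = catalog or PatternCatalog()
    n = gg.size
    if n > 4:
        return OVERSIZE_LABEL
    if n < 2:
        raise ValueError("monomers carry no interaction pattern")
    hb = gg.hbond_edges
    if hb:
        local = {m: k for k, m in enumerate(gg.molecules)}
        code = canonical_code(n, [(local[i], local[j]) for i, j in hb])
        return catalog.lookup(n, code)
    # no H-bond: OHπ if some molecule interacts solely through
    # hydroxyl-ring contacts, else ππ
    incident: dict[int, set[str]] = {m: set() for m in gg.molecules}
    for i, j, c in gg.edges:
        incident[i].add(c)
        incident[j].add(c)
    for m in gg.molecules:
        if incident[m] and incident[m] == {"ohpi"}:
            return OHPI_LABEL
    return PIPI_LABEL


def classify_frame(frame, specs, criteria=None, catalog=None):
    """Full per-frame pipeline: detect → adjacency → components →
    classify.

    Returns (aggregates, histogram) where aggregates is a list of
    (molecule tuple, size, pattern label or None for monomers).
    """
    from .interactions import detect_interactions

    records = detect_interactions(frame, specs, criteria)
    adj = build_system_adjacency(records, frame.n_molecules)
    solute = {m for m in range(frame.n_molecules)
              if specs[frame.mol_species[m]].groups}
    comps, _ = extract_aggregates(adj)
    out = []
    hist: dict[int, int] = {}
    for comp in comps:
        if not set(comp) <= solute:
            continue  # solvent never aggregates (no groups, no records)
        n = len(comp)
        hist[n] = hist.get(n, 0) + 1
        if n == 1:
            out.append((comp, 1, None))
        else:
            gg = GroupGraph.from_records(comp, records)
            out.append((comp, n, classify_pattern(gg, catalog)))
    return out, hist
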