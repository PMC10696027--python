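"""Maximum-common-subgraph (MCS) Tanimoto similarity.

The similarity between two molecules A and B is

    T(A, B) = m / (|A| + |B| - m)

where ``m`` is the heavy-atom count of a maximum common connected induced
subgraph of the two hydrogen-suppressed molecular graphs and |A|, |B| are
their heavy-atom counts. Atoms are compatible when their element symbols
match; bonds must match in order, with aromatic treated as a distinct order
(so a Kekulé ring never matches an aliphatic one). The search is exact: a
McGregor-style branch-and-bound over atom mappings grown along bonds, with
a node-expansion cap that raises rather than silently truncating.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from rdkit import Chem

from csncrit.mol_io import MoleculeSet

logger = logging.getLogger(__name__)

#: Default branch-and-bound expansion budget per molecule pair. Generous for
#: drug-like sizes; pairs that exceed it raise McsTimeoutError.
DEFAULT_EXPANSION_CAP = 2_000_000


class McsTimeoutError(RuntimeError):
    """The exact MCS search exceeded its node-expansion budget."""


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    ``atoms[i]`` is ``(element symbol, aromatic flag)``; ``bonds`` maps the
    unordered heavy-atom index pair to a bond-order token in
    {"single", "double", "triple", "aromatic"}; ``adjacency[i]`` lists the
    neighbours of atom i.
    """

    atoms: tuple[tuple[str, bool], ...]
    bonds: dict[tuple[int, int], str]
    adjacency: tuple[tuple[int, ...], ...]

    @property
    def size(self) -> int:
        return len(self.atoms)

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return cls.from_rdkit(mol)

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MolecularGraph":
        atoms = tuple(
            (a.GetSymbol(), a.GetIsAromatic()) for a in mol.GetAtoms()
        )
        bonds: dict[tuple[int, int], str] = {}
        adj: list[list[int]] = [[] for _ in atoms]
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if b.GetIsAromatic():
                order = "aromatic"
            else:
                order = {
                    Chem.BondType.SINGLE: "single",
                    Chem.BondType.DOUBLE: "double",
                    Chem.BondType.TRIPLE: "triple",
                }.get(b.GetBondType(), "single")
            bonds[(min(i, j), max(i, j))] = order
            adj[i].append(j)
            adj[j].append(i)
        return cls(atoms=atoms, bonds=bonds, adjacency=tuple(tuple(n) for n in adj))

    def bond_order(self, i: int, j: int) -> str | None:
        return self.bonds.get((min(i, j), max(i, j)))


def _element_counts(g: MolecularGraph, exclude: set[int] | None = None) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i, (el, _) in enumerate(g.atoms):
        if exclude and i in exclude:
            continue
        counts[el] = counts.get(el, 0) + 1
    return counts


def _element_bound(a: MolecularGraph, b: MolecularGraph) -> int:
    ca, cb = _element_counts(a), _element_counts(b)
    return sum(min(n, cb.get(el, 0)) for el, n in ca.items())


_ORDER_TOKEN = {"single": 1, "double": 2, "triple": 3, "aromatic": 4}


class _Done(Exception):
    """Internal: the search proved it cannot improve further."""


class _McsSearch:
    """Branch-and-bound over connected common-induced-subgraph mappings.

    The mapping grows one atom pair at a time; every atom added after the
    seed must be bonded (in A) to an already-mapped atom, which keeps the
    common subgraph connected. The induced condition — for all mapped pairs,
    A has a bond iff B has a bond, with equal order — is maintained
    incrementally as per-atom candidate bitmasks over B. Branching is
    fail-first (pivot on the frontier atom with fewest candidates, plus the
    branch that excludes it) and bounded by the number of A-atoms still
    reachable from the frontier with non-empty candidate sets.

    ``lower_bound`` seeds the incumbent so callers that only care whether
    the MCS exceeds a size (floor pruning) can cut the search early; the
    returned value is then only guaranteed exact when it beats the seed.
    """

    def __init__(
        self,
        a: MolecularGraph,
        b: MolecularGraph,
        expansion_cap: int,
        lower_bound: int = 0,
    ):
        self.a = a
        self.b = b
        self.cap = expansion_cap
        self.expansions = 0
        self.best = lower_bound
        self.best_found = 0
        na, nb = a.size, b.size
        self.na, self.nb = na, nb

        bond_a = [[0] * na for _ in range(na)]
        for (i, j), order in a.bonds.items():
            tok = _ORDER_TOKEN[order]
            bond_a[i][j] = tok
            bond_a[j][i] = tok
        bond_b = [[0] * nb for _ in range(nb)]
        for (i, j), order in b.bonds.items():
            tok = _ORDER_TOKEN[order]
            bond_b[i][j] = tok
            bond_b[j][i] = tok
        self.bond_a = bond_a

        self.adj_a = [
            sum(1 << k for k in a.adjacency[i]) for i in range(na)
        ]
        # mask_b[l][o]: atoms j != l of B whose bond order to l is o (0 = none).
        self.mask_b = [[0] * 5 for _ in range(nb)]
        for l in range(nb):
            for j in range(nb):
                if j != l:
                    self.mask_b[l][bond_b[j][l]] |= 1 << j
        # Element-compatible B atoms per A atom.
        self.compat = [
            sum(1 << j for j in range(nb) if b.atoms[j][0] == a.atoms[i][0])
            for i in range(na)
        ]

    def run(self) -> int:
        na = self.na
        if na == 0 or self.nb == 0:
            return 0
        max_possible = min(na, self.nb)
        try:
            for i0 in range(na):
                # Each connected subgraph of A has a unique minimum-index
                # atom; seeding on i0 and restricting later atoms to > i0
                # covers every candidate without cross-seed duplication.
                allowed = ~((1 << i0) - 1)
                if bin(allowed & ((1 << na) - 1)).count("1") <= self.best:
                    break
                cands0 = self.compat[i0]
                while cands0:
                    j0 = (cands0 & -cands0).bit_length() - 1
                    cands0 &= cands0 - 1
                    cand = [
                        self.compat[i] & self.mask_b[j0][self.bond_a[i][i0]]
                        for i in range(na)
                    ]
                    if self.best < 1:
                        self.best = 1
                    self.best_found = max(self.best_found, 1)
                    if self.best_found == max_possible:
                        raise _Done
                    self._extend(
                        depth=1,
                        cand=cand,
                        frontier=self.adj_a[i0] & allowed,
                        mapped_a=1 << i0,
                        used_b=1 << j0,
                        allowed=allowed,
                    )
        except _Done:
            pass
        return self.best_found

    def _extend(
        self,
        depth: int,
        cand: list[int],
        frontier: int,
        mapped_a: int,
        used_b: int,
        allowed: int,
    ) -> None:
        self.expansions += 1
        if self.expansions > self.cap:
            raise McsTimeoutError(
                f"MCS search exceeded {self.cap} node expansions "
                f"(|A|={self.na}, |B|={self.nb})"
            )
        # Atoms still eligible: unmapped, index >= seed, some candidate left.
        avail = 0
        mm = frontier
        reach = 0
        not_used = ~used_b
        avail_mask = allowed & ~mapped_a
        for i in range(self.na):
            bit = 1 << i
            if bit & avail_mask and cand[i] & not_used:
                avail |= bit
        # Connectivity bound: only atoms reachable from the frontier through
        # eligible atoms can ever join this mapping.
        reach = frontier & avail
        while True:
            grow = reach
            mm = reach
            while mm:
                i = (mm & -mm).bit_length() - 1
                mm &= mm - 1
                grow |= self.adj_a[i]
            grow &= avail
            if grow == reach:
                break
            reach = grow
        ub = depth + bin(reach).count("1")
        if ub <= self.best:
            return
        # Fail-first pivot: frontier atom with the fewest candidates.
        pivot = -1
        pivot_cands = 0
        pivot_count = 1 << 30
        mm = frontier & reach
        while mm:
            i = (mm & -mm).bit_length() - 1
            mm &= mm - 1
            c = cand[i] & not_used
            cnt = bin(c).count("1")
            if cnt < pivot_count:
                pivot, pivot_cands, pivot_count = i, c, cnt
        if pivot < 0:
            return
        max_possible = min(self.na, self.nb)
        # Branch 1: map the pivot to each of its candidates.
        cands = pivot_cands
        pivot_bit = 1 << pivot
        bond_row = self.bond_a[pivot]
        while cands:
            j = (cands & -cands).bit_length() - 1
            cands &= cands - 1
            mask_j = self.mask_b[j]
            new_cand = [cand[i] & mask_j[bond_row[i]] for i in range(self.na)]
            new_depth = depth + 1
            if new_depth > self.best_found:
                self.best_found = new_depth
                if new_depth == max_possible:
                    raise _Done
            if new_depth > self.best:
                self.best = new_depth
            self._extend(
                depth=new_depth,
                cand=new_cand,
                frontier=(frontier | self.adj_a[pivot]) & allowed & ~(mapped_a | pivot_bit),
                mapped_a=mapped_a | pivot_bit,
                used_b=used_b | (1 << j),
                allowed=allowed,
            )
        # Branch 2: never map the pivot in this subtree.
        cand_no = list(cand)
        cand_no[pivot] = 0
        self._extend(
            depth=depth,
            cand=cand_no,
            frontier=frontier & ~pivot_bit,
            mapped_a=mapped_a,
            used_b=used_b,
            allowed=allowed,
        )


def mcs_size(
    a: MolecularGraph,
    b: MolecularGraph,
    expansion_cap: int = DEFAULT_EXPANSION_CAP,
) -> int:
    """Heavy-atom count of a maximum common connected induced subgraph.

    Deterministic for fixed inputs. Raises :class:`McsTimeoutError` when the
    branch-and-bound exceeds ``expansion_cap`` node expansions — never a
    silent approximation.
    """
    if a.size > b.size:
        a, b = b, a
    return _McsSearch(a, b, expansion_cap).run()


def tanimoto_smsd(
    a: MolecularGraph,
    b: MolecularGraph,
    expansion_cap: int = DEFAULT_EXPANSION_CAP,
) -> float:
    """MCS-Tanimoto similarity m / (|A| + |B| - m); 1.0 iff isomorphic."""
    if a.size == 0 or b.size == 0:
        raise ValueError("Tanimoto similarity requires non-empty molecular graphs")
    m = mcs_size(a, b, expansion_cap=expansion_cap)
    return m / (a.size + b.size - m)


@dataclass
class SimilarityStore:
    """Sparse symmetric pairwise similarities above a floor.

    Only pairs ``(i, j)`` with ``i < j`` and similarity strictly above
    ``floor`` are stored; everything else is implicitly at-or-below floor.
    ``ids`` gives a stable node ordering; ``timeouts`` lists pairs whose MCS
    search exceeded its budget (missing-with-reason, never silently zero).
    """

    ids: list[str]
    floor: float
    entries: dict[tuple[int, int], float] = field(default_factory=dict)
    timeouts: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return len(self.ids)

    def similarity(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        return self.entries.get((min(i, j), max(i, j)), 0.0)

    def to_csv(self, edge_path: str | Path, meta_path: str | Path | None = None) -> None:
        with open(edge_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id_i", "id_j", "similarity"])
            for (i, j), s in sorted(self.entries.items()):
                writer.writerow([self.ids[i], self.ids[j], f"{s:.6f}"])
        if meta_path is not None:
            meta = {
                "ids": self.ids,
                "n_molecules": self.n_molecules,
                "floor": self.floor,
                "n_pairs_stored": len(self.entries),
                "n_timeouts": len(self.timeouts),
            }
            Path(meta_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, edge_path: str | Path, meta_path: str | Path) -> "SimilarityStore":
        meta = json.loads(Path(meta_path).read_text())
        store = cls(ids=list(meta["ids"]), floor=float(meta["floor"]))
        index = {mol_id: i for i, mol_id in enumerate(store.ids)}
        with open(edge_path, newline="") as fh:
            for row in csv.DictReader(fh):
                i, j = index[row["id_i"]], index[row["id_j"]]
                store.entries[(min(i, j), max(i, j))] = float(row["similarity"])
        return store


def _pair_iter(n: int) -> Iterator[tuple[int, int]]:
    for i in range(n):
        for j in range(i + 1, n):
            yield i, j


def pairwise_similarity(
    mols: MoleculeSet,
    floor: float = 0.3,
    expansion_cap: int = DEFAULT_EXPANSION_CAP,
    progress_every: int = 0,
) -> SimilarityStore:
    """Evaluate all N(N-1)/2 MCS-Tanimoto pairs, keeping values above ``floor``.

    The floor (default 0.3) drops pairs too dissimilar to carry meaningful
    structural information and keeps the store sparse. Pairs whose search
    times out are recorded in ``store.timeouts``.
    """
    if not 0.0 <= floor < 1.0:
        raise ValueError(f"floor must be in [0, 1), got {floor}")
    if mols.n < 2:
        raise ValueError("pairwise similarity needs at least 2 molecules")
    graphs = [MolecularGraph.from_smiles(r.smiles_canonical) for r in mols.records]
    store = SimilarityStore(ids=[r.id for r in mols.records], floor=floor)
    n_done = 0
    for i, j in _pair_iter(mols.n):
        ga, gb = graphs[i], graphs[j]
        if ga.size > gb.size:
            ga, gb = gb, ga
        # Only pairs above the floor are kept, so the search may be seeded
        # with the smallest MCS size that could clear it: anything below is
        # provably at-or-under the floor and needs no exact value.
        lb = int(floor * (ga.size + gb.size) / (1.0 + floor))
        try:
            m = _McsSearch(ga, gb, expansion_cap, lower_bound=lb).run()
        except McsTimeoutError:
            store.timeouts.append((i, j))
            logger.warning("MCS timeout for pair (%s, %s)", store.ids[i], store.ids[j])
            continue
        if m > lb:
            s = m / (ga.size + gb.size - m)
            if s > floor:
                store.entries[(i, j)] = s
        n_done += 1
        if progress_every and n_done % progress_every == 0:
            logger.info("similarity: %d pairs done", n_done)
    return store
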