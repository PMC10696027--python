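"""Synthetic molecule families and planted similarity stores.

Two generators make every pipeline stage testable without external data:

* :func:`generate_scaffold_families` builds real molecules — each family
  shares a scaffold core carrying random small decorations, so within-family
  MCS-Tanimoto similarity is high (the scaffold is a guaranteed common
  subgraph) and cross-family similarity is low (the cores are structurally
  dissimilar). Labels are assigned per family with optional flip noise.
* :func:`generate_planted_store` builds an abstract similarity store with
  the same block structure but no chemistry at all, so the network and
  statistics layers never depend on the MCS engine's runtime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from csncrit.mcs import SimilarityStore
from csncrit.mol_io import (
    LABEL_NONTOXIC,
    LABEL_TOXIC,
    MoleculeRecord,
    MoleculeSet,
    canonicalize,
)

logger = logging.getLogger(__name__)

#: Small substituents with a free valence on their first atom.
DEFAULT_DECORATIONS = ("C", "CC", "O", "N", "F", "Cl", "CO")


@dataclass
class FamilySpec:
    """One structural family: a scaffold plus random decorations and a label."""

    name: str
    scaffold: str
    n_members: int
    label: str = LABEL_TOXIC
    decorations: tuple[str, ...] = DEFAULT_DECORATIONS
    decoration_count: tuple[int, int] = (1, 3)
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if Chem.MolFromSmiles(self.scaffold) is None:
            raise ValueError(f"unparseable scaffold SMILES: {self.scaffold!r}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


def _attach(core: Chem.Mol, fragment: str, rng: np.random.Generator) -> Chem.Mol | None:
    """Bond a substituent's first atom to a random core atom with a free valence."""
    frag = Chem.MolFromSmiles(fragment)
    if frag is None:
        return None
    sites = [
        a.GetIdx()
        for a in core.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetSymbol() in ("C", "N", "O")
    ]
    if not sites:
        return None
    site = int(rng.choice(sites))
    combined = Chem.RWMol(Chem.CombineMols(core, frag))
    combined.AddBond(site, core.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _decorated_molecule(spec: FamilySpec, rng: np.random.Generator) -> str | None:
    mol = Chem.MolFromSmiles(spec.scaffold)
    lo, hi = spec.decoration_count
    k = int(rng.integers(lo, hi + 1))
    for _ in range(k):
        fragment = str(rng.choice(list(spec.decorations)))
        for _attempt in range(5):
            out = _attach(mol, fragment, rng)
            if out is not None:
                mol = out
                break
        else:
            logger.warning("could not attach %r; skipping decoration", fragment)
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def generate_scaffold_families(
    specs: list[FamilySpec], seed: int = 0
) -> MoleculeSet:
    """Generate distinct decorated molecules per family spec, reproducibly.

    Each record's ``source`` is the family name and its label is the family
    label, independently flipped with probability ``label_noise``.
    """
    if not specs:
        raise ValueError("need at least one family spec")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records: list[MoleculeRecord] = []
    for spec in specs:
        seen: set[str] = set()
        attempts = 0
        max_attempts = 200 * spec.n_members
        while len(seen) < spec.n_members and attempts < max_attempts:
            attempts += 1
            smi = _decorated_molecule(spec, rng)
            if smi is None:
                continue
            can = canonicalize(smi)
            if can in seen:
                continue
            seen.add(can)
            label = spec.label
            if spec.label_noise and rng.random() < spec.label_noise:
                label = LABEL_NONTOXIC if label == LABEL_TOXIC else LABEL_TOXIC
            records.append(
                MoleculeRecord(
                    id=f"{spec.name}:{len(seen) - 1}",
                    smiles_raw=smi,
                    smiles_canonical=can,
                    label=label,
                    source=spec.name,
                )
            )
        if len(seen) < spec.n_members:
            raise RuntimeError(
                f"family {spec.name!r}: only {len(seen)} distinct molecules "
                f"after {attempts} attempts; enlarge the decoration set"
            )
    return MoleculeSet(records)


def three_archetypes_preset(
    seed: int = 0, n_members: int = 40, label_noise: float = 0.0
) -> MoleculeSet:
    """Three structurally distinct families echoing the archetype pattern.

    An aromatic bicyclic (aryl-like, toxic), an aliphatic fused bicyclic
    (steroid-core-like, toxic) and a short polyether chain (volatile-ether-
    like, non-toxic). Aromatic vs single bond orders keep cross-family MCS
    small while the shared cores keep within-family similarity high.
    """
    specs = [
        FamilySpec(name="aryl", scaffold="c1ccc2ccccc2c1",
                   n_members=n_members, label=LABEL_TOXIC, label_noise=label_noise),
        FamilySpec(name="fused-ring", scaffold="C1CCC2CCCCC2C1",
                   n_members=n_members, label=LABEL_TOXIC, label_noise=label_noise),
        FamilySpec(name="ether", scaffold="CCOCCOCC",
                   n_members=n_members, label=LABEL_NONTOXIC, label_noise=label_noise),
    ]
    return generate_scaffold_families(specs, seed=seed)


def generate_planted_store(
    n_families: int,
    family_size: int,
    within_sim: tuple[float, float],
    between_sim: tuple[float, float],
    seed: int = 0,
    floor: float = 0.3,
) -> SimilarityStore:
    """Abstract block-structured similarity store with no molecules behind it.

    Within-family pair similarities are uniform on ``within_sim`` and
    cross-family pairs uniform on ``between_sim``; only values above the
    floor are stored. Node ids encode the family (``f<k>:<member>``) and
    :func:`planted_families` recovers the planted assignment.
    """
    w_lo, w_hi = within_sim
    b_lo, b_hi = between_sim
    if not (0.0 <= b_lo <= b_hi <= 1.0 and 0.0 <= w_lo <= w_hi <= 1.0):
        raise ValueError("similarity ranges must lie within [0, 1]")
    if w_lo <= b_hi:
        raise ValueError(
            f"within range {within_sim} must lie strictly above between range {between_sim}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = n_families * family_size
    ids = [f"f{i // family_size}:{i % family_size}" for i in range(n)]
    store = SimilarityStore(ids=ids, floor=floor)
    for i in range(n):
        for j in range(i + 1, n):
            if i // family_size == j // family_size:
                s = float(rng.uniform(w_lo, w_hi))
            else:
                s = float(rng.uniform(b_lo, b_hi))
            if s > floor:
                store.entries[(i, j)] = s
    return store


def planted_families(store: SimilarityStore) -> list[int]:
    """Recover the planted family index for each node of a planted store."""
    return [int(mol_id[1:].split(":")[0]) for mol_id in store.ids]
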