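"""Reading, canonicalising and merging labelled SMILES tables.

Curation mirrors the usual read-across preprocessing: every structure is
reduced to a stereo-free canonical SMILES, multi-fragment inputs (salts,
mixtures) are reduced to their largest fragment, duplicate structures are
collapsed, and structures reported with opposite toxicity labels in
different sources are discarded entirely since their label is unreliable.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about sanitisation on stderr; route through logging instead.
RDLogger.DisableLog("rdApp.*")

LABEL_TOXIC = "toxic"
LABEL_NONTOXIC = "nontoxic"
LABEL_UNLABELLED = "unlabelled"

_LABEL_ALIASES = {
    "toxic": LABEL_TOXIC,
    "1": LABEL_TOXIC,
    "positive": LABEL_TOXIC,
    "nontoxic": LABEL_NONTOXIC,
    "non-toxic": LABEL_NONTOXIC,
    "non_toxic": LABEL_NONTOXIC,
    "0": LABEL_NONTOXIC,
    "negative": LABEL_NONTOXIC,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecular graph."""


def normalise_label(value: object) -> str:
    """Map a raw label value onto {toxic, nontoxic, unlabelled}."""
    if value is None:
        return LABEL_UNLABELLED
    return _LABEL_ALIASES.get(str(value).strip().lower(), LABEL_UNLABELLED)


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated molecule: raw and canonical SMILES, label and provenance."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    label: str = LABEL_UNLABELLED
    source: str = ""


@dataclass
class MoleculeSet:
    """An ordered collection of molecule records.

    After :func:`merge_and_deduplicate` all canonical SMILES are distinct;
    raw single-source sets may still contain duplicates.
    """

    records: list[MoleculeRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def smiles(self) -> list[str]:
        return [r.smiles_canonical for r in self.records]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles", "label", "source"])
            for r in self.records:
                writer.writerow([r.id, r.smiles_canonical, r.label, r.source])


@dataclass
class ConflictReport:
    """Structures seen with opposite labels across sources, all discarded."""

    discarded: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=list
    )

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_discarded": self.n_discarded,
            "discarded": [
                {"smiles_canonical": s, "labels": list(l), "sources": list(src)}
                for s, l, src in self.discarded
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def canonicalize(smiles: str) -> str:
    """Return the stereo-free canonical SMILES of a structure.

    Stereo bond directions and atom parities are removed before writing the
    canonical form, so enantiomers and E/Z isomers collapse onto one string;
    multi-fragment inputs are reduced to the largest fragment. The output is
    idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    n_frags = len(Chem.GetMolFrags(mol))
    if n_frags > 1:
        logger.info("multi-fragment SMILES %r: keeping largest fragment", smiles)
        mol = _largest_fragment(mol)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol, isomericSmiles=False, canonical=True)


def merge_and_deduplicate(
    sets: Sequence[MoleculeSet],
) -> tuple[MoleculeSet, ConflictReport]:
    """Cross-merge molecule sets, collapsing duplicates and dropping conflicts.

    One record is kept per canonical SMILES (first-seen id/source wins).
    A canonical SMILES observed with both the toxic and non-toxic label is
    removed entirely and logged in the :class:`ConflictReport`. Unlabelled
    records never create conflicts but are kept (and excluded downstream
    from classification).
    """
    seen: dict[str, MoleculeRecord] = {}
    labels_seen: dict[str, set[str]] = {}
    sources_seen: dict[str, set[str]] = {}
    order: list[str] = []

    for molset in sets:
        for rec in molset.records:
            key = rec.smiles_canonical
            if key not in seen:
                seen[key] = rec
                labels_seen[key] = set()
                sources_seen[key] = set()
                order.append(key)
            if rec.label != LABEL_UNLABELLED:
                labels_seen[key].add(rec.label)
            sources_seen[key].add(rec.source)
            # Prefer a labelled record over an earlier unlabelled duplicate.
            if seen[key].label == LABEL_UNLABELLED and rec.label != LABEL_UNLABELLED:
                seen[key] = MoleculeRecord(
                    id=seen[key].id,
                    smiles_raw=seen[key].smiles_raw,
                    smiles_canonical=key,
                    label=rec.label,
                    source=seen[key].source,
                )

    report = ConflictReport()
    kept: list[MoleculeRecord] = []
    for key in order:
        if len(labels_seen[key]) > 1:
            report.discarded.append(
                (key, tuple(sorted(labels_seen[key])), tuple(sorted(sources_seen[key])))
            )
        else:
            kept.append(seen[key])
    if report.n_discarded:
        logger.info("discarded %d structures with conflicting labels", report.n_discarded)
    return MoleculeSet(kept), report


def _records_from_rows(
    rows: Iterable[tuple[str, object, str, str]],
) -> tuple[list[MoleculeRecord], int]:
    records = []
    n_skipped = 0
    for smiles, label, mol_id, source in rows:
        try:
            can = canonicalize(smiles)
        except SmilesParseError:
            n_skipped += 1
            logger.warning("skipping unparseable SMILES %r (id=%s)", smiles, mol_id)
            continue
        records.append(
            MoleculeRecord(
                id=mol_id,
                smiles_raw=smiles,
                smiles_canonical=can,
                label=normalise_label(label),
                source=source,
            )
        )
    return records, n_skipped


def read_smiles_table(
    path: str | Path,
    fmt: str = "csv",
    source: str | None = None,
) -> MoleculeSet:
    """Read a labelled SMILES table into a canonicalised :class:`MoleculeSet`.

    ``csv`` expects a header with a ``smiles`` column and optional ``label``,
    ``id`` and ``source`` columns. ``smi`` expects ``SMILES [id]`` per line
    (no labels). Unparseable rows are skipped with a logged count.
    """
    path = Path(path)
    default_source = source if source is not None else path.name
    rows: list[tuple[str, object, str, str]] = []

    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return MoleculeSet([])
            fields = {f.lower(): f for f in reader.fieldnames}
            if "smiles" not in fields:
                raise ValueError(f"{path}: no 'smiles' column (found {reader.fieldnames})")
            for i, row in enumerate(reader):
                smiles = row[fields["smiles"]]
                if smiles is None or not smiles.strip():
                    continue
                label = row.get(fields.get("label", ""), None)
                mol_id = row.get(fields.get("id", ""), None) or f"{path.stem}:{i}"
                src = row.get(fields.get("source", ""), None) or default_source
                rows.append((smiles.strip(), label, mol_id, src))
    elif fmt == "smi":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                mol_id = parts[1] if len(parts) > 1 else f"{path.stem}:{i}"
                rows.append((smiles, None, mol_id, default_source))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'smi'")

    records, n_skipped = _records_from_rows(rows)
    if n_skipped:
        logger.info("%s: skipped %d unparseable rows", path, n_skipped)
    return MoleculeSet(records)
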