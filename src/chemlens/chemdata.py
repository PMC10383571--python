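"""Structure parsing, dataset containers and compound-curation filters.

Compound sets are four-class: dual-target actives (DT), single-target
actives for each target of the pair (ST_A, ST_B), and randomly selected,
presumed inactive compounds (R).  Curation mirrors the conventional
ChEMBL-style record filters: activity-comment blocklist, molecular-mass
ceiling, standard potency types (Ki/Kd/IC50), exact standard relation,
top target-confidence score, and a potency cutoff.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")


class ClassLabel(Enum):
    """The four prediction classes, with a fixed integer encoding.

    The code order DT=0, ST_A=1, ST_B=2, R=3 is part of the contract:
    probability vectors are indexed by it and argmax ties break toward
    the smallest code (i.e. toward DT).
    """

    DT = 0
    ST_A = 1
    ST_B = 2
    R = 3

    @property
    def code(self) -> int:
        return self.value

    @classmethod
    def from_code(cls, code: int) -> "ClassLabel":
        return cls(code)

    @classmethod
    def from_string(cls, text: str) -> "ClassLabel":
        """Parse a label from its name or common aliases like ``ST(A)``."""
        key = text.strip().upper().replace("(", "_").replace(")", "").rstrip("_")
        aliases = {"DT": cls.DT, "ST_A": cls.ST_A, "ST_B": cls.ST_B, "R": cls.R,
                   "RANDOM": cls.R, "STA": cls.ST_A, "STB": cls.ST_B}
        if key not in aliases:
            raise ValueError(f"unknown class label: {text!r}")
        return aliases[key]


CLASS_ORDER: tuple[ClassLabel, ...] = (
    ClassLabel.DT,
    ClassLabel.ST_A,
    ClassLabel.ST_B,
    ClassLabel.R,
)


class StructureError(ValueError):
    """Raised when a structure string cannot be parsed or sanitized."""


@dataclass
class AnnotatedMolecule:
    """A parsed structure with canonical form, optional label, and id.

    ``canonical_key`` is the canonical SMILES of the largest fragment with
    stereochemistry removed; two inputs encoding the same structure always
    share the same key.
    """

    structure: Chem.Mol
    canonical_key: str
    label: ClassLabel | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.structure.GetNumHeavyAtoms() < 1:
            raise StructureError("molecule has no heavy atoms")

    @property
    def num_heavy_atoms(self) -> int:
        return self.structure.GetNumHeavyAtoms()

    def with_label(self, label: ClassLabel) -> "AnnotatedMolecule":
        return AnnotatedMolecule(self.structure, self.canonical_key, label, self.source_id)


def parse_structure(text: str, label: ClassLabel | None = None, source_id: str = "") -> AnnotatedMolecule:
    """Parse a SMILES string into an :class:`AnnotatedMolecule`.

    Salts are stripped to the largest fragment (by heavy-atom count) and
    stereochemistry is discarded: attributions downstream are atom-level
    and stereo-agnostic, so a single stereo-insensitive canonical key per
    connectivity graph is the reproducible convention.

    Raises
    ------
    StructureError
        If the string is empty, unparseable, or chemically invalid.
    """
    if not text or not text.strip():
        raise StructureError("empty structure string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureError(f"could not parse structure: {text!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    Chem.RemoveStereochemistry(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise StructureError(f"sanitization failed for {text!r}: {exc}") from exc
    key = Chem.MolToSmiles(mol)
    return AnnotatedMolecule(structure=mol, canonical_key=key, label=label, source_id=source_id)


@dataclass
class ActivityRecord:
    """One activity measurement for one compound, as curated upstream."""

    compound: AnnotatedMolecule
    potency_value: float | None  # µM
    potency_type: str | None  # Ki / Kd / IC50
    relation: str | None
    mass_da: float | None
    confidence_score: int | None
    activity_comment: str = ""


#: The comment phrases that disqualify a record, matched case-insensitively
#: as substrings of the activity comment.
DEFAULT_BLOCKED_COMMENTS: frozenset[str] = frozenset(
    {"inactive", "not active", "inconclusive", "potential transcription error"}
)

STANDARD_POTENCY_TYPES: frozenset[str] = frozenset({"Ki", "Kd", "IC50"})


def apply_curation_filters(
    records: Sequence[ActivityRecord],
    max_mass_da: float = 1000.0,
    potency_cutoff_um: float = 10.0,
    required_confidence: int = 9,
    blocked_comments: Iterable[str] = DEFAULT_BLOCKED_COMMENTS,
    relation_required: str = "=",
    keep_potent: bool = True,
) -> tuple[list[ActivityRecord], dict[str, int]]:
    """Apply the compound-curation filters; return kept records and an audit.

    A record is kept iff it passes *all* filters, applied in this order for
    audit attribution: malformed fields, activity comment not blocked,
    mass below ``max_mass_da``, standard potency type, exact relation,
    exact confidence score, and the potency criterion.  With the default
    ``keep_potent=True`` the potency filter keeps records with
    ``potency_value <= potency_cutoff_um`` (activity at 10 µM or better);
    setting it False inverts the direction.

    Returns
    -------
    (kept, audit)
        ``audit`` maps filter name to the number of removals it caused
        (each removal attributed to the first failing filter).
    """
    blocked = tuple(p.lower() for p in blocked_comments)
    audit = {
        "malformed": 0,
        "comment": 0,
        "mass": 0,
        "potency_type": 0,
        "relation": 0,
        "confidence": 0,
        "potency": 0,
    }
    kept: list[ActivityRecord] = []
    for rec in records:
        required = (rec.potency_value, rec.potency_type, rec.relation, rec.mass_da,
                    rec.confidence_score)
        if any(v is None for v in required) or rec.potency_value <= 0 or rec.mass_da <= 0:
            audit["malformed"] += 1
            continue
        comment = (rec.activity_comment or "").lower()
        if any(p in comment for p in blocked):
            audit["comment"] += 1
            continue
        if not rec.mass_da < max_mass_da:
            audit["mass"] += 1
            continue
        if rec.potency_type not in STANDARD_POTENCY_TYPES:
            audit["potency_type"] += 1
            continue
        if rec.relation != relation_required:
            audit["relation"] += 1
            continue
        if rec.confidence_score != required_confidence:
            audit["confidence"] += 1
            continue
        potent = rec.potency_value <= potency_cutoff_um
        if potent != keep_potent:
            audit["potency"] += 1
            continue
        kept.append(rec)
    return kept, audit


@dataclass
class MulticlassDataset:
    """A labeled compound collection covering the four prediction classes."""

    entries: list[AnnotatedMolecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.label is None:
                raise ValueError(f"unlabeled entry: {e.source_id or e.canonical_key}")

    @property
    def class_counts(self) -> dict[ClassLabel, int]:
        counts = {label: 0 for label in CLASS_ORDER}
        for e in self.entries:
            counts[e.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, indices: Sequence[int]) -> "MulticlassDataset":
        return MulticlassDataset([self.entries[i] for i in indices])

    def labels_as_codes(self) -> list[int]:
        return [e.label.code for e in self.entries]


def balance_by_undersampling(dataset: MulticlassDataset, seed: int) -> MulticlassDataset:
    """Balance class sizes by randomly undersampling majority classes.

    All classes are reduced to the minimum class count; removals are drawn
    uniformly at random under ``seed`` and the surviving entries keep their
    original order.  A minimum-count class is never touched.
    """
    counts = dataset.class_counts
    for label, n in counts.items():
        if n == 0:
            raise ValueError(f"class {label.name} has no members")
    n_min = min(counts.values())
    rng = random.Random(seed)
    keep: set[int] = set()
    for label in CLASS_ORDER:
        idx = [i for i, e in enumerate(dataset.entries) if e.label == label]
        if len(idx) > n_min:
            idx = rng.sample(idx, n_min)
        keep.update(idx)
    return MulticlassDataset([e for i, e in enumerate(dataset.entries) if i in keep])


# ---------------------------------------------------------------------------
# Readers / writers


def read_smi(path: str | Path) -> list[AnnotatedMolecule]:
    """Read a .smi file: one ``SMILES [id]`` per line, '#' comments allowed."""
    mols = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        source_id = parts[1].strip() if len(parts) > 1 else f"line{line_no}"
        mols.append(parse_structure(smiles, source_id=source_id))
    return mols


def write_smi(mols: Iterable[AnnotatedMolecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.canonical_key} {m.source_id}\n".rstrip() + "\n")


def read_csv(path: str | Path) -> MulticlassDataset:
    """Read a labeled dataset from CSV with columns ``smiles,label[,id]``."""
    entries = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            label = ClassLabel.from_string(row["label"])
            source_id = row.get("id") or f"cpd{i}"
            entries.append(parse_structure(row["smiles"], label=label, source_id=source_id))
    return MulticlassDataset(entries)


def write_csv(dataset: MulticlassDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "label", "id"])
        for e in dataset.entries:
            writer.writerow([e.canonical_key, e.label.name, e.source_id])


def read_sdf(path: str | Path) -> list[AnnotatedMolecule]:
    """Read structures from an SDF file (label from a ``label`` property if set)."""
    mols = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        label = None
        if mol.HasProp("label"):
            label = ClassLabel.from_string(mol.GetProp("label"))
        source_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
        mols.append(parse_structure(Chem.MolToSmiles(mol), label=label, source_id=source_id))
    return mols


def write_audit_json(audit: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(audit, indent=2, sort_keys=True) + "\n")
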