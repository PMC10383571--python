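"""Four-class molecular benchmarks with planted class-discriminative motifs.

The generator emulates the statistical structure that the explanation
pipeline assumes in real dual-target data: dual-target (DT) compounds
carry two planted substituent motifs, single-target compounds carry one
(motif A for ST_A, motif B for ST_B), and random (R) compounds carry
none; all classes share a common scaffold/decoy chemistry so that only
the motifs are class-discriminative.  The default motifs echo the
aliphatic nitrogen heterocycles typically enriched in dual-target
actives (a methylpiperidine and a phenylpiperazine).

Label noise is structural: with probability ``noise`` a required motif is
omitted while the label is kept, decoupling structure from label the way
mislabeled records would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import random

from rdkit import Chem

from chemlens.chemdata import (
    AnnotatedMolecule,
    ClassLabel,
    MulticlassDataset,
    parse_structure,
)

DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "[*:1]c1cc([*:2])cc([*:3])c1",              # benzene-1,3,5
    "[*:1]c1ccc([*:2])c([*:3])c1",              # benzene-1,2,4
    "[*:1]c1ccc2cc([*:2])c([*:3])cc2c1",        # naphthalene
    "[*:1]c1ccc(-c2ccc([*:2])c([*:3])c2)cc1",   # biphenyl
    "[*:1]c1cc([*:2])cnc1",                     # pyridine
    "[*:1]c1csc([*:2])c1",                      # thiophene
    "[*:1]C1CCC([*:2])CC1",                     # cyclohexane
)

DEFAULT_DECOYS: tuple[str, ...] = (
    "[*]F",
    "[*]Cl",
    "[*]C",
    "[*]CC",
    "[*]OC",
    "[*]O",
    "[*]C(C)C",
    "[*]C(N)=O",
    "[*]C#N",
)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Configuration of one planted-motif benchmark.

    ``noise`` is the per-motif probability that a required motif is
    omitted (label unchanged).  Motifs must be valid substituents, be
    structurally distinct, and occur in no scaffold or decoy.
    """

    motif_a: str = "[*]N1CCC(C)CC1"              # 4-methylpiperidin-1-yl
    motif_b: str = "[*]N1CCN(c2ccccc2)CC1"       # 4-phenylpiperazin-1-yl
    scaffold_library: tuple[str, ...] = DEFAULT_SCAFFOLDS
    decoy_library: tuple[str, ...] = DEFAULT_DECOYS
    n_per_class: int = 100
    noise: float = 0.0
    decoy_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be a probability")
        qa, qb = self.motif_query("A"), self.motif_query("B")
        if Chem.MolToSmiles(qa) == Chem.MolToSmiles(qb):
            raise ValueError("motif_a and motif_b must be structurally distinct")
        for library, name in ((self.scaffold_library, "scaffold"), (self.decoy_library, "decoy")):
            for smi in library:
                bare = _strip_dummies(smi)
                if bare.HasSubstructMatch(qa) or bare.HasSubstructMatch(qb):
                    raise ValueError(f"{name} {smi!r} contains a planted motif")
        for smi in self.scaffold_library:
            if _count_sites(smi) < 2:
                raise ValueError(f"scaffold {smi!r} has fewer than 2 substitutable sites")

    def motif_query(self, which: str) -> Chem.Mol:
        """The motif as a substructure query molecule (dummy removed)."""
        smi = {"A": self.motif_a, "B": self.motif_b}[which]
        return _strip_dummies(smi)


def _strip_dummies(frag_smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(frag_smiles)
    if mol is None:
        raise ValueError(f"invalid fragment SMILES: {frag_smiles!r}")
    bare = Chem.DeleteSubstructs(mol, Chem.MolFromSmarts("[#0]"))
    Chem.SanitizeMol(bare)
    return bare


def _count_sites(scaffold_smiles: str) -> int:
    mol = Chem.MolFromSmiles(scaffold_smiles)
    if mol is None:
        raise ValueError(f"invalid scaffold SMILES: {scaffold_smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def _site_labels(scaffold_smiles: str) -> list[int]:
    mol = Chem.MolFromSmiles(scaffold_smiles)
    return sorted(a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def _assemble(scaffold_smiles: str, site_fragments: dict[int, str | None]) -> str | None:
    """Zip substituents onto the scaffold's numbered sites; None caps with H."""
    pieces = [Chem.MolFromSmiles(scaffold_smiles)]
    for label, frag in site_fragments.items():
        smi = (frag or "[*][H]").replace("[*]", f"[*:{label}]", 1)
        mol = Chem.MolFromSmiles(smi, sanitize=frag is not None)
        if mol is None:
            return None
        pieces.append(mol)
    combined = pieces[0]
    for p in pieces[1:]:
        combined = Chem.CombineMols(combined, p)
    try:
        product = Chem.RemoveHs(Chem.molzip(combined))
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return Chem.MolToSmiles(product)


def generate_benchmark(spec: BenchmarkSpec) -> MulticlassDataset:
    """Generate a balanced, deduplicated four-class benchmark set.

    DT = scaffold + motif A + motif B (+ decoys); ST_A/ST_B = scaffold +
    one motif (+ decoys); R = scaffold + decoys only.  Under ``noise`` > 0
    each required motif is independently omitted with that probability,
    with the label unchanged.  Deterministic given ``spec.seed``;
    deduplication is per class (structural label noise may legitimately
    duplicate structures across classes).
    """
    rng = random.Random(spec.seed)
    requirements = {
        ClassLabel.DT: ("A", "B"),
        ClassLabel.ST_A: ("A",),
        ClassLabel.ST_B: ("B",),
        ClassLabel.R: (),
    }
    motif_smiles = {"A": spec.motif_a, "B": spec.motif_b}
    entries: list[AnnotatedMolecule] = []
    for label, required in requirements.items():
        seen: set[str] = set()
        for produced in range(spec.n_per_class):
            # the motif-omission draw happens once per compound so the noise
            # rate stays binomial; only scaffold/decoy choices are re-rolled
            # when an assembly collides with an earlier structure
            motifs = [m for m in required if rng.random() >= spec.noise]
            smiles = None
            for _ in range(500):
                scaffold = rng.choice(spec.scaffold_library)
                sites = _site_labels(scaffold)
                rng.shuffle(sites)
                if len(motifs) > len(sites):
                    continue
                assignment: dict[int, str | None] = {}
                for m, site in zip(motifs, sites):
                    assignment[site] = motif_smiles[m]
                for site in sites[len(motifs):]:
                    use_decoy = rng.random() < spec.decoy_probability
                    assignment[site] = rng.choice(spec.decoy_library) if use_decoy else None
                candidate = _assemble(scaffold, assignment)
                if candidate is not None and candidate not in seen:
                    smiles = candidate
                    break
            if smiles is None:
                raise RuntimeError(
                    f"could not generate {spec.n_per_class} unique {label.name} compounds; "
                    "enlarge the scaffold or decoy libraries"
                )
            seen.add(smiles)
            entries.append(
                parse_structure(smiles, label=label, source_id=f"{label.name}_{produced:04d}")
            )
    return MulticlassDataset(entries)


@dataclass
class MotifGroundTruth:
    """Atom index sets of each planted motif for one compound."""

    source_id: str
    motif_a_atoms: frozenset[int] = field(default_factory=frozenset)
    motif_b_atoms: frozenset[int] = field(default_factory=frozenset)

    @property
    def all_motif_atoms(self) -> frozenset[int]:
        return self.motif_a_atoms | self.motif_b_atoms


def benchmark_ground_truth(
    spec: BenchmarkSpec, dataset: MulticlassDataset
) -> list[MotifGroundTruth]:
    """Locate planted motif atoms in every compound via substructure matching.

    The union over all matches is reported per motif; in symmetric cases
    (e.g. the phenylpiperazine's two equivalent ring nitrogens) this may
    extend slightly beyond the planted copy, which is the faithful
    substructure-level read-out.
    """
    qa, qb = spec.motif_query("A"), spec.motif_query("B")
    out = []
    for entry in dataset.entries:
        atoms_a: set[int] = set()
        atoms_b: set[int] = set()
        for match in entry.structure.GetSubstructMatches(qa):
            atoms_a.update(match)
        for match in entry.structure.GetSubstructMatches(qb):
            atoms_b.update(match)
        out.append(
            MotifGroundTruth(entry.source_id, frozenset(atoms_a), frozenset(atoms_b))
        )
    return out


def ground_truth_to_json(truths: Sequence[MotifGroundTruth], path: str | Path) -> None:
    payload = {
        t.source_id: {"motif_a": sorted(t.motif_a_atoms), "motif_b": sorted(t.motif_b_atoms)}
        for t in truths
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
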