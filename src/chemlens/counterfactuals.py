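"""Counterfactual search: analogue generation, prediction, qualification.

A counterfactual (CF) of a correctly predicted single-target base compound
is a close structural analogue whose predicted class flips to the target
class (dual-target).  Narrow chemical space around a base is populated by
pluggable generator strategies; every candidate is fingerprinted and
predicted, and qualification simply means the target class wins the
argmax.  No similarity cutoff is applied by default — similarity is
recorded for ranking and optional post-filtering.

Two built-in strategies:

* :func:`mutate_string_analogues` — point edits (substitute / insert /
  delete) on the tokenized SMILES string, keeping only candidates that
  parse and sanitize; every emitted candidate is chemically valid.
* :func:`transform_analogues` — medicinal-chemistry style substituent
  edits: attach a library substituent at an H-bearing site, replace a
  terminal substituent with one, or delete a terminal substituent.
  :func:`substituents_from_actives` derives the library from substituents
  frequently observed in active compounds, so the edits are not specific
  to any one prediction task.
"""

from __future__ import annotations

import csv
import hashlib
import random
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from chemlens.chemdata import AnnotatedMolecule, ClassLabel, StructureError, parse_structure
from chemlens.fingerprints import Fingerprint, fingerprint_molecule, tanimoto
from chemlens.model import ClassProbabilities, TrainedModel, assign_class, predict_probabilities

# SMILES tokenization: bracket atoms, two-letter organic-subset elements,
# single-letter atoms (aromatic included), bonds, branches, ring closures.
_SMILES_TOKEN = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOSPFIbcnops]|[=#\-+\\/()]|\d)"
)

#: Tokens drawn on for substitutions/insertions: the common organic subset.
MUTATION_ALPHABET: tuple[str, ...] = (
    "C", "N", "O", "F", "S", "Cl", "Br", "c", "n", "o", "s", "=", "#", "(", ")", "1", "2",
)


def tokenize_smiles(smiles: str) -> list[str]:
    tokens = _SMILES_TOKEN.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"cannot tokenize SMILES: {smiles!r}")
    return tokens


def _try_parse(smiles: str) -> AnnotatedMolecule | None:
    try:
        return parse_structure(smiles)
    except StructureError:
        return None


def mutate_string_analogues(
    base: AnnotatedMolecule,
    n_candidates: int = 1000,
    mutations_per_candidate: tuple[int, int] = (1, 3),
    seed: int = 0,
    max_attempts_factor: int = 40,
) -> list[AnnotatedMolecule]:
    """Generate analogues by random point edits of the base SMILES tokens.

    Each attempt applies k ∈ ``mutations_per_candidate`` random token
    substitutions, insertions or deletions and keeps the result only if it
    parses and sanitizes, so every emitted candidate is valid.  Output is
    deduplicated by canonical key, excludes the base, and is deterministic
    given ``seed``.
    """
    if n_candidates <= 0:
        return []
    lo, hi = mutations_per_candidate
    if lo < 1 or hi < lo:
        raise ValueError("mutations_per_candidate must be a non-empty positive range")
    base_tokens = tokenize_smiles(base.canonical_key)
    if _try_parse("".join(base_tokens)) is None:  # round-trip guard
        raise StructureError(f"base SMILES does not round-trip: {base.canonical_key!r}")
    rng = random.Random(seed)
    seen = {base.canonical_key}
    out: list[AnnotatedMolecule] = []
    attempts = 0
    max_attempts = max_attempts_factor * n_candidates
    while len(out) < n_candidates and attempts < max_attempts:
        attempts += 1
        tokens = list(base_tokens)
        for _ in range(rng.randint(lo, hi)):
            op = rng.choice(("substitute", "insert", "delete"))
            if op == "substitute" and tokens:
                tokens[rng.randrange(len(tokens))] = rng.choice(MUTATION_ALPHABET)
            elif op == "insert":
                tokens.insert(rng.randrange(len(tokens) + 1), rng.choice(MUTATION_ALPHABET))
            elif op == "delete" and len(tokens) > 1:
                tokens.pop(rng.randrange(len(tokens)))
        mol = _try_parse("".join(tokens))
        if mol is None or mol.canonical_key in seen:
            continue
        seen.add(mol.canonical_key)
        mol.source_id = f"{base.source_id}:mut{len(out)}"
        out.append(mol)
    return out


#: Curated default substituent library (attachment point = dummy atom).
DEFAULT_FRAGMENT_LIBRARY: tuple[str, ...] = (
    "[*]F",                      # fluoro
    "[*]Cl",                     # chloro
    "[*]Br",                     # bromo
    "[*]C",                      # methyl
    "[*]OC",                     # methoxy
    "[*]C(N)=O",                 # amide
    "[*]c1ccccc1",               # phenyl
    "[*]Cc1ccccc1",              # benzyl
    "[*]N1CCCCC1",               # piperidinyl
    "[*]N1CCNCC1",               # piperazinyl
    "[*]N1CCOCC1",               # morpholinyl
    "[*]N1CCC1",                 # azetidinyl
    "[*]S(N)(=O)=O",             # sulfonamide
)


def _fragment_mol(frag_smiles: str) -> Chem.Mol:
    """Parse a substituent SMILES whose attachment point is a dummy atom."""
    mol = Chem.MolFromSmiles(frag_smiles)
    if mol is None:
        raise ValueError(f"invalid fragment SMILES: {frag_smiles!r}")
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError(f"fragment must have exactly one attachment dummy: {frag_smiles!r}")
    return mol


def _attach(mol: Chem.Mol, atom_idx: int, frag: Chem.Mol) -> str | None:
    """Bond a fragment's attachment neighbor to ``atom_idx``; return SMILES or None."""
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    offset = mol.GetNumAtoms()
    dummy = next(a.GetIdx() for a in frag.GetAtoms() if a.GetAtomicNum() == 0)
    anchor = frag.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    combined.AddBond(atom_idx, offset + anchor, Chem.BondType.SINGLE)
    combined.RemoveAtom(offset + dummy)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def _substitutable_sites(mol: Chem.Mol) -> list[int]:
    """H-bearing heavy atoms that are not ring junctions."""
    ring_info = mol.GetRingInfo()
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() >= 1 and ring_info.NumAtomRings(a.GetIdx()) <= 1
    ]


def _terminal_substituent_cuts(mol: Chem.Mol, max_heavy: int = 12) -> list[tuple[int, int]]:
    """Acyclic single bonds whose smaller side is a removable substituent.

    Returns (keep_atom, cut_atom) pairs: ``cut_atom`` starts the fragment
    to remove (≤ ``max_heavy`` heavy atoms).
    """
    cuts = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        em = Chem.RWMol(mol)
        em.RemoveBond(i, j)
        frags = Chem.GetMolFrags(em.GetMol())
        if len(frags) != 2:
            continue
        side_i = next(f for f in frags if i in f)
        side_j = next(f for f in frags if j in f)
        if len(side_j) < len(side_i) and len(side_j) <= max_heavy:
            cuts.append((i, j))
        elif len(side_i) < len(side_j) and len(side_i) <= max_heavy:
            cuts.append((j, i))
    return cuts


def _delete_substituent(mol: Chem.Mol, keep_atom: int, cut_atom: int) -> str | None:
    em = Chem.RWMol(mol)
    em.RemoveBond(keep_atom, cut_atom)
    frags = Chem.GetMolFrags(em.GetMol(), asMols=False)
    drop = next(f for f in frags if cut_atom in f)
    for idx in sorted(drop, reverse=True):
        em.RemoveAtom(idx)
    try:
        out = em.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if out.GetNumHeavyAtoms() < 1:
        return None
    return Chem.MolToSmiles(out)


def transform_analogues(
    base: AnnotatedMolecule,
    fragment_library: Sequence[str] = DEFAULT_FRAGMENT_LIBRARY,
    seed: int = 0,
    operations: Sequence[str] = ("attach", "replace", "delete"),
    max_candidates: int | None = 1000,
) -> list[AnnotatedMolecule]:
    """Substituent-level analogues: attach / replace / delete library groups.

    Enumerates all edits deterministically, deduplicates by canonical key,
    then (if over budget) subsamples under ``seed``.  A base with no
    substitutable site yields an empty list, not an error.
    """
    if not fragment_library:
        raise ValueError("fragment library must be non-empty")
    frags = [_fragment_mol(s) for s in fragment_library]
    mol = base.structure
    smiles_out: list[str] = []
    if "attach" in operations:
        for site in _substitutable_sites(mol):
            for frag in frags:
                smi = _attach(mol, site, frag)
                if smi:
                    smiles_out.append(smi)
    cuts = _terminal_substituent_cuts(mol) if {"replace", "delete"} & set(operations) else []
    for keep_atom, cut_atom in cuts:
        trimmed_smi = _delete_substituent(mol, keep_atom, cut_atom)
        if trimmed_smi is None:
            continue
        if "delete" in operations:
            smiles_out.append(trimmed_smi)
        if "replace" in operations:
            trimmed = Chem.MolFromSmiles(trimmed_smi)
            if trimmed is None:
                continue
            for site in _substitutable_sites(trimmed):
                for frag in frags:
                    smi = _attach(trimmed, site, frag)
                    if smi:
                        smiles_out.append(smi)
    seen = {base.canonical_key}
    out = []
    for smi in smiles_out:
        cand = _try_parse(smi)
        if cand is None or cand.canonical_key in seen:
            continue
        seen.add(cand.canonical_key)
        out.append(cand)
    if max_candidates is not None and len(out) > max_candidates:
        rng = random.Random(seed)
        out = rng.sample(out, max_candidates)
        out.sort(key=lambda m: m.canonical_key)
    for i, cand in enumerate(out):
        cand.source_id = f"{base.source_id}:tf{i}"
    return out


def substituents_from_actives(
    mols: Sequence[AnnotatedMolecule],
    max_heavy: int = 16,
    top_k: int = 20,
) -> list[str]:
    """Extract the most frequent terminal substituents from active compounds.

    Every acyclic single bond is cut; the smaller side (≤ ``max_heavy``
    heavy atoms) is recorded as a dummy-tagged substituent SMILES.  The
    ``top_k`` by frequency (ties by SMILES) form a task-agnostic fragment
    library for :func:`transform_analogues`.
    """
    counts: dict[str, int] = {}
    for m in mols:
        mol = m.structure
        for keep_atom, cut_atom in _terminal_substituent_cuts(mol, max_heavy=max_heavy):
            em = Chem.RWMol(mol)
            em.RemoveBond(keep_atom, cut_atom)
            dummy = em.AddAtom(Chem.Atom(0))
            em.AddBond(cut_atom, dummy, Chem.BondType.SINGLE)
            frags = Chem.GetMolFrags(em.GetMol(), asMols=True, sanitizeFrags=False)
            sub = next((f for f in frags if any(a.GetAtomicNum() == 0 for a in f.GetAtoms())), None)
            if sub is None or sub.GetNumHeavyAtoms() > max_heavy:
                continue
            try:
                Chem.SanitizeMol(sub)
            except Exception:
                continue
            smi = Chem.MolToSmiles(sub)
            counts[smi] = counts.get(smi, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [smi for smi, _ in ranked[:top_k]]


def derive_generation_seed(base: AnnotatedMolecule, base_seed: int) -> int:
    """Stable per-compound seed: hash of (canonical key, base seed), < 2^31."""
    digest = hashlib.sha256(f"{base.canonical_key}|{base_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class CounterfactualRecord:
    """One predicted analogue of a base compound, qualified or not."""

    base: AnnotatedMolecule
    base_probabilities: ClassProbabilities
    candidate: AnnotatedMolecule
    probabilities: ClassProbabilities
    qualified: bool
    similarity: float
    generator_tag: str = ""

    def __post_init__(self) -> None:
        if self.candidate.canonical_key == self.base.canonical_key:
            raise ValueError("candidate must differ from the base compound")


def find_counterfactuals(
    model: TrainedModel,
    base: AnnotatedMolecule,
    target_class: ClassLabel,
    candidates: Sequence[AnnotatedMolecule],
    n_bits: int = 4096,
    max_radius: int = 2,
    generator_tag: str = "",
    base_fp: Fingerprint | None = None,
) -> list[CounterfactualRecord]:
    """Predict all candidates and flag those whose argmax class is the target.

    Returns records for *all* candidates; the qualified subset (argmax ==
    ``target_class``) comes first, sorted by descending similarity to the
    base, ties by descending target-class probability, then canonical key.
    The base must not itself be predicted as the target class.
    """
    base_fp = base_fp or fingerprint_molecule(base, n_bits, max_radius)
    base_probs = predict_probabilities(model, base_fp)
    if assign_class(base_probs) == target_class:
        raise ValueError(
            f"base compound is already predicted as {target_class.name}: not a counterfactual setting"
        )
    records = []
    for cand in candidates:
        fp = fingerprint_molecule(cand, n_bits, max_radius)
        probs = predict_probabilities(model, fp)
        records.append(
            CounterfactualRecord(
                base=base,
                base_probabilities=base_probs,
                candidate=cand,
                probabilities=probs,
                qualified=assign_class(probs) == target_class,
                similarity=tanimoto(base_fp, fp),
                generator_tag=generator_tag,
            )
        )
    records.sort(
        key=lambda r: (
            not r.qualified,
            -r.similarity,
            -r.probabilities[target_class],
            r.candidate.canonical_key,
        )
    )
    return records


def records_to_csv(records: Sequence[CounterfactualRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["base_id", "base_smiles", "candidate_smiles", "P_DT", "P_ST_A", "P_ST_B", "P_R",
             "qualified", "similarity", "generator_tag"]
        )
        for r in records:
            writer.writerow(
                [r.base.source_id, r.base.canonical_key, r.candidate.canonical_key]
                + [repr(float(p)) for p in r.probabilities.p]
                + [int(r.qualified), repr(r.similarity), r.generator_tag]
            )
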