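"""Atom-level feature mapping: project per-bit attributions onto atoms.

Each set fingerprint bit carries an attribution φ for the target class.
The bit's φ is split equally among the atom environments that set it
(folding-collision apportionment, which conserves the bit's mass), and
each environment's share is assigned in full to every atom it covers; an
atom participating in several environments accumulates their shares.
Only present features are mapped — absent-feature attributions have no
atoms to receive them.  Maps are normalized per molecule to [−1, 1] and
rendered on a diverging blue–white–red scale (red supports the target
class).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from matplotlib import colormaps
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from chemlens.chemdata import AnnotatedMolecule, ClassLabel
from chemlens.fingerprints import Fingerprint
from chemlens.shapley import ShapExplanation


@dataclass
class AtomAttributionMap:
    """Per-atom summed attribution values for one molecule and one class."""

    molecule: AnnotatedMolecule
    target_class: ClassLabel
    raw: np.ndarray  # (n_atoms,)
    normalized: np.ndarray | None = None


def atom_attributions(
    mol: AnnotatedMolecule,
    fp: Fingerprint,
    expl: ShapExplanation,
    target_class: ClassLabel,
) -> AtomAttributionMap:
    """Sum bit attributions onto atoms via the fingerprint's provenance map.

    Conservation identity (holds exactly): the total over atoms equals
    Σ over set bits of φ_bit · (Σ_env |atoms(env)|) / n_envs(bit).
    """
    n_atoms = mol.structure.GetNumAtoms()
    raw = np.zeros(n_atoms)
    phi = expl.phi[target_class.code]
    for b in fp.on_bits:
        envs = fp.provenance.get(int(b))
        if not envs:
            raise ValueError(f"set bit {int(b)} has no provenance: corrupt fingerprint")
        share = phi[int(b)] / len(envs)
        for env in envs:
            for atom in env.atom_indices:
                raw[atom] += share
    return AtomAttributionMap(molecule=mol, target_class=target_class, raw=raw)


def conservation_residual(amap: AtomAttributionMap, fp: Fingerprint, expl: ShapExplanation) -> float:
    """|Σ atoms − Σ bits φ·(mean env size apportionment)|; 0 up to float error."""
    phi = expl.phi[amap.target_class.code]
    expected = 0.0
    for b in fp.on_bits:
        envs = fp.provenance[int(b)]
        expected += phi[int(b)] * sum(len(e.atom_indices) for e in envs) / len(envs)
    return abs(float(amap.raw.sum()) - expected)


def normalize_attributions(amap: AtomAttributionMap) -> AtomAttributionMap:
    """Symmetric max-abs scaling into [−1, 1]; an all-zero map stays zero."""
    peak = float(np.max(np.abs(amap.raw))) if amap.raw.size else 0.0
    normalized = amap.raw / peak if peak > 0 else np.zeros_like(amap.raw)
    return AtomAttributionMap(amap.molecule, amap.target_class, amap.raw.copy(), normalized)


def render_depiction(
    amap: AtomAttributionMap,
    out_path: str | Path,
    probability: float | None = None,
    size: tuple[int, int] = (400, 350),
) -> Path:
    """Write an SVG depiction with atoms shaded blue–white–red by attribution.

    Red atoms support the target-class prediction, blue atoms oppose it;
    unhighlighted atoms carry zero attribution.  The legend reports
    P(target class) when given.  Output is deterministic for fixed input.
    """
    if amap.normalized is None:
        amap = normalize_attributions(amap)
    cmap = colormaps["bwr"]
    colors = {}
    for idx, v in enumerate(amap.normalized):
        if v == 0.0:
            continue
        r, g, b, _ = cmap(0.5 * (float(v) + 1.0))
        colors[idx] = (r, g, b)
    drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    legend = f"P({amap.target_class.name}) = {probability:.2f}" if probability is not None else ""
    mol = Chem.Mol(amap.molecule.structure)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer,
        mol,
        legend=legend,
        highlightAtoms=sorted(colors),
        highlightAtomColors=colors,
        highlightBonds=[],
    )
    drawer.FinishDrawing()
    out = Path(out_path)
    try:
        out.write_text(drawer.GetDrawingText())
    except OSError as exc:
        raise OSError(f"cannot write depiction to {out}: {exc}") from exc
    return out


def attributions_to_csv(
    maps: Sequence[AtomAttributionMap], path: str | Path
) -> None:
    """Per-atom attribution table: compound id, atom index, element, raw, normalized."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "atom_index", "element", "raw", "normalized"])
        for amap in maps:
            norm = amap.normalized
            if norm is None:
                norm = normalize_attributions(amap).normalized
            for i, atom in enumerate(amap.molecule.structure.GetAtoms()):
                writer.writerow(
                    [amap.molecule.source_id, i, atom.GetSymbol(),
                     repr(float(amap.raw[i])), repr(float(norm[i]))]
                )


def compare_substructure_enrichment(
    set_a: Sequence[AnnotatedMolecule],
    set_b: Sequence[AnnotatedMolecule],
    patterns: Sequence[str],
) -> list[dict]:
    """Per-SMARTS fractions in two compound sets and their difference.

    The classic read-out: substructures driving counterfactual predictions
    should be preferentially found in actual dual-target compounds.
    """
    if not set_a or not set_b:
        raise ValueError("both compound sets must be non-empty")
    rows = []
    for pattern in patterns:
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise ValueError(f"invalid SMARTS pattern: {pattern!r}")
        frac_a = sum(1 for m in set_a if m.structure.HasSubstructMatch(query)) / len(set_a)
        frac_b = sum(1 for m in set_b if m.structure.HasSubstructMatch(query)) / len(set_b)
        rows.append(
            {"pattern": pattern, "fraction_a": frac_a, "fraction_b": frac_b,
             "difference": frac_a - frac_b}
        )
    return rows
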