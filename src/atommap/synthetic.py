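"""Synthetic mapped reactions with ground truth known by construction.

Each :class:`SyntheticTemplate` is a small reaction core written as mapped
SMILES with numbered dummy attachment points (``[1*]``, ``[2*]``) plus a
substituent vocabulary per slot.  Assembling a core with sampled
substituents yields a fully mapped, valence-legal reaction whose
ground-truth atom map is carried by the map numbers — so every downstream
module (filters, CGR equivalence, template extraction, the mapper network,
the active-learning loop) can be exercised without any external data.

Substituent vocabularies are deliberately chosen so the atoms at distance
<= 1 from the reaction center are invariant within a template (e.g. ester
O-substituents always attach through a CH2): all reactions generated from
one template then share a single canonical extended-local template.

``corrupt`` plants controlled errors: ``wrong_atom_source`` re-sources a
product atom from a chemically plausible but wrong reactant atom (the
classic leaking-group-vs-water oxygen confusion in hydrolysis),
``equivalent_relabel`` permutes homotopic atoms, and ``shuffled_numbers``
renumbers map labels only — the latter two are CGR-equivalent by design.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .cgr import aam_equivalent
from .mapping import AtomMapping
from .reaction_io import ReactionRecord, parse_reaction

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTemplate",
    "default_templates",
    "generate",
    "corrupt",
    "CorruptionError",
]


class CorruptionError(ValueError):
    """The requested corruption mode does not apply to this example."""


# attachment is always atom 0 of the fragment SMILES; the whole vocabulary
# stays small (<= 12 unique fragments) so the fixture suite runs in minutes.
#
# identifiability constraint: the mapper's reactant embeddings come from a
# 3-layer MPNN, so two atoms with identical 3-bond environments in different
# contexts are indistinguishable in principle.  Fragments are therefore kept
# short/branched (every atom within 3 bonds of a distinguishing feature),
# and the two coupling partners draw from vocabularies whose attachment
# environments differ, mirroring how real substrates are locally
# distinguishable.  Atoms that are genuinely interchangeable (homotopic)
# remain, and are handled by CGR equivalence, not avoided.
# decodability constraint: the greedy decoder resolves exactly-tied cells
# independently, so a *multi-atom* homotopic group (the two halves of a
# mirror-symmetric ring, twin methoxy arms of a symmetric acetal) can decode
# into a "chimera" that mixes the two orientations and is no automorphism.
# Substrates therefore avoid multi-atom symmetric groups — rings carry a
# meta substituent — while single-atom homotopic pairs (gem-dimethyls),
# where any tie resolution is an automorphism, are kept on purpose.
_ALKYL_CH2 = ("CC", "CCC", "CC(C)C")
_ARYL = (
    "c1cccc(C)c1",
    "c1cccc(F)c1",
    "c1cccc(CC)c1",
    "c1cccc(C(C)C)c1",
)
_COUPLING_A = ("C", "C(C)C", "CC")

_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "alkyl_ch2": _ALKYL_CH2,
    "aryl": _ARYL,
    "coupling_a": _COUPLING_A,
}


@dataclass(frozen=True)
class SyntheticTemplate:
    """A reaction core with numbered dummies plus per-slot vocabularies.

    ``reactant_cores``/``product_cores`` are mapped SMILES; map numbers
    shared across the two sides define the ground-truth correspondence.
    ``slots`` maps each dummy label to a vocabulary key.
    ``expected_bond_changes`` is the bond-change count of the gold CGR,
    fixed by the core alone.
    """

    name: str
    reactant_cores: tuple[str, ...]
    product_cores: tuple[str, ...]
    slots: dict[int, str] = field(default_factory=dict)
    expected_bond_changes: int = 0


def default_templates() -> list[SyntheticTemplate]:
    """Eight organic reaction classes with known atom provenance.

    Hydrolyses and condensations encode the mechanistically correct oxygen
    provenance (the water oxygen ends up in the acid / carbonyl product),
    which is exactly the atom the corruption mode swaps.
    """
    return [
        SyntheticTemplate(
            name="ester_hydrolysis",
            reactant_cores=("[1*][C:1](=[O:2])[O:3][2*]", "[OH2:4]"),
            product_cores=("[1*][C:1](=[O:2])[OH:4]", "[OH:3][2*]"),
            slots={1: "alkyl_ch2", 2: "alkyl_ch2"},
            expected_bond_changes=2,
        ),
        SyntheticTemplate(
            name="esterification",
            reactant_cores=("[1*][C:1](=[O:2])[OH:3]", "[OH:4][2*]"),
            product_cores=("[1*][C:1](=[O:2])[O:4][2*]", "[OH2:3]"),
            slots={1: "alkyl_ch2", 2: "alkyl_ch2"},
            expected_bond_changes=2,
        ),
        SyntheticTemplate(
            # mixed methyl/ethyl acetal: the two alkoxy arms are
            # distinguishable, so the gold oxygen provenance is unambiguous
            name="acetal_hydrolysis",
            reactant_cores=(
                "[1*][CH:1]([O:2][CH3:3])[O:4][CH2:5][CH3:6]",
                "[OH2:7]",
            ),
            product_cores=(
                "[1*][CH:1]=[O:7]",
                "[OH:2][CH3:3]",
                "[OH:4][CH2:5][CH3:6]",
            ),
            slots={1: "alkyl_ch2"},
            expected_bond_changes=3,
        ),
        SyntheticTemplate(
            name="sn2_halide",
            reactant_cores=("[1*][CH2:1][Br:2]", "[I-:3]"),
            product_cores=("[1*][CH2:1][I:3]",),
            slots={1: "alkyl_ch2"},
            expected_bond_changes=2,
        ),
        SyntheticTemplate(
            name="amide_coupling",
            reactant_cores=("[1*][C:1](=[O:2])[OH:3]", "[NH2:4][2*]"),
            product_cores=("[1*][C:1](=[O:2])[NH:4][2*]", "[OH2:3]"),
            slots={1: "alkyl_ch2", 2: "alkyl_ch2"},
            expected_bond_changes=2,
        ),
        SyntheticTemplate(
            name="nitro_reduction",
            reactant_cores=("[1*][N+:1](=[O:2])[O-:3]",),
            product_cores=("[1*][NH2:1]",),
            slots={1: "aryl"},
            expected_bond_changes=2,
        ),
        SyntheticTemplate(
            # aryl bromide + 3-pyridylboronic acid: the ring nitrogen sits
            # inside the ring, so every atom of either partner is within
            # three bonds of a feature identifying its ring; both rings are
            # asymmetric (meta substituent / meta nitrogen)
            name="suzuki_coupling",
            reactant_cores=(
                "[Br:1][c:2]1[cH:3][c:4]([1*])[cH:5][cH:6][cH:7]1",
                "[B:8]([OH:9])([OH:10])[c:11]1[cH:12][n:13][cH:14][cH:15][cH:16]1",
            ),
            product_cores=(
                "[c:2]1([c:11]2[cH:12][n:13][cH:14][cH:15][cH:16]2)"
                "[cH:3][c:4]([1*])[cH:5][cH:6][cH:7]1",
            ),
            slots={1: "coupling_a"},
            # aryl-Br and aryl-B bonds break, the biaryl bond forms
            expected_bond_changes=3,
        ),
        SyntheticTemplate(
            name="imine_condensation",
            reactant_cores=("[1*][CH:1]=[O:2]", "[NH2:3][2*]"),
            product_cores=("[1*][CH:1]=[N:3][2*]", "[OH2:2]"),
            slots={1: "aryl", 2: "alkyl_ch2"},
            expected_bond_changes=2,
        ),
    ]


def _mapped_fragment(smiles: str, base: int) -> Chem.Mol:
    frag = Chem.MolFromSmiles(smiles)
    if frag is None:
        raise ValueError(f"bad substituent SMILES {smiles!r}")
    for i, atom in enumerate(frag.GetAtoms()):
        atom.SetAtomMapNum(base + i)
    return frag


def _assemble(core_smiles: str, fragments: dict[int, Chem.Mol]) -> Chem.Mol:
    """Replace each numbered dummy by its slot fragment (bond to atom 0)."""
    mol = Chem.MolFromSmiles(core_smiles)
    if mol is None:
        raise ValueError(f"bad core SMILES {core_smiles!r}")
    rw = Chem.RWMol(mol)
    while True:
        dummy = next(
            (a for a in rw.GetAtoms() if a.GetAtomicNum() == 0), None
        )
        if dummy is None:
            break
        slot = dummy.GetIsotope()
        frag = fragments[slot]
        neighbors = dummy.GetNeighbors()
        if len(neighbors) != 1:
            raise ValueError("dummy attachment points must have one neighbor")
        nbr_idx = neighbors[0].GetIdx()
        dummy_idx = dummy.GetIdx()
        offset = rw.GetNumAtoms()
        rw = Chem.RWMol(Chem.CombineMols(rw.GetMol(), frag))
        rw.AddBond(nbr_idx, offset, Chem.BondType.SINGLE)
        rw.RemoveAtom(dummy_idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _shuffled_smiles(mol: Chem.Mol, rng: np.random.Generator) -> str:
    perm = rng.permutation(mol.GetNumAtoms()).tolist()
    shuffled = Chem.RenumberAtoms(mol, perm)
    return Chem.MolToSmiles(shuffled, canonical=False)


def _realize(
    template: SyntheticTemplate,
    substituents: dict[int, str],
    rng: np.random.Generator,
    reaction_id: str,
) -> tuple[ReactionRecord, AtomMapping]:
    fragments = {
        slot: _mapped_fragment(smiles, base=100 * slot)
        for slot, smiles in substituents.items()
    }
    reactants = [_assemble(c, fragments) for c in template.reactant_cores]
    products = [_assemble(c, fragments) for c in template.product_cores]
    # randomize map labels so nothing downstream can key on their values
    old_numbers = sorted(
        {
            a.GetAtomMapNum()
            for m in itertools.chain(reactants, products)
            for a in m.GetAtoms()
            if a.GetAtomMapNum() > 0
        }
    )
    new_numbers = rng.permutation(len(old_numbers)) + 1
    relabel = dict(zip(old_numbers, (int(x) for x in new_numbers)))
    for mol in itertools.chain(reactants, products):
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum() > 0:
                atom.SetAtomMapNum(relabel[atom.GetAtomMapNum()])
    text = (
        ".".join(_shuffled_smiles(m, rng) for m in reactants)
        + ">>"
        + ".".join(_shuffled_smiles(m, rng) for m in products)
    )
    record = parse_reaction(text, reaction_id)
    gold = record.given_mapping
    if gold is None or not gold.is_total_over(record.n_product_atoms):
        raise ValueError(f"template {template.name} produced a partial mapping")
    return record, gold


def generate(
    templates: list[SyntheticTemplate] | None = None,
    n: int = 100,
    seed: int = 0,
) -> list[tuple[ReactionRecord, AtomMapping, str]]:
    """Sample ``n`` mapped reactions uniformly over (template, substituents).

    Deterministic given ``seed``; atom orders are shuffled per record.
    Combinations yielding invalid molecules are skipped with a log message.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    templates = templates if templates is not None else default_templates()
    rng = np.random.default_rng(seed)
    out: list[tuple[ReactionRecord, AtomMapping, str]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n:
            raise RuntimeError("generator failed to produce enough valid reactions")
        template = templates[int(rng.integers(len(templates)))]
        substituents = {
            slot: _VOCABULARIES[key][int(rng.integers(len(_VOCABULARIES[key])))]
            for slot, key in template.slots.items()
        }
        rid = f"synth-{len(out):05d}"
        try:
            record, gold = _realize(template, substituents, rng, rid)
        except (ValueError, RuntimeError) as exc:
            logger.warning(
                "skipping %s with %s: %s", template.name, substituents, exc
            )
            continue
        out.append((record, gold, template.name))
    return out


# --- controlled corruptions ---------------------------------------------


def _reactant_automorphisms(record: ReactionRecord) -> list[tuple[int, ...]]:
    combined = record.reactant_molecules[0]
    for m in record.reactant_molecules[1:]:
        combined = Chem.CombineMols(combined, m)
    combined = Chem.Mol(combined)
    for a in combined.GetAtoms():
        a.SetAtomMapNum(0)
    return list(
        combined.GetSubstructMatches(
            combined, uniquify=False, useChirality=True, maxMatches=256
        )
    )


def corrupt(
    example: tuple[ReactionRecord, AtomMapping],
    mode: str,
    seed: int = 0,
) -> tuple[ReactionRecord, AtomMapping]:
    """Return the record with a corrupted (or harmlessly relabeled) mapping.

    ``wrong_atom_source``: move one product atom's provenance to a same-
    element but incorrect reactant atom, verified non-equivalent to gold.
    ``equivalent_relabel``: compose the mapping with a non-trivial reactant
    automorphism (homotopic-atom permutation).  ``shuffled_numbers``:
    permute the serialized map numbers only.
    """
    record, gold = example
    rng = np.random.default_rng(seed)
    if mode == "shuffled_numbers":
        perm = rng.permutation(len(gold)) + 1
        return record, gold.renumbered(tuple(int(x) for x in perm))
    if mode == "equivalent_relabel":
        # keep only automorphisms that actually move some mapped atom — a
        # permutation of spectators alone would leave the mapping unchanged
        autos = []
        for a in _reactant_automorphisms(record):
            pairs = tuple((p, a[r]) for p, r in gold.pairs)
            if pairs != gold.pairs:
                autos.append(pairs)
        if not autos:
            raise CorruptionError(
                "no reactant automorphism moves a mapped atom"
            )
        pairs = autos[int(rng.integers(len(autos)))]
        return record, AtomMapping(pairs, gold.map_numbers)
    if mode == "wrong_atom_source":
        used = {r for _, r in gold.pairs}
        # candidates: re-source one product atom from an unused same-element
        # reactant atom, or swap the sources of two same-element product atoms
        resource = []
        for p, r in gold.pairs:
            element = record.reactant_atom(r).GetSymbol()
            for r2 in range(record.n_reactant_atoms):
                if r2 in used or record.reactant_atom(r2).GetSymbol() != element:
                    continue
                resource.append(("move", p, r2))
        swaps = []
        for i, (p1, r1) in enumerate(gold.pairs):
            e1 = record.reactant_atom(r1).GetSymbol()
            for p2, r2 in gold.pairs[i + 1 :]:
                if record.reactant_atom(r2).GetSymbol() == e1:
                    swaps.append(("swap", p1, p2))
        candidates = resource + swaps
        rng.shuffle(candidates)
        for kind, a, b in candidates:
            if kind == "move":
                pairs = tuple(
                    (pp, b if pp == a else rr) for pp, rr in gold.pairs
                )
            else:
                p2r = gold.product_to_reactant
                swap = {a: p2r[b], b: p2r[a]}
                pairs = tuple(
                    (pp, swap.get(pp, rr)) for pp, rr in gold.pairs
                )
            wrong = AtomMapping(pairs, gold.map_numbers)
            if not aam_equivalent(wrong, gold, record):
                return record, wrong
        raise CorruptionError(
            "no chemically plausible wrong atom source for this example"
        )
    raise ValueError(f"unknown corruption mode {mode!r}")
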