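"""Reaction parsing, validation, filtering, and mapped-SMILES serialization.

A reaction SMILES ``reactants>agents>products`` is parsed into a
:class:`ReactionRecord` holding RDKit molecules.  Agents from the middle
field are stored with the reactants (they may donate atoms — water in a
hydrolysis is a mapped reactant) but flagged so they are never *required*
to map.  Only heavy atoms are considered throughout; hydrogens stay
implicit.

Two dataset-cleaning rules are provided for judging a dataset's recorded
mapping before evaluation:

* ``invalid_product_mapping`` — a product atom without a map number, or two
  product atoms sharing one;
* ``confusing_reagent`` — a reactant that contributes no atom to the product
  yet is structurally similar (Tanimoto >= 0.5, Morgan radius 2, 2048 bits)
  to a product molecule.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, DataStructs

from .mapping import AtomMapping

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ReactionRecord",
    "FilterVerdict",
    "FilterReason",
    "ReactionParseError",
    "parse_reaction",
    "check_product_mapping",
    "check_confusing_reagents",
    "filter_reaction",
    "write_mapped_smiles",
    "read_reactions",
    "write_reactions",
]

TANIMOTO_REAGENT_THRESHOLD = 0.5
_MORGAN_RADIUS = 2
_MORGAN_NBITS = 2048


class ReactionParseError(ValueError):
    """The text is not a parseable reaction SMILES."""


class FilterReason(str, enum.Enum):
    clean = "clean"
    invalid_product_mapping = "invalid_product_mapping"
    confusing_reagent = "confusing_reagent"
    unparseable = "unparseable"


@dataclass(frozen=True)
class FilterVerdict:
    keep: bool
    reason: FilterReason

    def __post_init__(self) -> None:
        if self.keep != (self.reason == FilterReason.clean):
            raise ValueError("keep must be true iff reason is clean")


@dataclass
class ReactionRecord:
    """A parsed reaction: reactant and product molecules plus optional map.

    Atom indices used everywhere downstream are *global* heavy-atom indices
    into the concatenation of ``reactant_molecules`` (reactants first, then
    agents) and of ``product_molecules`` respectively, in RDKit atom order.
    """

    reaction_id: str
    reactant_molecules: list[Chem.Mol]
    product_molecules: list[Chem.Mol]
    raw_text: str
    given_mapping: Optional[AtomMapping] = None
    agent_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.agent_flags:
            self.agent_flags = [False] * len(self.reactant_molecules)

    # --- global-index helpers -------------------------------------------
    @property
    def reactant_offsets(self) -> list[int]:
        offs, total = [], 0
        for m in self.reactant_molecules:
            offs.append(total)
            total += m.GetNumAtoms()
        return offs

    @property
    def product_offsets(self) -> list[int]:
        offs, total = [], 0
        for m in self.product_molecules:
            offs.append(total)
            total += m.GetNumAtoms()
        return offs

    @property
    def n_reactant_atoms(self) -> int:
        return sum(m.GetNumAtoms() for m in self.reactant_molecules)

    @property
    def n_product_atoms(self) -> int:
        return sum(m.GetNumAtoms() for m in self.product_molecules)

    @property
    def reactant_elements(self) -> tuple[str, ...]:
        return tuple(
            a.GetSymbol() for m in self.reactant_molecules for a in m.GetAtoms()
        )

    @property
    def product_elements(self) -> tuple[str, ...]:
        return tuple(
            a.GetSymbol() for m in self.product_molecules for a in m.GetAtoms()
        )

    def reactant_atom(self, global_index: int) -> Chem.Atom:
        return _atom_at(self.reactant_molecules, global_index)

    def product_atom(self, global_index: int) -> Chem.Atom:
        return _atom_at(self.product_molecules, global_index)

    def reactant_molecule_of_atom(self, global_index: int) -> int:
        return _mol_of(self.reactant_molecules, global_index)


def _atom_at(mols: Sequence[Chem.Mol], idx: int) -> Chem.Atom:
    for m in mols:
        n = m.GetNumAtoms()
        if idx < n:
            return m.GetAtomWithIdx(idx)
        idx -= n
    raise IndexError("atom index out of range")


def _mol_of(mols: Sequence[Chem.Mol], idx: int) -> int:
    for i, m in enumerate(mols):
        n = m.GetNumAtoms()
        if idx < n:
            return i
        idx -= n
    raise IndexError("atom index out of range")


def parse_reaction(text: str, reaction_id: str = "") -> ReactionRecord:
    """Parse a reaction SMILES into a :class:`ReactionRecord`.

    The middle (agent) field is stored with the reactants, flagged as agent.
    A given mapping is extracted from atom-map numbers when every mapped
    product atom has exactly one reactant partner carrying the same number.

    Raises
    ------
    ReactionParseError
        On malformed text or unparseable molecules; callers batch-filtering
        a dataset catch this and record an ``unparseable`` verdict.
    """
    text = text.strip()
    parts = text.split(">")
    if len(parts) != 3:
        raise ReactionParseError(f"expected 'reactants>agents>products': {text!r}")
    reactant_field, agent_field, product_field = parts

    def _mols(smiles_field: str, side: str) -> list[Chem.Mol]:
        if not smiles_field:
            return []
        mols = []
        for smi in smiles_field.split("."):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ReactionParseError(f"unparseable {side} SMILES {smi!r}")
            mols.append(mol)
        return mols

    reactants = _mols(reactant_field, "reactant")
    agents = _mols(agent_field, "agent")
    products = _mols(product_field, "product")
    if not reactants or not products:
        raise ReactionParseError(
            "reaction must have at least one reactant and one product"
        )
    flags = [False] * len(reactants) + [True] * len(agents)
    record = ReactionRecord(
        reaction_id=reaction_id or "",
        reactant_molecules=reactants + agents,
        product_molecules=products,
        raw_text=text,
        agent_flags=flags,
    )
    record.given_mapping = _extract_given_mapping(record)
    return record


def _extract_given_mapping(record: ReactionRecord) -> Optional[AtomMapping]:
    r_by_num: dict[int, list[int]] = {}
    for gi in range(record.n_reactant_atoms):
        num = record.reactant_atom(gi).GetAtomMapNum()
        if num > 0:
            r_by_num.setdefault(num, []).append(gi)
    pairs, numbers = [], []
    for gi in range(record.n_product_atoms):
        num = record.product_atom(gi).GetAtomMapNum()
        if num <= 0:
            continue
        partners = r_by_num.get(num, [])
        if len(partners) != 1:
            return None  # missing or ambiguous partner: no usable mapping
        pairs.append((gi, partners[0]))
        numbers.append(num)
    if not pairs:
        return None
    try:
        return AtomMapping(tuple(pairs), tuple(numbers))
    except ValueError:
        return None  # e.g. repeated product map numbers break injectivity


def check_product_mapping(record: ReactionRecord) -> FilterVerdict:
    """Reject records whose *recorded* product mapping is unusable as truth:
    any product heavy atom without a map number, or a duplicated number."""
    seen: set[int] = set()
    for gi in range(record.n_product_atoms):
        num = record.product_atom(gi).GetAtomMapNum()
        if num <= 0 or num in seen:
            return FilterVerdict(False, FilterReason.invalid_product_mapping)
        seen.add(num)
    return FilterVerdict(True, FilterReason.clean)


def _fingerprint(mol: Chem.Mol):
    clean = Chem.Mol(mol)
    for atom in clean.GetAtoms():
        atom.SetAtomMapNum(0)
    return AllChem.GetMorganFingerprintAsBitVect(
        clean, _MORGAN_RADIUS, nBits=_MORGAN_NBITS
    )


def check_confusing_reagents(
    record: ReactionRecord,
    mapping: Optional[AtomMapping] = None,
    threshold: float = TANIMOTO_REAGENT_THRESHOLD,
) -> FilterVerdict:
    """Reject records with a non-participating reactant that looks like the
    product.

    A reactant molecule participates when it contributes at least one mapped
    atom under ``mapping`` (default: the record's given mapping).  A
    non-participating reactant whose Morgan-fingerprint Tanimoto similarity
    to any product molecule reaches ``threshold`` makes the record ambiguous
    for mapping evaluation.
    """
    mapping = mapping if mapping is not None else record.given_mapping
    if mapping is None:
        raise ValueError("a given or predicted mapping is required")
    participating = {
        record.reactant_molecule_of_atom(r) for _, r in mapping.pairs
    }
    product_fps = [_fingerprint(m) for m in record.product_molecules]
    for i, mol in enumerate(record.reactant_molecules):
        if i in participating:
            continue
        fp = _fingerprint(mol)
        for pfp in product_fps:
            if DataStructs.TanimotoSimilarity(fp, pfp) >= threshold:
                return FilterVerdict(False, FilterReason.confusing_reagent)
    return FilterVerdict(True, FilterReason.clean)


def filter_reaction(text: str, reaction_id: str = "") -> FilterVerdict:
    """Combined dataset filter for one raw reaction SMILES.

    Checks are independent; when several fail, the reported reason follows
    the fixed priority unparseable > invalid_product_mapping >
    confusing_reagent so that verdicts are reproducible.
    """
    try:
        record = parse_reaction(text, reaction_id)
    except ReactionParseError:
        return FilterVerdict(False, FilterReason.unparseable)
    verdict = check_product_mapping(record)
    if not verdict.keep:
        return verdict
    if record.given_mapping is None:
        # fully mapped product but no usable mapping (numbers missing on the
        # reactant side): treat as invalid recorded mapping
        return FilterVerdict(False, FilterReason.invalid_product_mapping)
    return check_confusing_reagents(record)


def write_mapped_smiles(record: ReactionRecord, mapping: AtomMapping) -> str:
    """Serialize the record with ``mapping`` as atom-map numbers.

    Every mapped pair shares one positive number; spectator reactant atoms
    carry none.  The output round-trips through :func:`parse_reaction` to an
    equivalent mapping.
    """
    if not mapping.is_total_over(record.n_product_atoms):
        raise ValueError("mapping must cover every product heavy atom")
    if any(r >= record.n_reactant_atoms or r < 0 for _, r in mapping.pairs):
        raise ValueError("mapping references a reactant atom out of range")
    r_mols = [Chem.Mol(m) for m in record.reactant_molecules]
    p_mols = [Chem.Mol(m) for m in record.product_molecules]
    for mols in (r_mols, p_mols):
        for m in mols:
            for a in m.GetAtoms():
                a.SetAtomMapNum(0)
    for (p, r), num in zip(mapping.pairs, mapping.map_numbers):
        _atom_at(p_mols, p).SetAtomMapNum(num)
        _atom_at(r_mols, r).SetAtomMapNum(num)
    reactant_smi = ".".join(Chem.MolToSmiles(m) for m in r_mols)
    product_smi = ".".join(Chem.MolToSmiles(m) for m in p_mols)
    return f"{reactant_smi}>>{product_smi}"


# --- file I/O -----------------------------------------------------------


def read_reactions(path: str | Path) -> list[tuple[str, str]]:
    """Read ``(id, reaction_smiles)`` rows from a ``.csv`` (columns
    ``id,rxn_smiles``) or a plain one-reaction-per-line file."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    if path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "rxn_smiles" not in reader.fieldnames:
                raise ValueError("CSV must have columns id,rxn_smiles")
            for i, row in enumerate(reader):
                rows.append((row.get("id") or str(i), row["rxn_smiles"]))
    else:
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if line:
                    rows.append((str(i), line))
    return rows


def write_reactions(
    path: str | Path, rows: Iterable[tuple[str, str]], csv_format: Optional[bool] = None
) -> None:
    path = Path(path)
    if csv_format is None:
        csv_format = path.suffix.lower() == ".csv"
    with path.open("w", newline="", encoding="utf-8") as fh:
        if csv_format:
            writer = csv.writer(fh)
            writer.writerow(["id", "rxn_smiles"])
            writer.writerows(rows)
        else:
            for _, smi in rows:
                fh.write(smi + "\n")
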