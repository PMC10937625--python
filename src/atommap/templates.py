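"""Extended-local reaction templates (ELRT) and the verified-template library.

A local reaction template is the subgraph rewrite at the reaction center —
the atoms whose bonds, charges or hydrogen counts change under the atom
map.  The *extended* template additionally pulls in chemically important
functional groups (carbonyl, acetal, nitrile, ...) that share an atom with
or sit directly on the center, which makes the pattern expressive enough to
distinguish e.g. ester hydrolysis from plain ether cleavage.

The canonical pattern string is the library key and the sole authority for
knowledge-based prediction confidence: a predicted mapping is *confident*
iff its extracted template is already present in the library and was
verified by a human labeler, otherwise *uncertain*.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml
from rdkit import Chem

from .cgr import build_cgr
from .mapping import AtomMapping
from .reaction_io import ReactionRecord

__all__ = [
    "ReactionTemplate",
    "TemplateEntry",
    "TemplateLibrary",
    "NullReactionError",
    "load_group_catalog",
    "extract_elrt",
    "classify_confidence",
    "update_library",
]


class NullReactionError(ValueError):
    """The mapping implies no chemical change at all."""


@dataclass(frozen=True)
class ReactionTemplate:
    canonical_pattern: str
    center_size: int
    extension_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.center_size < 1:
            raise ValueError("center_size must be >= 1")


@dataclass
class TemplateEntry:
    verified: bool
    reaction_count: int
    first_seen_iteration: int = 0
    provenance: str = ""


@dataclass
class TemplateLibrary:
    entries: dict[str, TemplateEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pattern: str) -> bool:
        return pattern in self.entries

    def verified_patterns(self) -> set[str]:
        return {p for p, e in self.entries.items() if e.verified}

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["canonical_pattern", "verified", "reaction_count", "iteration", "labeler"]
            )
            for pattern in sorted(self.entries):
                e = self.entries[pattern]
                writer.writerow(
                    [pattern, int(e.verified), e.reaction_count,
                     e.first_seen_iteration, e.provenance]
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TemplateLibrary":
        lib = cls()
        with Path(path).open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                lib.entries[row["canonical_pattern"]] = TemplateEntry(
                    verified=bool(int(row["verified"])),
                    reaction_count=int(row["reaction_count"]),
                    first_seen_iteration=int(row["iteration"]),
                    provenance=row["labeler"],
                )
        return lib


def load_group_catalog(path: Optional[str | Path] = None) -> dict[str, list[str]]:
    """Load the functional-group SMARTS catalog (name -> SMARTS list).

    Without ``path`` the catalog shipped with the package is used.
    """
    if path is None:
        text = (
            resources.files("atommap").joinpath("data/functional_groups.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    catalog: dict[str, list[str]] = {}
    for name, patterns in raw.items():
        if isinstance(patterns, str):
            patterns = [patterns]
        catalog[str(name)] = [str(p) for p in patterns]
    return catalog


_DEFAULT_CATALOG: Optional[dict[str, list[str]]] = None


def _default_catalog() -> dict[str, list[str]]:
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = load_group_catalog()
    return _DEFAULT_CATALOG


def _combine(mols: Sequence[Chem.Mol]) -> Chem.Mol:
    combined = mols[0]
    for m in mols[1:]:
        combined = Chem.CombineMols(combined, m)
    combined = Chem.Mol(combined)
    for a in combined.GetAtoms():
        a.SetAtomMapNum(0)
    return combined


def _extension_atoms(
    mol: Chem.Mol, center: set[int], catalog: dict[str, list[str]]
) -> tuple[set[int], set[str]]:
    """Atoms of catalog groups sharing an atom with, or bonded to, the center."""
    neighbourhood = set(center)
    for idx in center:
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            neighbourhood.add(nb.GetIdx())
    extension: set[int] = set()
    names: set[str] = set()
    for name, patterns in catalog.items():
        for smarts in patterns:
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"bad SMARTS for group {name!r}: {smarts}")
            for match in mol.GetSubstructMatches(query):
                if set(match) & neighbourhood:
                    extension.update(match)
                    names.add(name)
    return extension - center, names


def _fragment_smiles(mol: Chem.Mol, atoms: Sequence[int]) -> str:
    return Chem.MolFragmentToSmiles(mol, atomsToUse=list(atoms), canonical=True)


def _canonical_order(
    mol: Chem.Mol, atoms: set[int], isotope_tags: Optional[dict[int, int]] = None
) -> list[int]:
    """Atoms in the canonical output order of the (map-free) fragment SMILES.

    ``isotope_tags`` are scratch invariants (set as isotopes on a copy) that
    let cross-side information break symmetry ties; they never appear in the
    written pattern.
    """
    bare = Chem.Mol(mol)
    for a in bare.GetAtoms():
        a.SetAtomMapNum(0)
        if isotope_tags is not None:
            a.SetIsotope(isotope_tags.get(a.GetIdx(), 0))
    Chem.MolFragmentToSmiles(bare, atomsToUse=sorted(atoms), canonical=True)
    raw = bare.GetProp("_smilesAtomOutputOrder").strip("[]")
    order = [int(x) for x in raw.split(",") if x]
    return [i for i in order if i in atoms]


def extract_elrt(
    record: ReactionRecord,
    mapping: AtomMapping,
    group_catalog: Optional[dict[str, list[str]]] = None,
) -> ReactionTemplate:
    """Extract the extended-local reaction template of a mapped reaction.

    The center is every atom incident to a bond whose order changes, plus
    atoms whose formal charge or hydrogen count changes (so a pure
    reduction still has a center).  Catalog functional groups overlapping
    or adjacent to the center are appended.  The pattern is canonicalized
    by renumbering template atom maps in canonical fragment order, so the
    same chemistry always yields the same string regardless of input atom
    order or original map labels.
    """
    catalog = group_catalog if group_catalog is not None else _default_catalog()
    cgr = build_cgr(record, mapping)
    g = cgr.graph

    center_nodes: set = set()
    for u, v, d in g.edges(data=True):
        if d["order_before"] != d["order_after"]:
            # ignore inert spectator-spectator bonds (never "changed" by
            # construction, but keep the guard explicit)
            center_nodes.update((u, v))
    for n, d in g.nodes(data=True):
        if d["spectator"]:
            continue
        if d["charge_before"] != d["charge_after"] or d["h_before"] != d["h_after"]:
            center_nodes.add(n)
    if not center_nodes:
        raise NullReactionError("mapping implies no chemical change (null reaction)")

    p2r = mapping.product_to_reactant
    r_center: set[int] = set()
    p_center: set[int] = set()
    for kind, idx in center_nodes:
        if kind == "m":
            p_center.add(idx)
            r_center.add(p2r[idx])
        else:
            r_center.add(idx)

    r_mol = _combine(record.reactant_molecules)
    p_mol = _combine(record.product_molecules)
    r_ext, r_names = _extension_atoms(r_mol, r_center, catalog)
    p_ext, p_names = _extension_atoms(p_mol, p_center, catalog)
    r_atoms = r_center | r_ext
    p_atoms = p_center | p_ext

    # canonical template map numbers: product atoms first, in canonical
    # fragment order, propagated to their reactant partners; leftover
    # reactant-only atoms numbered afterwards in canonical order.  Product
    # atoms that are symmetric within their own fragment (e.g. the two aryl
    # carbons of a freshly formed biaryl bond) are disambiguated by their
    # reactant partner's canonical rank, carried over as a scratch isotope.
    r_rank = {
        idx: rank + 1
        for rank, idx in enumerate(_canonical_order(r_mol, r_atoms))
    }
    p_tags = {
        p_idx: r_rank.get(p2r[p_idx], 0)
        for p_idx in p_atoms
        if p_idx in p2r
    }
    num_of_reactant: dict[int, int] = {}
    num_of_product: dict[int, int] = {}
    next_num = 1
    for p_idx in _canonical_order(p_mol, p_atoms, isotope_tags=p_tags):
        num_of_product[p_idx] = next_num
        partner = p2r.get(p_idx)
        if partner is not None:
            num_of_reactant[partner] = next_num
        next_num += 1
    for r_idx in _canonical_order(r_mol, r_atoms):
        if r_idx not in num_of_reactant:
            num_of_reactant[r_idx] = next_num
            next_num += 1

    for idx, num in num_of_reactant.items():
        if idx in r_atoms:
            r_mol.GetAtomWithIdx(idx).SetAtomMapNum(num)
    for idx, num in num_of_product.items():
        p_mol.GetAtomWithIdx(idx).SetAtomMapNum(num)

    pattern = f"{_fragment_smiles(r_mol, sorted(r_atoms))}>>{_fragment_smiles(p_mol, sorted(p_atoms))}"
    return ReactionTemplate(
        canonical_pattern=pattern,
        center_size=len(center_nodes),
        extension_groups=tuple(sorted(r_names | p_names)),
    )


def classify_confidence(
    template: ReactionTemplate, library: TemplateLibrary
) -> str:
    """``"confident"`` iff the template is a *verified* library entry."""
    entry = library.entries.get(template.canonical_pattern)
    return "confident" if entry is not None and entry.verified else "uncertain"


def update_library(
    library: TemplateLibrary,
    templates: Sequence[tuple[ReactionTemplate, bool]],
    iteration: int = 0,
    labeler: str = "",
) -> tuple[TemplateLibrary, dict[str, int]]:
    """Fold extracted templates into the library.

    Counts are incremented per occurrence; the verified flag is monotone
    (once verified, always verified).  Returns the updated library and a
    delta report ``{new, updated, newly_verified}``.
    """
    delta = {"new": 0, "updated": 0, "newly_verified": 0}
    for template, verified in templates:
        entry = library.entries.get(template.canonical_pattern)
        if entry is None:
            library.entries[template.canonical_pattern] = TemplateEntry(
                verified=bool(verified),
                reaction_count=1,
                first_seen_iteration=iteration,
                provenance=labeler,
            )
            delta["new"] += 1
            if verified:
                delta["newly_verified"] += 1
        else:
            entry.reaction_count += 1
            if verified and not entry.verified:
                entry.verified = True
                delta["newly_verified"] += 1
            delta["updated"] += 1
    return library, delta
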