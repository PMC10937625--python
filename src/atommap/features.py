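"""Molecule featurization for the mapper network.

Reactant molecules are merged into one graph (no cross-molecule bonds),
likewise products; atom order equals the parse order of the record so that
matrix rows/columns line up with global atom indices everywhere else.

The atom/bond feature schema follows the common graph-network convention
for reaction models: element one-hot over a fixed vocabulary (with an
explicit *unknown* slot), degree, formal charge, hybridization,
aromaticity, implicit hydrogen count, ring membership, and chirality tag;
bonds carry order, conjugation, ring membership, and stereo.  The schema
is versioned: checkpoints record it and refuse to load under a different
schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .reaction_io import ReactionRecord

logger = logging.getLogger(__name__)

__all__ = ["FeatureConfig", "MolecularGraph", "featurize"]

_DEFAULT_ELEMENTS = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
    "Si", "Sn", "Li", "Mg", "Zn", "Cu", "Na", "K",
)
_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_CHI_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
_BOND_STEREO = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
)


@dataclass(frozen=True)
class FeatureConfig:
    """Versioned feature schema; changing it invalidates saved parameters."""

    elements: tuple[str, ...] = _DEFAULT_ELEMENTS
    max_degree: int = 5
    charge_range: tuple[int, int] = (-2, 2)
    max_num_h: int = 4
    version: str = "1"

    @property
    def atom_dim(self) -> int:
        n_charge = self.charge_range[1] - self.charge_range[0] + 1
        return (
            len(self.elements) + 1          # + unknown slot
            + self.max_degree + 1
            + n_charge + 1                  # + out-of-range slot
            + len(_HYBRIDIZATIONS) + 1
            + 1                             # aromatic
            + self.max_num_h + 1
            + 1                             # in ring
            + len(_CHI_TAGS) + 1
        )

    @property
    def bond_dim(self) -> int:
        return len(_BOND_TYPES) + 1 + 1 + 1 + len(_BOND_STEREO) + 1

    def schema_id(self) -> str:
        return f"v{self.version}:{','.join(self.elements)}:{self.atom_dim}x{self.bond_dim}"


def _one_hot(value, choices, unknown_slot: bool = True) -> list[float]:
    vec = [0.0] * (len(choices) + (1 if unknown_slot else 0))
    try:
        vec[list(choices).index(value)] = 1.0
    except ValueError:
        if unknown_slot:
            vec[-1] = 1.0
    return vec


@dataclass
class MolecularGraph:
    """Merged heavy-atom graph of one reaction side.

    ``src``/``dst`` list every bond twice (both directions) so a message
    from neighbor ``dst[k]`` over bond ``k`` is aggregated into ``src[k]``.
    """

    atom_features: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    bond_features: np.ndarray
    elements: tuple[str, ...]

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_directed_bonds(self) -> int:
        return self.src.shape[0]


def _atom_features(atom: Chem.Atom, cfg: FeatureConfig) -> list[float]:
    symbol = atom.GetSymbol()
    if symbol not in cfg.elements:
        logger.warning("element %s outside vocabulary; using unknown slot", symbol)
    lo, hi = cfg.charge_range
    return (
        _one_hot(symbol, cfg.elements)
        + _one_hot(min(atom.GetDegree(), cfg.max_degree),
                   range(cfg.max_degree + 1), unknown_slot=False)
        + _one_hot(atom.GetFormalCharge(), range(lo, hi + 1))
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(min(atom.GetTotalNumHs(), cfg.max_num_h),
                   range(cfg.max_num_h + 1), unknown_slot=False)
        + [1.0 if atom.IsInRing() else 0.0]
        + _one_hot(atom.GetChiralTag(), _CHI_TAGS)
    )


def _bond_features(bond: Chem.Bond) -> list[float]:
    return (
        _one_hot(bond.GetBondType(), _BOND_TYPES)
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
        + _one_hot(bond.GetStereo(), _BOND_STEREO)
    )


def _build_graph(mols, cfg: FeatureConfig) -> MolecularGraph:
    feats: list[list[float]] = []
    src: list[int] = []
    dst: list[int] = []
    bfeats: list[list[float]] = []
    elements: list[str] = []
    offset = 0
    for mol in mols:
        for atom in mol.GetAtoms():
            feats.append(_atom_features(atom, cfg))
            elements.append(atom.GetSymbol())
        for bond in mol.GetBonds():
            u = bond.GetBeginAtomIdx() + offset
            v = bond.GetEndAtomIdx() + offset
            bf = _bond_features(bond)
            src.extend((u, v))
            dst.extend((v, u))
            bfeats.extend((bf, bf))
        offset += mol.GetNumAtoms()
    return MolecularGraph(
        atom_features=np.asarray(feats, dtype=np.float64),
        src=np.asarray(src, dtype=np.intp),
        dst=np.asarray(dst, dtype=np.intp),
        bond_features=(
            np.asarray(bfeats, dtype=np.float64)
            if bfeats
            else np.zeros((0, cfg.bond_dim))
        ),
        elements=tuple(elements),
    )


def featurize(
    record: ReactionRecord, cfg: FeatureConfig | None = None
) -> tuple[MolecularGraph, MolecularGraph]:
    """Featurize a record into (reactant graph, product graph)."""
    cfg = cfg or FeatureConfig()
    return (
        _build_graph(record.reactant_molecules, cfg),
        _build_graph(record.product_molecules, cfg),
    )
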