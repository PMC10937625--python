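"""Atom maps and greedy decoding of mapping probability matrices.

The mapper network emits, for every reaction, a matrix ``P`` with one row
per product heavy atom and one column per reactant heavy atom, each row a
probability distribution ``p(reactant atom | product atom)``.  The decoder
turns that matrix into a concrete one-to-one atom map by accepting cells
from the highest probability to the lowest, skipping cells whose product
or reactant atom is already taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AtomMapping",
    "MappingProbabilityMatrix",
    "DecodeError",
    "decode_greedy",
    "confidence_score",
]


class DecodeError(ValueError):
    """Raised when no admissible reactant atom remains for a product atom."""


@dataclass(frozen=True)
class AtomMapping:
    """A bijection from product heavy atoms into a subset of reactant atoms.

    Parameters
    ----------
    pairs:
        ``(product_atom_index, reactant_atom_index)`` tuples, indices into
        the concatenated heavy-atom lists of the product and reactant sides.
    map_numbers:
        Positive integers, one per pair, used when serializing to reaction
        SMILES.  Defaults to ``1..len(pairs)`` in pair order.
    """

    pairs: tuple[tuple[int, int], ...]
    map_numbers: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        pairs = tuple((int(p), int(r)) for p, r in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        nums = tuple(int(n) for n in self.map_numbers)
        if not nums:
            nums = tuple(range(1, len(pairs) + 1))
        if len(nums) != len(pairs):
            raise ValueError("map_numbers length must match pairs")
        if any(n <= 0 for n in nums):
            raise ValueError("atom-map numbers must be positive integers")
        object.__setattr__(self, "map_numbers", nums)
        prods = [p for p, _ in pairs]
        reacts = [r for _, r in pairs]
        if len(set(prods)) != len(prods) or len(set(reacts)) != len(reacts):
            raise ValueError("mapping must be injective on both sides")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def product_to_reactant(self) -> dict[int, int]:
        return {p: r for p, r in self.pairs}

    @property
    def reactant_to_product(self) -> dict[int, int]:
        return {r: p for p, r in self.pairs}

    def map_number_of_product_atom(self, product_index: int) -> Optional[int]:
        for (p, _), n in zip(self.pairs, self.map_numbers):
            if p == product_index:
                return n
        return None

    def renumbered(self, numbers: Sequence[int]) -> "AtomMapping":
        """Same pairing with fresh map numbers (serialization labels only)."""
        return AtomMapping(self.pairs, tuple(numbers))

    def is_total_over(self, n_product_atoms: int) -> bool:
        return {p for p, _ in self.pairs} == set(range(n_product_atoms))


@dataclass
class MappingProbabilityMatrix:
    """Row-stochastic matrix ``p(reactant atom | product atom)``.

    ``product_elements`` / ``reactant_elements`` carry per-atom element
    symbols so the decoder can refuse chemically impossible cross-element
    assignments.
    """

    entries: np.ndarray
    product_elements: tuple[str, ...]
    reactant_elements: tuple[str, ...]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2:
            raise ValueError("entries must be a 2-D matrix")
        n_p, n_r = self.entries.shape
        if len(self.product_elements) != n_p or len(self.reactant_elements) != n_r:
            raise ValueError("element lists must match matrix shape")

    def validate(self, atol: float = 1e-6) -> None:
        if np.any(self.entries < -atol) or np.any(self.entries > 1 + atol):
            raise ValueError("probabilities must lie in [0, 1]")
        rows = self.entries.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=atol):
            raise ValueError("each row must sum to 1")


def decode_greedy(
    P: MappingProbabilityMatrix, enforce_element_match: bool = True
) -> AtomMapping:
    """Greedy highest-probability-first assignment of product to reactant atoms.

    All cells are visited in order of decreasing probability (ties broken by
    ascending ``(product index, reactant index)``); a cell is accepted when
    neither of its atoms has been assigned yet and, if
    ``enforce_element_match``, the two atoms are the same element.  Decoding
    stops once every product atom is assigned; reactant atoms left over are
    spectators and receive no map number.

    Raises
    ------
    DecodeError
        If some product atom has no admissible reactant atom left.
    """
    entries = P.entries
    n_p, n_r = entries.shape
    if n_r == 0:
        raise DecodeError("no reactant atoms to map onto")
    # argsort on (-p, prod, react): flatten row-major so index order is the
    # tie-break, and negate with stable sort.
    flat = entries.ravel()
    order = np.argsort(-flat, kind="stable")
    assigned_p: dict[int, int] = {}
    used_r: set[int] = set()
    for cell in order:
        if len(assigned_p) == n_p:
            break
        p, r = divmod(int(cell), n_r)
        if p in assigned_p or r in used_r:
            continue
        if enforce_element_match and P.product_elements[p] != P.reactant_elements[r]:
            continue
        assigned_p[p] = r
        used_r.add(r)
    if len(assigned_p) != n_p:
        missing = sorted(set(range(n_p)) - set(assigned_p))
        raise DecodeError(
            f"no admissible reactant atom for product atom(s) {missing} "
            f"(element(s) {[P.product_elements[m] for m in missing]})"
        )
    pairs = tuple(sorted(assigned_p.items()))
    return AtomMapping(pairs)


def confidence_score(P: MappingProbabilityMatrix, mapping: AtomMapping) -> float:
    """Product of the accepted cells' probabilities.

    A model-internal diagnostic only: the knowledge-based confident /
    uncertain classification lives in the template engine.
    """
    score = 1.0
    for p, r in mapping.pairs:
        score *= float(P.entries[p, r])
    return score
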