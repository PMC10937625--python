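"""Condensed graph of reaction (CGR) construction and mapping evaluation.

A CGR superposes the reactant and product graphs of a mapped reaction into
one graph whose bonds carry a *before* and an *after* order (0 = absent)
and whose atoms carry before/after formal charge and hydrogen count.  Two
atom maps of the same reaction are judged equivalent when their CGRs are
isomorphic respecting those labels — the standard device for not punishing
a model that maps one of two homotopic atoms the "other" way.

Also here: the number-of-bond-changes statistic and the calibrated
accuracy that combines dataset-based accuracy on unconfident predictions
with manually verified accuracy on confident ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
from networkx.algorithms.isomorphism import categorical_edge_match, categorical_node_match

from .mapping import AtomMapping
from .reaction_io import ReactionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CondensedGraphOfReaction",
    "AccuracyReport",
    "build_cgr",
    "count_bond_changes",
    "aam_equivalent",
    "calibrated_accuracy",
    "evaluate",
]


@dataclass
class CondensedGraphOfReaction:
    """Superposed reactant/product graph.

    ``graph`` is an undirected NetworkX graph.  Node attributes: ``element``,
    ``charge_before``, ``charge_after``, ``h_before``, ``h_after``,
    ``spectator`` (reactant atom with no product image).  Edge attributes:
    ``order_before``, ``order_after`` as floats (aromatic = 1.5, absent = 0).
    """

    graph: nx.Graph

    def changed_bonds(self) -> list[tuple]:
        return [
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d["order_before"] != d["order_after"]
        ]

    def mapped_subgraph(self) -> nx.Graph:
        keep = [n for n, d in self.graph.nodes(data=True) if not d["spectator"]]
        return self.graph.subgraph(keep).copy()


def build_cgr(
    record: ReactionRecord,
    mapping: AtomMapping,
    include_h_labels: bool = True,
) -> CondensedGraphOfReaction:
    """Build the CGR of ``record`` under ``mapping``.

    Mapped atoms get before-state from their reactant partner and
    after-state from the product atom.  Spectator reactant atoms are kept:
    their bonds to mapped atoms are broken bonds (order_after = 0), while
    bonds inside fully-spectator molecules are carried unchanged so an inert
    bystander contributes no bond change.

    The mapping must be injective and total over product heavy atoms.
    """
    if not mapping.is_total_over(record.n_product_atoms):
        raise ValueError("mapping must cover every product heavy atom")
    p2r = mapping.product_to_reactant
    r2p = mapping.reactant_to_product

    g = nx.Graph()
    for p_gi, r_gi in p2r.items():
        ra = record.reactant_atom(r_gi)
        pa = record.product_atom(p_gi)
        if ra.GetSymbol() != pa.GetSymbol():
            logger.warning(
                "mapping pairs %s with %s in reaction %s",
                ra.GetSymbol(), pa.GetSymbol(), record.reaction_id,
            )
        g.add_node(
            ("m", p_gi),
            element=pa.GetSymbol(),
            charge_before=ra.GetFormalCharge(),
            charge_after=pa.GetFormalCharge(),
            h_before=ra.GetTotalNumHs() if include_h_labels else 0,
            h_after=pa.GetTotalNumHs() if include_h_labels else 0,
            spectator=False,
        )
    for r_gi in range(record.n_reactant_atoms):
        if r_gi in r2p:
            continue
        ra = record.reactant_atom(r_gi)
        g.add_node(
            ("s", r_gi),
            element=ra.GetSymbol(),
            charge_before=ra.GetFormalCharge(),
            charge_after=ra.GetFormalCharge(),
            h_before=ra.GetTotalNumHs() if include_h_labels else 0,
            h_after=ra.GetTotalNumHs() if include_h_labels else 0,
            spectator=True,
        )

    def _node_of_reactant(r_gi: int):
        return ("m", r2p[r_gi]) if r_gi in r2p else ("s", r_gi)

    # product-side bonds: order_after, with order_before looked up between
    # the reactant partners (0 when they sit in different molecules or are
    # simply not bonded before the reaction)
    r_order = _bond_orders(record.reactant_molecules)
    p_order = _bond_orders(record.product_molecules)
    for (pu, pv), order in p_order.items():
        before = r_order.get(_key(p2r[pu], p2r[pv]), 0.0)
        g.add_edge(("m", pu), ("m", pv), order_before=before, order_after=order)
    # reactant-side bonds not covered above
    for (ru, rv), order in r_order.items():
        nu, nv = _node_of_reactant(ru), _node_of_reactant(rv)
        if g.has_edge(nu, nv):
            continue
        both_spectator = nu[0] == "s" and nv[0] == "s"
        after = order if both_spectator else 0.0
        g.add_edge(nu, nv, order_before=order, order_after=after)
    return CondensedGraphOfReaction(g)


def _key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


def _bond_orders(mols: Sequence) -> dict[tuple[int, int], float]:
    orders: dict[tuple[int, int], float] = {}
    offset = 0
    for mol in mols:
        for bond in mol.GetBonds():
            u = bond.GetBeginAtomIdx() + offset
            v = bond.GetEndAtomIdx() + offset
            orders[_key(u, v)] = bond.GetBondTypeAsDouble()
        offset += mol.GetNumAtoms()
    return orders


def count_bond_changes(cgr: CondensedGraphOfReaction) -> int:
    """Number of heavy-atom bonds whose order differs before vs after.

    Hydrogen-count changes are atom-label changes, not bond changes.
    """
    return len(cgr.changed_bonds())


def _labelled_copy(g: nx.Graph) -> nx.Graph:
    h = nx.Graph()
    for n, d in g.nodes(data=True):
        h.add_node(
            n,
            label=(
                d["element"],
                d["charge_before"],
                d["charge_after"],
                d["h_before"],
                d["h_after"],
            ),
        )
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, label=(d["order_before"], d["order_after"]))
    return h


def _hash(g: nx.Graph) -> str:
    gh = nx.Graph()
    for n, d in g.nodes(data=True):
        gh.add_node(n, label=str(d["label"]))
    for u, v, d in g.edges(data=True):
        gh.add_edge(u, v, label=str(d["label"]))
    return nx.weisfeiler_lehman_graph_hash(
        gh, node_attr="label", edge_attr="label", iterations=3
    )


def cgr_isomorphic(
    a: CondensedGraphOfReaction, b: CondensedGraphOfReaction
) -> bool:
    ga, gb = _labelled_copy(a.graph), _labelled_copy(b.graph)
    if ga.number_of_nodes() != gb.number_of_nodes():
        return False
    if ga.number_of_edges() != gb.number_of_edges():
        return False
    if _hash(ga) != _hash(gb):
        return False
    return nx.is_isomorphic(
        ga,
        gb,
        node_match=categorical_node_match("label", None),
        edge_match=categorical_edge_match("label", None),
    )


def aam_equivalent(
    mapping_a: AtomMapping,
    mapping_b: AtomMapping,
    record: ReactionRecord,
    include_spectators: bool = False,
    include_h_labels: bool = True,
) -> bool:
    """True when the two mappings induce isomorphic CGRs on ``record``.

    By default only the mapped-atom subgraph is compared, since the
    evaluation concerns where the *product* atoms came from; set
    ``include_spectators`` to compare the full superposed graphs.
    """
    ca = build_cgr(record, mapping_a, include_h_labels=include_h_labels)
    cb = build_cgr(record, mapping_b, include_h_labels=include_h_labels)
    if not include_spectators:
        ca = CondensedGraphOfReaction(ca.mapped_subgraph())
        cb = CondensedGraphOfReaction(cb.mapped_subgraph())
    return cgr_isomorphic(ca, cb)


# --- accuracy metrics ---------------------------------------------------


@dataclass
class AccuracyReport:
    """Evaluation summary.  Undefined ratios (empty subsets) are ``None``,
    never coerced to 0."""

    acc_overall_dataset: Optional[float] = None
    acc_conf_dataset: Optional[float] = None
    acc_conf_manual: Optional[float] = None
    ratio_conf: Optional[float] = None
    ratio_unconf: Optional[float] = None
    acc_unconf_dataset: Optional[float] = None
    acc_calibrated: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return dict(self.__dict__)


def calibrated_accuracy(
    acc_overall_dataset: float,
    acc_conf_dataset: float,
    ratio_conf: float,
    acc_conf_manual: float,
) -> AccuracyReport:
    """Combine dataset accuracy with manually checked confident accuracy.

    The dataset-based accuracy of the unconfident subset is backed out as
    ``(overall - conf * ratio_conf) / ratio_unconf`` and recombined with the
    manually verified confident accuracy weighted by the confident ratio.
    Inputs and outputs are fractions in [0, 1].
    """
    for name, v in (
        ("acc_overall_dataset", acc_overall_dataset),
        ("acc_conf_dataset", acc_conf_dataset),
        ("ratio_conf", ratio_conf),
        ("acc_conf_manual", acc_conf_manual),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    ratio_unconf = 1.0 - ratio_conf
    if math.isclose(ratio_unconf, 0.0, abs_tol=1e-12):
        acc_unconf = 0.0  # weight-zero term
    else:
        acc_unconf = (acc_overall_dataset - acc_conf_dataset * ratio_conf) / ratio_unconf
        if not 0.0 <= acc_unconf <= 1.0:
            logger.warning(
                "unconfident-subset accuracy %.4f outside [0, 1]; clamping",
                acc_unconf,
            )
            acc_unconf = min(1.0, max(0.0, acc_unconf))
    acc_cal = acc_unconf * ratio_unconf + acc_conf_manual * ratio_conf
    return AccuracyReport(
        acc_overall_dataset=acc_overall_dataset,
        acc_conf_dataset=acc_conf_dataset,
        acc_conf_manual=acc_conf_manual,
        ratio_conf=ratio_conf,
        ratio_unconf=ratio_unconf,
        acc_unconf_dataset=acc_unconf,
        acc_calibrated=acc_cal,
    )


def evaluate(
    predictions: Sequence[tuple[ReactionRecord, AtomMapping, bool]],
    gold: Sequence[AtomMapping],
    manual_conf_accuracy: Optional[float] = None,
) -> tuple[AccuracyReport, list[bool]]:
    """Score predicted mappings against gold mappings by CGR equivalence.

    ``predictions`` holds ``(record, predicted_mapping, is_confident)``
    aligned with ``gold``.  Returns the aggregate report plus per-reaction
    correctness verdicts.  When ``manual_conf_accuracy`` is given the
    calibrated accuracy is filled in as well.
    """
    if len(predictions) != len(gold):
        raise ValueError("predictions and gold must have equal length")
    if not predictions:
        raise ValueError("nothing to evaluate")
    verdicts: list[bool] = []
    conf_flags: list[bool] = []
    for (record, pred, confident), truth in zip(predictions, gold):
        verdicts.append(aam_equivalent(pred, truth, record))
        conf_flags.append(bool(confident))
    n = len(verdicts)
    n_conf = sum(conf_flags)
    acc_overall = sum(verdicts) / n
    ratio_conf = n_conf / n
    acc_conf = (
        sum(v for v, c in zip(verdicts, conf_flags) if c) / n_conf
        if n_conf
        else None
    )
    n_unconf = n - n_conf
    acc_unconf = (
        sum(v for v, c in zip(verdicts, conf_flags) if not c) / n_unconf
        if n_unconf
        else None
    )
    report = AccuracyReport(
        acc_overall_dataset=acc_overall,
        acc_conf_dataset=acc_conf,
        ratio_conf=ratio_conf,
        ratio_unconf=1.0 - ratio_conf,
        acc_unconf_dataset=acc_unconf,
    )
    if manual_conf_accuracy is not None and acc_conf is not None:
        report = calibrated_accuracy(
            acc_overall, acc_conf, ratio_conf, manual_conf_accuracy
        )
    return report, verdicts
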