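"""CGR construction, equivalence, bond-change counts, accuracy metrics."""

import numpy as np
import pytest
from rdkit import Chem

import atommap as am


def shuffled_copy(record, gold, seed):
    """The same reaction re-serialized with a random atom order."""
    rng = np.random.default_rng(seed)
    text = am.write_mapped_smiles(record, gold)
    parts = text.split(">>")

    def shuffle_side(side):
        out = []
        for smi in side.split("."):
            mol = Chem.MolFromSmiles(smi)
            perm = rng.permutation(mol.GetNumAtoms()).tolist()
            out.append(
                Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
            )
        rng.shuffle(out)
        return ".".join(out)

    back = am.parse_reaction(
        f"{shuffle_side(parts[0])}>>{shuffle_side(parts[1])}"
    )
    assert back.given_mapping is not None
    return back, back.given_mapping


class TestBuildCgr:
    def test_identity_reaction_no_changes(self):
        record = am.parse_reaction("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        cgr = am.build_cgr(record, record.given_mapping)
        assert am.count_bond_changes(cgr) == 0

    def test_sn2_two_bond_changes(self, sn2_record):
        cgr = am.build_cgr(sn2_record, sn2_record.given_mapping)
        changed = {
            tuple(sorted(d["order_before"] for d in [x]))
            for *_, x in cgr.graph.edges(data=True)
            if x["order_before"] != x["order_after"]
        }
        assert am.count_bond_changes(cgr) == 2

    def test_ester_hydrolysis_two_changes(self):
        record = am.parse_reaction(
            "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]>>"
            "[CH3:1][C:2](=[O:3])[OH:6].[OH:4][CH3:5]"
        )
        cgr = am.build_cgr(record, record.given_mapping)
        assert am.count_bond_changes(cgr) == 2

    def test_inert_spectator_contributes_nothing(self):
        # spectator butane's internal bonds must not count as broken
        record = am.parse_reaction("[CH3:1][Br:2].CCCC.[OH2:3]>>[CH3:1][OH:3]")
        cgr = am.build_cgr(record, record.given_mapping)
        assert am.count_bond_changes(cgr) == 2  # C-Br broken, C-O formed

    def test_requires_total_mapping(self):
        record = am.parse_reaction("CCO>>CCO")
        with pytest.raises(ValueError):
            am.build_cgr(record, am.AtomMapping(((0, 0),)))


class TestAamEquivalent:
    def test_map_number_permutation_invariant(self, examples):
        for record, gold, _ in examples[:10]:
            _, renumbered = am.corrupt((record, gold), "shuffled_numbers", seed=1)
            assert am.aam_equivalent(gold, renumbered, record)

    def test_homotopic_atom_swap_equivalent(self):
        # the tert-butyl methyls are homotopic: any of them may serve as
        # the source of any product methyl
        record = am.parse_reaction(
            "[CH3:1][C:2]([CH3:3])([CH3:4])[Br:5].[I-:6]>>"
            "[CH3:1][C:2]([CH3:3])([CH3:4])[I:6]"
        )
        gold = record.given_mapping
        swapped = am.AtomMapping(
            tuple((p, {0: 2, 2: 0}.get(r, r)) for p, r in gold.pairs)
        )
        assert am.aam_equivalent(gold, swapped, record)

    def test_distinct_charge_oxygens_not_homotopic(self):
        # in the charge-separated nitro group, =O and O- carry different
        # labels; swapping them is a real CGR change, not a relabeling
        record = am.parse_reaction(
            "[CH3:1][N+:2](=[O:3])[O-:4]>>[CH3:1][N+:2](=[O:3])[O-:4]"
        )
        gold = record.given_mapping
        swapped = am.AtomMapping(
            tuple((p, {2: 3, 3: 2}.get(r, r)) for p, r in gold.pairs)
        )
        assert not am.aam_equivalent(gold, swapped, record)

    def test_water_vs_leaving_group_oxygen_not_equivalent(self):
        # ester hydrolysis: acid OH oxygen sourced from water (correct)
        # versus from the ester leaving group (the classic dataset error)
        record = am.parse_reaction(
            "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]>>"
            "[CH3:1][C:2](=[O:3])[OH:6].[OH:4][CH3:5]"
        )
        gold = record.given_mapping
        # wrong provenance: product acid O <- ester O, product alcohol O <- water
        swap = {3: 5, 5: 3}
        wrong = am.AtomMapping(
            tuple((p, swap.get(r, r)) for p, r in gold.pairs)
        )
        assert not am.aam_equivalent(gold, wrong, record)

    def test_equivalence_relation_axioms(self, examples):
        subset = examples[:6]
        for record, gold, _ in subset:
            variants = [
                gold,
                am.corrupt((record, gold), "shuffled_numbers", seed=2)[1],
            ]
            try:
                variants.append(
                    am.corrupt((record, gold), "equivalent_relabel", seed=2)[1]
                )
            except am.synthetic.CorruptionError:
                pass
            # reflexive, symmetric, transitive on the variant set
            for a in variants:
                assert am.aam_equivalent(a, a, record)
            for a in variants:
                for b in variants:
                    assert am.aam_equivalent(a, b, record) == am.aam_equivalent(
                        b, a, record
                    )
            for a in variants:
                for b in variants:
                    for c in variants:
                        if am.aam_equivalent(a, b, record) and am.aam_equivalent(
                            b, c, record
                        ):
                            assert am.aam_equivalent(a, c, record)

    def test_invariant_under_atom_order_shuffles(self, examples):
        for record, gold, _ in examples[:5]:
            base_changes = am.count_bond_changes(am.build_cgr(record, gold))
            for seed in range(10):
                rec2, gold2 = shuffled_copy(record, gold, seed)
                assert (
                    am.count_bond_changes(am.build_cgr(rec2, gold2))
                    == base_changes
                )
                assert am.aam_equivalent(gold2, gold2, rec2)

    def test_equivalent_implies_equal_bond_changes(self, examples):
        for record, gold, _ in examples[:10]:
            try:
                _, relabeled = am.corrupt(
                    (record, gold), "equivalent_relabel", seed=3
                )
            except am.synthetic.CorruptionError:
                continue
            assert am.aam_equivalent(gold, relabeled, record)
            assert am.count_bond_changes(
                am.build_cgr(record, gold)
            ) == am.count_bond_changes(am.build_cgr(record, relabeled))


class TestCalibratedAccuracy:
    def test_high_confidence_mapper_row(self):
        report = am.calibrated_accuracy(0.915, 0.928, 0.970, 1.000)
        assert report.acc_calibrated == pytest.approx(0.985, abs=5e-4)

    def test_language_model_baseline_row(self):
        report = am.calibrated_accuracy(0.981, 0.997, 0.309, 0.936)
        assert report.acc_calibrated == pytest.approx(0.962, abs=5e-4)

    def test_zero_confident_ratio_reduces_to_overall(self):
        report = am.calibrated_accuracy(0.8, 0.9, 0.0, 0.95)
        assert report.acc_calibrated == pytest.approx(0.8)

    def test_full_confident_ratio_uses_manual_only(self):
        report = am.calibrated_accuracy(0.9, 0.9, 1.0, 0.97)
        assert report.acc_calibrated == pytest.approx(0.97)

    def test_linear_in_manual_accuracy_with_slope_ratio_conf(self):
        r1 = am.calibrated_accuracy(0.9, 0.92, 0.6, 0.5)
        r2 = am.calibrated_accuracy(0.9, 0.92, 0.6, 0.9)
        slope = (r2.acc_calibrated - r1.acc_calibrated) / (0.9 - 0.5)
        assert slope == pytest.approx(0.6)

    def test_clamping_of_inconsistent_inputs(self):
        report = am.calibrated_accuracy(0.5, 1.0, 0.9, 1.0)
        assert 0.0 <= report.acc_unconf_dataset <= 1.0

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            am.calibrated_accuracy(bad, 0.9, 0.5, 0.9)


class TestEvaluate:
    def test_all_correct(self, examples):
        subset = examples[:4]
        predictions = [(r, g, True) for r, g, _ in subset]
        gold = [g for _, g, _ in subset]
        report, verdicts = am.evaluate(predictions, gold)
        assert all(verdicts)
        assert report.acc_overall_dataset == 1.0
        assert report.acc_conf_dataset == 1.0

    def test_mixed_arithmetic(self, examples):
        # 3 of 4 correct; the 2 confident ones both correct
        subset = examples[:4]
        wrong_record, wrong_gold, _ = subset[3]
        _, wrong = am.corrupt((wrong_record, wrong_gold), "wrong_atom_source", seed=0)
        predictions = [
            (subset[0][0], subset[0][1], True),
            (subset[1][0], subset[1][1], True),
            (subset[2][0], subset[2][1], False),
            (wrong_record, wrong, False),
        ]
        gold = [g for _, g, _ in subset]
        report, verdicts = am.evaluate(predictions, gold)
        assert verdicts == [True, True, True, False]
        assert report.acc_overall_dataset == pytest.approx(0.75)
        assert report.acc_conf_dataset == pytest.approx(1.0)
        assert report.ratio_conf == pytest.approx(0.5)

    def test_empty_confident_subset_is_undefined_not_zero(self, examples):
        subset = examples[:2]
        predictions = [(r, g, False) for r, g, _ in subset]
        gold = [g for _, g, _ in subset]
        report, _ = am.evaluate(predictions, gold)
        assert report.acc_conf_dataset is None

    def test_length_mismatch_errors(self, examples):
        record, gold, _ = examples[0]
        with pytest.raises(ValueError):
            am.evaluate([(record, gold, True)], [])
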