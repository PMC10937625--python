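# atommap

Atom-to-atom mapping (AAM) of organic reactions: a graph-neural mapper
trained through human-in-the-loop active learning, with knowledge-based
prediction confidence from a library of human-verified reaction templates
and a condensed-graph-of-reaction (CGR) evaluation suite.

## Who this is for

AAM assigns every product heavy atom of a reaction to the reactant atom it
came from, written as shared atom-map numbers in reaction SMILES
(`[CH3:1][Br:2].[I-:3]>>[CH3:1][I:3]`). Anyone building retrosynthesis or
reaction-prediction models needs correct AAM: it defines the reaction
center, the extracted templates, and the CGR. `atommap` provides the full
workflow — dataset filtering, model training, greedy map decoding,
template-based confidence, active-learning orchestration, and evaluation —
with a synthetic reaction generator so everything is testable without
external data.

## The model

Reactant and product molecules are encoded as graphs
G_r = (V_r, E_r), G_p = (V_p, E_p) and passed through:

1. a 3-layer message-passing network (shared weights for both sides):
   h_u ← ReLU(W_s h_u + Σ_v W_m [h_v ‖ e_uv] + b),
2. three 8-head cross-attention blocks in which product atoms attend over
   all reactant atoms, e_uv = Q_u K_vᵀ / √(d/n), folded in by a gated
   residual h ← LN(h + σ(W_g m + b_g) ⊙ m) and a feed-forward sublayer,
3. a single-head attention classifier with row softmax:
   P[u_p, u_r] = softmax_r(K_p Q_rᵀ / √d) = p(u_r | u_p).

Training minimizes the cross-entropy of the gold atom pairs (Adam, lr
10⁻³, batch 16, weight decay 10⁻⁶, gradient clip 20, lr halved on
validation plateau). The map is decoded greedily from the highest
probability cell to the lowest, one-to-one, with an element-match
constraint by default.

A prediction is **confident** iff the extended-local reaction template
(ELRT) extracted from it already exists, human-verified, in the template
library — a pure chemistry-knowledge test, independent of model
internals. Accuracy is always judged by CGR equivalence so that
symmetric-but-different maps are never counted as errors, and the
calibrated accuracy combines dataset-based accuracy on unconfident
predictions with manually checked accuracy on confident ones:

    acc_unconf = (acc_overall − acc_conf · ratio_conf) / ratio_unconf
    acc_calibrated = acc_unconf · ratio_unconf + acc_manual · ratio_conf

See `docs/methods.md` for the full model and design notes.

## Worked example

```python
import atommap as am

rxn = ("[CH3:1][C:2](=[O:3])[O:4][CH2:5][CH3:6].[OH2:7]>>"
       "[CH3:1][C:2](=[O:3])[OH:7].[OH:4][CH2:5][CH3:6]")
record = am.parse_reaction(rxn, "ester-1")
gold = record.given_mapping

print("bond changes:", am.count_bond_changes(am.build_cgr(record, gold)))
t = am.extract_elrt(record, gold)
print("template:", t.canonical_pattern)
print("center size:", t.center_size, "| extensions:", t.extension_groups)

# the classic dataset error: sourcing the acid oxygen from the ester
# leaving group instead of from water (reactant indices 3 and 6)
wrong = am.AtomMapping(tuple((p, {3: 6, 6: 3}.get(r, r)) for p, r in gold.pairs))
print("wrong-oxygen map equivalent:", am.aam_equivalent(gold, wrong, record))

report = am.calibrated_accuracy(0.915, 0.928, 0.970, 1.000)
print(f"calibrated accuracy: {report.acc_calibrated:.3f}")
```

prints

```
bond changes: 2
template: [O:1]([C:3]=[O:4])[CH2:5].[OH2:2]>>[OH:1].[OH:2][C:3]=[O:4]
center size: 3 | extensions: ('carbonyl', 'carboxylic_acid', 'ester')
wrong-oxygen map equivalent: False
calibrated accuracy: 0.985
```

The ester hydrolysis breaks the acyl C–O bond and forms the C–O(water)
bond (2 bond changes); its template is the acyl substitution center
extended by the carbonyl/ester groups; the wrong oxygen provenance is a
different CGR — it even has the same bond-change count, yet is correctly
judged non-equivalent; and combining the four evaluation statistics
(overall 91.5%, confident 92.8%, confident ratio 97.0%, manual 100%)
calibrates to an overall accuracy of 98.5%.

## Training and the active-learning loop

```python
examples = am.generate(n=600, seed=42)           # synthetic, gold known
pool = [r for r, _, _ in examples[:500]]
oracle = am.GroundTruthOracle({r.reaction_id: g for r, g, _ in examples})
state = am.run_loop(
    pool, oracle, k=20, iterations=3, seed=7,
    model_factory=lambda s: am.AtomMapper(hidden_dim=64, epochs=40,
                                          random_state=s),
)
```

Each iteration samples k reactions (randomly at first, then one per
uncertain template by popularity), labels them through the oracle, updates
the verified-template library, retrains, and re-predicts the pool. On the
synthetic benchmark this reaches full coverage with every confident
prediction CGR-correct while labeling 60 of 500 reactions.

The same workflow is available from the shell:

```sh
atommap fixtures --out fx --n 100 --seed 0      # synthetic mapped data
atommap filter   --in fx/reactions.smi --out clean.smi --report report.json
atommap train    --data clean.smi --out mapper.npz
atommap map      --model mapper.npz --in clean.smi --out mapped.csv
atommap templates --in fx/reactions.smi --out library.tsv --verified
atommap evaluate --pred mapped.csv --gold fx/reactions.smi --report report.tsv
atommap loop     --oracle fixture --k 20 --iters 3 --seed 0 --workdir run/
```

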