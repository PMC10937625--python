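# Methods

## Problem

Atom-to-atom mapping (AAM) assigns each heavy atom of a reaction's products
to the reactant atom it originated from. Correct AAM determines the
reaction center, enables reaction-template extraction for retrosynthesis
and forward-prediction models, and underlies the condensed graph of
reaction (CGR) representation. `atommap` implements a complete AAM
workflow: a graph-neural mapper, greedy decoding of its probability
matrices, knowledge-based prediction confidence from a library of
human-verified reaction templates, active-learning orchestration, and a
CGR-based evaluation suite.

## The mapper network

Molecules are represented as heavy-atom graphs. Atom features: element
one-hot over an 18-element vocabulary plus an explicit *unknown* slot,
degree (0–5), formal charge (−2…+2 with an out-of-range slot),
hybridization, aromaticity, total hydrogen count (0–4), ring membership,
and tetrahedral chirality tag. Bond features: order (single / double /
triple / aromatic), conjugation, ring membership, and stereo code. The
schema is versioned; checkpoints refuse to load under a different schema.

The network has three stages:

1. **Message passing (3 layers, shared between the two sides).** Per
   layer, each atom receives `Σ_v ReLU`-free messages
   `W_msg·[h_v ‖ e_uv] + b_msg` summed over incident bonds, combined with
   its own transform through a ReLU:
   `h_u ← ReLU(W_self·h_u + b_self + Σ_v W_msg·[h_v ‖ e_uv] + b_msg)`.
   Sum aggregation with bond features concatenated to the neighbor state
   is the conventional choice for reaction-graph models; isolated atoms
   (e.g. halide ions) simply pass through their own transform. Three
   layers give every atom a 3-bond receptive field.

2. **Reaction cross-attention (3 blocks, 8 heads).** Product atoms attend
   over *all* reactant atoms: per head,
   `e_uv = (Q_u K_vᵀ)/√(d/n)` with `Q` from the product side and `K`, `V`
   from the reactant side; head outputs are concatenated. The attended
   message `m` is folded in by a gated residual
   `h ← LayerNorm(h + σ(W_g m + b_g) ⊙ m)` followed by a two-layer
   feed-forward sublayer with its own residual and layer norm. The gate
   and the feed-forward net use distinct parameter sets. Reactant features
   are *not* updated by attention — they enter the classifier straight
   from the MPNN. Dropout 0.1 is applied to the attention weights in
   training mode only.

3. **Atom-mapping classifier.** A single-head attention head scores every
   (product, reactant) atom pair, `s = (K_p Q_rᵀ)/√d`, and a row softmax
   yields `P[u_p, u_r] = p(u_r | u_p)` — one distribution over reactant
   atoms per product atom.

The hidden dimension defaults to `d = 320` (divisible by the 8 heads);
tests and the desk-scale workflow use `d = 64` for speed.

**Training.** The loss is the mean negative log-probability of the gold
pairs (cross-entropy per product atom). Optimization: Adam, learning rate
10⁻³, weight decay 10⁻⁶, batch size 16, gradient norm clipped at 20,
100 epochs by default, deterministic given the seed. The learning rate is
halved when the validation loss fails to improve (relative threshold
10⁻⁴) for more than one consecutive epoch; the plateau signal is computed
by a clean inference-mode pass — over the caller-supplied validation
split, or over the training set when no split is given. A batch is packed
into one block-diagonal graph with an additive attention mask, so a batch
is a single forward/backward pass; the mask is quadratic in atoms per
pack, which is why validation loss is also evaluated in batch-size chunks.

The network, including its reverse-mode differentiation, is implemented
directly on NumPy (`atommap.nn.autograd` is a ~200-line tape). This keeps
the dependency surface at NumPy + RDKit + NetworkX and is entirely
adequate at the problem sizes the package targets.

## Greedy decoding

All cells of `P` are visited from the highest probability to the lowest
(ties broken by ascending product-, then reactant-index); a cell is
accepted when neither atom is taken yet and, by default, when the two
atoms are the same element (`enforce_element_match=True` — cross-element
maps would poison template extraction; the check can be disabled).
Leftover reactant atoms are spectators and receive no map number.

A known limitation of cell-wise greedy decoding: over a *multi-atom*
homotopic group (e.g. the two halves of a mirror-symmetric ring) a
perfectly trained model emits exact 0.5/0.5 ties, and independent
tie-resolution can mix the two orientations into a "chimera" assignment
that is not an automorphism and is therefore wrong. Neighbor-consistent
decoding schemes exist precisely for this; this package deliberately
keeps the plain greedy rule (it is the specified procedure) and documents
the consequence. Single-atom homotopic pairs are unaffected — any
resolution is an automorphism and CGR equivalence accepts it.

## Knowledge-based confidence via extended-local templates

From a mapped reaction the **reaction center** is extracted: every atom
incident to a bond whose order changes, plus atoms whose formal charge or
hydrogen count changes (so a pure reduction still has a center), plus
reactant atoms that lose bonds to mapped atoms (leaving groups). The
**extended-local reaction template** (ELRT) adds the atoms of catalog
functional groups (carbonyl, carboxylic acid, ester, amide, nitrile,
nitro, acetal, imine, sulfonyl, boronic, organohalide, aromatic
heteroatom) that share an atom with or sit directly on the center. The
catalog is a YAML file of named SMARTS, not code; users can supply their
own.

**Canonicalization.** Template atoms are renumbered canonically: product
atoms first, in the canonical output order of the map-free product
fragment — with symmetry ties broken by the canonical rank of each atom's
reactant partner, carried over as a scratch isotope (this disambiguates
e.g. the two aryl carbons of a freshly formed biaryl bond) — then leftover
reactant-only atoms in reactant-fragment canonical order. The pattern
string is the canonical fragment SMILES of both sides joined by `>>`; it
is invariant to input atom order and map relabeling (property-tested with
random shuffles) and serves as the library key. Reagents and catalysts
are never part of templates. Stereo on center atoms is retained through
the fragment writer; stereo elsewhere is not part of the pattern.

A prediction is **confident** iff its extracted template is present in
the library *and* was verified by a human labeler; everything else —
unknown template, unverified template, failed extraction — is uncertain.
This is a pure lookup with no model internals involved. The
probability-product `confidence_score` is exposed separately as a
diagnostic only.

## CGR construction and equivalence

The CGR superposes reactant and product graphs through the mapping. Atoms
carry (element, charge before/after, H-count before/after); bonds carry
(order before, order after), 0 meaning absent, aromatic 1.5. Spectator
reactant atoms are kept: their bonds to mapped atoms are broken bonds,
while bonds inside fully-spectator molecules are carried unchanged so an
inert bystander contributes nothing to the change count.

Two mappings are **equivalent** iff their CGRs are isomorphic respecting
all labels (Weisfeiler–Lehman hash as a fast reject, then exact VF2
matching). By default the comparison covers the mapped-atom subgraph —
the question being evaluated is where the product atoms came from — with
`include_spectators=True` available. H-count labels participate in atom
equivalence but H-count changes are not bond changes;
`count_bond_changes` counts heavy-atom bonds with `order_before ≠
order_after`.

**Calibrated accuracy.** Given overall dataset accuracy, confident-subset
dataset accuracy, the confident ratio and a manually verified
confident-subset accuracy, the unconfident-subset accuracy is backed out
as `(overall − conf·ratio)/(1−ratio)` (clamped to [0,1] with a logged
warning if the inputs are inconsistent) and recombined as
`calibrated = unconf·(1−ratio) + manual·ratio`. Undefined ratios (empty
subsets) are reported as absent values, never as 0.

## Active learning

Iteration 1 samples `k` reactions uniformly; the oracle labels them;
their templates enter the library as verified. Later iterations rank
uncertain templates by reaction count (ties by pattern string) and take
one reaction per template in rank order, wrapping around for a second
pass when templates run out before `k`; within a template the order is a
seed-deterministic shuffle of record ids. From iteration 2 the training
set is augmented with up to 100 confident predictions per verified
template, split 9:1 into train/validation; human-labeled reactions always
stay in the training set. Each iteration trains a fresh model (derived
seed) and re-predicts the whole pool; coverage is the fraction of the
pool whose predicted template is verified. Invalid oracle labels are
rejected and the record stays in the pool.

Because the confident class requires the *exact* canonical template, a
wrong mapping that alters any bond inside or into the center produces a
different template and lands in the uncertain class; this is the
mechanism behind the perfectly accurate confident subset, and the
augmentation labels it supplies are correspondingly clean.

## Synthetic reactions

The generator emulates eight reaction classes — ester hydrolysis,
esterification, mixed (methyl/ethyl) acetal hydrolysis, SN2 halide
substitution, amide coupling, nitro reduction, a Suzuki-type biaryl
coupling, and imine condensation (standing in for ring-forming
condensations; a full thiazole synthesis would add fixture complexity
without exercising anything new). Each class is a mapped core with
numbered dummy attachment points plus a substituent vocabulary; map
numbers shared across the two sides carry the ground truth, so every
generated reaction has a total, injective gold mapping by construction.
Hydrolyses and condensations encode the mechanistically correct oxygen
provenance (the water oxygen ends up in the acid/carbonyl product) — the
atom the corruption mode swaps. Atom orders are shuffled and map numbers
randomized per record; generation is deterministic given the seed.

Two fixture-design constraints keep the ground truth *recoverable*:

- **Identifiability.** Reactant embeddings come from a 3-layer MPNN and
  are never refined by attention, so two atoms with identical 3-bond
  environments in different contexts are indistinguishable in principle.
  Substituents are short and branched so every atom is within three bonds
  of a distinguishing feature; in the biaryl coupling the boronic partner
  is a 3-pyridyl ring, whose in-ring nitrogen identifies the ring to all
  of its atoms (a substituent-only difference sits outside the horizon of
  the CH farthest from it).
- **Decodability.** Multi-atom mirror-symmetric groups are avoided (rings
  carry a meta substituent; the acetal is mixed) because of the greedy
  chimera effect described above. Genuinely homotopic single atoms
  (gem-dimethyls) are kept and handled by CGR equivalence.

What passing fixtures does *not* show: robustness to the long-range
ambiguities, stereochemical subtleties, unbalanced/noisy records, and
condition-dependent chemistry of real patent data; the fixtures
demonstrate the mechanics of the workflow, not patent-scale accuracy.

Controlled corruptions: `wrong_atom_source` re-sources a product atom
from a plausible (same-element) but wrong reactant atom, verified
non-equivalent — emulating the classic leaving-group-vs-water oxygen
error; `equivalent_relabel` composes the mapping with a reactant
automorphism that moves a mapped atom; `shuffled_numbers` permutes
serialization labels only. The latter two are CGR-equivalent by design.

## Dataset filters

Two cleaning rules are applied before judging a dataset's recorded
mapping: *invalid product mapping* (a product atom without a map number,
or a duplicated number) and *confusing reagent* (a reactant contributing
zero mapped atoms whose Morgan-fingerprint (radius 2, 2048 bits) Tanimoto
similarity to any product molecule is ≥ 0.5). Agents in the middle SMILES
field are treated as reactants that may donate atoms but are never
required to map. Filters are order-independent and idempotent; when
several fail, the reported reason follows a fixed priority (unparseable >
invalid product mapping > confusing reagent).

## Problem sizes and numerical choices

- Desk-scale workflow (tests, acceptance): pool of 500 reactions over the
  8 classes, held-out set of 100, `k = 20`, 3 iterations, `d = 64`,
  40 epochs per iteration — chosen once as a single-CPU configuration.
- Row-stochasticity tolerance 10⁻⁶; cross-entropy is computed on
  probabilities with a 10⁻¹² floor; layer-norm ε 10⁻⁵; softmax is
  computed shifted by the row maximum.
- Greedy ties: ascending (product index, reactant index) — deterministic,
  documented, and pinned by the decoder-oracle tests.
- Degenerate inputs: empty reactant set → error; a product atom with no
  admissible partner → error naming the atom; `ratio_conf = 1` gives the
  unconfident term weight zero; empty confident subsets report `None`.

## Known limitations

- Templates are canonical *identification* patterns, not executable
  rewrite rules; applying templates for forward/retro prediction is out
  of scope.
- The chimera limitation of plain greedy decoding on symmetric substrates
  (see above).
- Training is plain NumPy on one CPU: ~0.1 s per 16-reaction batch at
  `d = 64`. Patent-scale corpora would need a GPU backend, which is
  deliberately out of scope.
- The mapper never balances reactions or fixes valence errors; upstream
  standardization is assumed.
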