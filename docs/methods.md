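# Methods

## Similarity by assay co-membership

The corpus treats two molecules as medicinal-chemistry-similar when they
were measured in the same small bioassay. No numerical activity is used;
activity *types* (IC50, pIC50, Ki, pKi, EC50, pEC50) and assay classes
(binding, functional) only gate inclusion. The assay-size window of 8–25
molecules keeps panels that plausibly represent one optimisation series
while excluding screening decks. The window is applied to the molecules
*surviving* the molecule-level filters; this choice is configurable
(`FilterConfig.min/max_assay_size`) because the alternative — bounding the
raw assay size — is equally defensible.

### Molecule filters

A molecule is retained iff it passes, in order: valid SMILES; single
fragment (salts/solvents are expected to be pre-stripped, so any remaining
dot-disconnection is rejected); not popularity-flagged (approved drug,
wiki-listed, or > 5 publications — consumed as input columns, never
scraped); not peptide-flagged (when no flag column exists, a SMARTS
heuristic of four consecutive backbone amides is applied); no isotope
labels; molecular weight ≤ 600 Da; elements within {C,N,H,O,S,F,Cl,Br};
≤ 7 rotatable bonds (strict definition — acyclic single bonds between
non-terminal heavy atoms, amide C–N excluded — configurable); ≤ 100 tokens.
The rejection log names the first failing rule, but every rule is a pure
predicate, so the retained set is order-independent.

### Pairing, cap, split

All unordered within-assay pairs are enumerated (n(n−1)/2), deduplicated
globally by unordered canonical pair, capped at 30 uniformly-sampled pairs
per document (seeded), and pairs whose members share a stereo-stripped
canonical form are removed — the generator should preserve stereochemistry,
not learn to permute it. The 80/10/10 split is seeded (42 by default);
an odd remainder goes to validation.

## Levenshtein alignment

Distance is the plain character-level edit distance (computed with edlib;
an O(nm) dynamic-programming fallback exists and doubles as the test
oracle). Alignment searches a pool of up to 10,000 randomised SMILES of the
partner molecule — generated by uniform atom-index permutation, written
unrooted and non-canonically, deduplicated — for the minimum-distance
string; ties break to the lexicographically smallest candidate. Pool seeds
derive from (global seed, pair id, direction) via CRC-32 so results are
independent of corpus order. The candidate pool is purely randomised by
default; `inject_canonical=True` additionally admits the canonical string.

The four dataset builders: `canonical` (2 directed records/pair),
`randomised` (2), `lev_aligned` (canonical source, best-aligned randomised
target; 2), `lev_extended` (per direction, 1 canonical + 4 distinct
randomised source forms each aligned against one shared partner pool; 10
records/pair). If a small molecule admits fewer than 5 distinct
representations after 50 resampling rounds, the builder emits what exists
and logs the shortfall.

## Model

Encoder–decoder transformer (post-norm residual blocks, learned positional
embeddings, scaled-dot-product multi-head attention, ReLU feed-forward)
over a shared vocabulary ordered by token frequency with
⟨pad⟩/⟨sos⟩/⟨eos⟩ first. The output projection is tied to the transposed
token-embedding matrix; tying removes a quarter of the parameters of the
desk-scale model and measurably accelerates convergence on the toy tasks.
The full-scale configuration is 3+3 layers, 8 heads, width 256,
feed-forward 512, batch 64; the desk-scale `ModelConfig.tiny()` used by the
tests is 2+2 layers, 4 heads, width 64, feed-forward 128, batch 32,
150 epochs.

Training minimises the teacher-forced masked NLL (summed from t = 2; ⟨sos⟩
is given, padding contributes exactly zero) with Adam, global
gradient-norm clipping at 1.0, linear warmup (5 epochs) into cosine decay
(floor 2–5 % of the base rate). Defaults: learning rate 5e-4 full scale /
4e-3 tiny, dropout 0.1 full / 0.0 tiny. These optimisation details are not
part of the modelled science; they are the package's own choices and all
configurable. Model selection keeps the lowest-validation-NLL epoch (final
epoch when no validation set is given). Every random stream (init,
shuffling, dropout) derives from one seed, so identical seeds reproduce
identical loss curves bit for bit.

The network runs on a small reverse-mode autodiff core (`seqhop.nn`)
written for this package over NumPy in float64: broadcast-aware
arithmetic, batched matmul, stable log-softmax, embedding gather and a
fused layer-norm primitive whose analytic gradient is verified against
numerical differentiation in the tests.

## Decoding

* **Greedy** — argmax per step; deterministic.
* **Beam** — candidates ranked by cumulative NLL with no length
  normalisation; at each step the k best candidates are taken, ⟨eos⟩
  candidates freeze into the completed pool, the search stops at k
  completed hypotheses or the length cap. Ties break on token id then
  hypothesis order, making beam width 1 byte-identical to greedy — the
  two are implemented independently and the equivalence is asserted, not
  assumed.
* **Sampling** — each token drawn from softmax(z_t / T), default T = 1.2;
  the reported NLL is always the model's unscaled likelihood.

*Prefix control* seeds every hypothesis with the tokenised prefix; prefix
tokens contribute no NLL (conditioning, not choice). *Invalid filtering*
prunes, after every token, partials that fail the feasibility check below,
and requires completed outputs to parse; pruned sampling chains redraw from
the renormalised remainder and a chain with no feasible continuation is
dropped with a warning rather than an exception. Generation length is
bounded by `max_length` (default 150) and by the positional table.

### Partial-SMILES feasibility

`chem.is_extensible` is a hand-written scanner checking grammar
transitions, branch balance, ring-bond feasibility (no self-bonds or
duplicate bonds) and a permissive valence cap per atom (counting opened
ring bonds). It is deliberately one-sided: it may accept a doomed prefix
(completed strings are re-checked with the full parser) but never rejects
a prefix of a valid SMILES — aromaticity and kekulisation are therefore
not modelled. The tests assert this conservativity over every prefix of
every fixture molecule.

## Evaluation

Similarity is the Tanimoto coefficient over Morgan fingerprints (radius 2,
16,384 bits), verified in tests against an explicit on-bit Jaccard
computation. The *global target* of a generated molecule is the most
similar assay member excluding the input (ties to the canonically smallest;
a per-input resolution flag exists because either reading of "the assay's
most similar member" is sensible). The NLL–similarity relation is
summarised by Spearman rank correlation plus a 2-D histogram; a constant
column is reported as undefined rather than coerced. Scaffold recall for
input i is |recovered ∩ (U ∖ {own})| / (|U| − 1) over the Bemis–Murcko
universe U of a reference set; recall-versus-generation-number curves use
cumulative prefixes of the ordered generation stream and are monotone by
construction. Neighbour-origin attribution pools two models' canonical
sets, ranks by similarity to the target, and credits molecules produced by
both models to both. Functional groups use the toolkit's published
implementation of Ertl's perception; ring systems are connected components
of ring bonds (fused and spiro rings merge; linker-joined rings stay
separate).

## Synthetic data

The fixture generator assembles molecules from a fragment grammar — cores
(benzene, substituted benzenes, naphthalene, thiophene, isoxazole,
pyrimidine, cyclohexane, piperidine, benzamide, biphenyl) with 1–3
enumerated attachment points filled from a small substituent set — so every
emitted SMILES is valid by construction and sits inside the filter windows.
Assay tables draw 8–25 molecules per assay across a configurable number of
documents, with B/F types and the six activity types; *planted violations*
are molecules crafted to break exactly one filter rule each (e.g. a rigid
spiro-cyclohexane chain for MW > 600 with zero rotatable bonds; an
explicit-hydrogen cyclopentadecane for > 100 tokens at 210 Da), recorded in
a manifest the rejection log must reproduce exactly.

Toy pair corpora implement three string rules: identity,
Cl→Br halogen swap (scaffold-preserving) and benzene→pyridine ring swap
(always scaffold-changing). The pair corpora use the compact substituent
subset, keeping sequences around 16 tokens so the desk-scale model solves
them within its training budget. What these corpora emulate is the
*mechanics* of the pipeline — learnable systematic transformations, known
scaffold behaviour, controllable diversity. What they do not emulate:
real bioactivity structure, ChEMBL's property distributions, stereo-rich
chemistry, or corpus scale. Passing tests therefore demonstrate that the
machinery is correct and that the model can learn planted rules; they say
nothing quantitative about performance on real assay data.

## Numerical and degenerate-input choices

* Log-softmax is computed in max-shifted form; sampling at temperatures as
  low as 1e-4 underflows to a point mass gracefully.
* Beam/greedy never emit ⟨pad⟩ or ⟨sos⟩.
* An empty candidate pool after filtering yields an empty result list plus
  a warning, not an exception.
* `enumerate_randomized` of a single-atom molecule returns the one string;
  distinct-variant shortfalls in `lev_extended` are logged, not fatal.
* Assays of size one make the global target undefined → error; scaffold
  universes of size ≤ 1 likewise.
* Ties everywhere (beam candidates, alignment pools, global target,
  neighbour ranking) break deterministically (token id, lexicographic
  SMILES), so every entry point is reproducible from its seed.

## Problem sizes

The test suite and the acceptance script run the study at desk scale as the
package's own configuration: 500-pair training corpora, candidate pools of
200–10,000, 50–100 evaluation inputs, tiny model configuration. The
full-scale configuration (3+3/256/512, pools of 10,000, ~10⁵–10⁶-pair
corpora) is expressed by the same code paths via `ModelConfig()` defaults.

## Known limitations

* Training is CPU-bound NumPy; corpus sizes beyond ~10⁴ records are
  impractical without a framework backend.
* The valence table in the partial-SMILES checker is permissive by design;
  with filtering on, some hypotheses are pruned only at completion time.
* The peptide heuristic (4 backbone amides) is a stand-in for a curated
  flag and will miss cyclic or heavily modified peptides.
* Scaffold recall depends on the reference universe; with the toy grammar
  the universes are small (tens of scaffolds), so recall values are coarse.
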