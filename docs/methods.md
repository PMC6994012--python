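# Methods

This note records the models, the synthetic data, and the numerical choices
behind `clinsyn`, in enough detail to reproduce or critique them.

## Task formalization

A corpus is a set of records; each record carries zero or more span-level
mention annotations linked to a concept identifier, the special value
`CUI-less` (no concept could be assigned), or a non-concept marker (dropped
by the mention filter; `CUI-less` mentions are kept but never count as
synonyms). Two mentions are synonyms iff they link to the same concept and
their normalized surfaces differ. Normalization — lowercase, collapse
internal whitespace, strip — is the package's definition of string
equivalence; clinical casing is too inconsistent for case-sensitive
equality. Discontiguous mentions join their span texts with single spaces.

Every mention is a query; candidates are all other mentions in the same data
fold, ranked by cosine similarity (ties broken by ascending mention id so
runs are reproducible; zero-norm vectors sort last via a −∞ sentinel).
Candidates whose normalized surface equals the query's are excluded *before*
truncation to k = 50, which maximizes informative candidates per list;
distinct mentions that share a surface with each other all remain. Queries
are eligible for evaluation only if a same-fold synonym exists. MRR averages
reciprocal ranks over *all* eligible queries, counting misses as 0 — with
coverage below 100%, averaging only hits would not produce a coherent
triple (top-1 ≤ MRR ≤ coverage), and that ordering is enforced as an
invariant. The mean Jaro-Winkler similarity between each eligible mention
and its gold synonyms summarizes how lexically hard a corpus is; the mean
over correct top-1 pairs summarizes how lexically conservative a model's
discoveries are.

Significance between two models is a two-sided pooled two-proportion z-test
on the top-1 and coverage proportions. None is defined for MRR (it is not a
proportion). A pooled proportion of exactly 0 or 1 returns (z=0, p=1):
saturated identical samples carry no evidence.

## String similarity primitives

**Character n-grams.** The mention is split on spaces; each word is padded
with one reserved start and one reserved end sentinel (non-printing
characters, configurable), and the n-grams of all padded words are unioned
with set semantics. Padding is per word, so no gram bridges a word boundary.
The ranking score is |grams(candidate) ∩ grams(query)| / |grams(query)| —
asymmetric by construction. A query whose words are all shorter than n − 2
has no grams and raises an explicit undefined-score error.

**Jaro-Winkler.** Standard parameters: match window ⌊max(|s1|,|s2|)/2⌋ − 1,
transpositions = ⌊mismatched matched-position pairs / 2⌋, prefix scale 0.1
with the common prefix capped at 4. Inputs are normalized first. Two empty
strings score 1.0 by convention. The exposed quantity is the *similarity*
(1 = identical): the printed statistics in the literature on this task are
on that scale even when called a distance.

## The reference bidirectional language model

Full-scale contextual encoders (and pretrained clinical code embeddings) are
GPU-scale models trained on restricted corpora; what this package implements
is a desk-scale reference BiLM that keeps their structural commitments:

* **Layer 0** — a context-independent token representation, either a word
  embedding with an unknown-word bucket, or (default) a character CNN:
  character embeddings (dim 12), one convolution of width 3 with 48 filters,
  max-over-time, tanh. Any string, including never-seen words, gets a finite
  representation. Identical surface words always get bitwise-identical
  layer-0 vectors.
* **Two recurrent layers per direction**, forward and backward, plain tanh
  cells of width 48. LSTMs buy little at these sentence lengths (≈5–12
  tokens) and would triple the parameter count.
* **A single prediction softmax shared between directions**, as is the token
  encoder. Training is cloze-style: token t_k is predicted from the forward
  state at k−1 concatenated with the backward state at k+1 (sentence
  boundary markers supply the edge states). The prediction input is
  therefore always left ⊕ right (⊕ ICD under output fusion), and its
  dimensionality is 2·hidden (+ d_c).
* **Contextual layers are context states.** The layer-1/2 representation of
  token k is [forward state over t_1..t_{k-1} ; backward state over
  t_N..t_{k+1}] — for layer 2, exactly the vector the trained softmax scores
  against the vocabulary. Same-position states (which include the token
  itself) were measured to be dominated by token identity: on the planted
  corpus they barely beat random ranking, while context states recover the
  signal. Token identity is still fully available, at layer 0.
* **Input-dominant initialization.** Recurrent weight matrices are scaled by
  0.15 at initialization, so the state adjacent to a mention is sharply
  driven by the nearest context words (an echo-state-style conditioning);
  training with Adagrad at lr 0.02 (gradient-norm clip 5) then refines this
  structure. Larger rates (≥0.1) were observed to wash it out before 5
  epochs can rebuild it.
* **Determinism.** All initialization and per-epoch shuffling derive from
  the configured seed; training twice with the same config yields identical
  parameters, and encoding is pure.

Held-out perplexity (10% of sentences) is recorded before training and after
every epoch.

**Mention encoding.** By default each contiguous run of a mention's span is
merged into a single lexical unit before its sentence is encoded (gold spans
are assumed, and the character CNN represents arbitrary strings), so the
span's contextual layers describe the sentence context around the whole
mention; a two-word mention otherwise contaminates its own context states
with mention-internal words, which was measured to halve MRR on the planted
corpus. Pooling (dimension-wise avg or max) then ranges over the span's
units — one for contiguous mentions, several for discontiguous ones — and
over individual tokens when `merge_spans=False`. In word mode a merged
multiword unit maps to the unknown token at the input, which simply makes
the representation purely contextual. Mentions that cannot be aligned to a
single sentence (cross-sentence spans are rejected rather than guessed) get
no representation and drop out of both query and candidate pools, as do
all-OOV mentions under the type-level encoder.

**Patient-context fusion.** An admission's ICD-9 codes map to one vector by
dimension-wise max over per-code embeddings (mean is exposed as an option;
the max is used in all fusion modes). Missing codes are skipped with a
logged count; an admission with no resolvable codes gets the zero vector —
the neutral element for concatenation. *Input* fusion concatenates this
vector onto every layer-0 token representation (layer 0 widens by d_c);
*output* fusion concatenates it onto the softmax input during training only.
`c2v_fuse` provides the left ⊕ right ⊕ ICD concatenation of the
Context2vec-style architecture for an external context MLP; this package
does not train that MLP.

## The synthetic corpus generator

The generator plants the statistical structure the method exploits, and
nothing else — no negation, section headers, or clinically plausible
language:

* **Concepts** (default 25) each have 3 surface forms built from a syllable
  inventory: a two-word base, plus variants that are either single-character
  edits of the base (probability `frac_lexical_synonyms`, emulating
  "dilated RA"/"dilated RV"-style lexical neighbors) or unrelated strings
  drawn from a rotated slice of the shuffled syllable inventory (emulating
  "cerebrovascular accident"/"stroke"). Multiword forms collapse to their
  initialism with probability `abbreviation_rate` (default 0.1). All forms
  are distinct after normalization.
* **Cues**: each concept owns two cue words, globally unique and disjoint
  from all surfaces and filler. With probability `cue_strength` (default
  0.9) a mention's sentence contains one cue of its concept, placed
  immediately before or after the mention — the planted contextual signal.
* **Documents** (default 200) have 5 sentences, 3 carrying mentions of a
  2-concept subset; filler words come from a 150-word Zipf-distributed
  background vocabulary, giving the language model a realistic frequency
  skew. One admission per document carries the mentioned concepts' codes,
  perturbed by `icd_noise` (default 0.1: each true code dropped, and a
  random code added, with that probability).
* **Folds** are assigned per document (train/tune/test at 0.4/0.3/0.3), so
  identical sentences never leak across folds and candidate pools stay
  fold-closed.

Defaults give ≈600 mentions. What passing tests on this corpus show is that
the pipeline recovers a *planted, adjacent, lexical-cue* signal well above a
random-ranking null; real clinical context is weaker, farther from the
mention, and confounded with section structure, so absolute numbers here say
nothing about performance on real notes — only the orderings (contextual ≫
string baseline on dissimilar synonyms; string baseline ≫ on single-edit
synonyms) are the point.

## Study conditions and problem sizes

The standard evaluation runs used by the test suite and
`scripts/acceptance.py`:

* **Signal recovery**: default corpus with `frac_lexical_synonyms=0`,
  `cue_strength=0.9`; reference BiLM in character mode, 5 epochs; max
  pooling; layer selected by tune-fold MRR (the usual model-selection
  protocol — layer 1 wins in practice), reported on the test fold against a
  100-permutation random-ranking null over the same eligible queries.
  Measured around 3× the null, with the character-trigram baseline at
  chance.
* **Lexical regime**: `frac_lexical_synonyms=1`, `cue_strength=0`,
  `abbreviation_rate=0` (the corpus is then exactly single-edit synonym
  pairs); the trigram baseline reaches top-1 ≈ 1.0.
* **Fusion sanity**: 120-document corpus with `icd_noise=0`, random
  16-dimensional code vectors, input fusion, 3 epochs, 3 seeds, against
  controls whose admission code sets are shuffled across documents. The
  pre-set noise margin for the 3-seed mean coverage is 0.10 absolute;
  measured fused coverage actually *exceeds* the shuffled control. Fusion
  dimensionality arithmetic (layer 0 + d_c; prediction input 2·hidden + d_c)
  is checked structurally with 200-dimensional code vectors, matching the
  512/600/200 configuration arithmetic of full-scale models.
* **Determinism**: two complete generate→train→rank→score runs with one
  seed must agree to 1e-9 (they agree exactly).

## Known limitations

* The reference BiLM is a small tanh-RNN cloze model: no LSTM gating, no
  layer normalization, one softmax rather than two direction-wise LMs. It is
  a testbed for the pipeline and the fusion sites, not a pretrained-quality
  encoder.
* The error taxonomy for incorrect top-1 pairs ships as labels only
  (`evaluation.ERROR_CATEGORIES`) for human annotation; no classifier.
* Nearest-neighbor search is exact and O(n²); fine at evaluation scale,
  deliberate (approximate search would confound metric comparisons).
* The concept allow-list consumed by `filter_mentions` is an input file;
  there is no ontology access or semantic-type resolution.
* Cross-sentence mention spans are rejected with a diagnostic; how such
  spans should be encoded is genuinely undefined for a sentence-scoped
  encoder.
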