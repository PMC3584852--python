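# Methods

## Label space

Function classes are second-level GO categories: terms exactly one `is_a`
step below a namespace root. Only `is_a` edges define the hierarchy —
`part_of` and other relationships are parsed but discarded — because the
second level is conventionally an `is_a` notion and a single edge type keeps
the upward collapse deterministic. "Level" is the shortest `is_a` distance
from the root, so a term is second-level iff it is a direct child of the
root; a term reachable from the root by both one and several steps still
counts.

Annotation handling, in order: (1) evidence filtering — only the eight
experimental/curated codes (EXP, IDA, IPI, IMP, IGI, IEP, IC, TAS) are kept;
rows with unknown codes are skipped with a warning (robust to newer GAF
releases), and NOT-qualified rows are dropped because a NOT annotation is
evidence *against* membership; (2) upward collapse of each protein's terms to
second-level labels; (3) exclusion of proteins with three or more distinct
second-level labels in the namespace (functionally ambiguous for training);
(4) removal of classes with fewer than `min_class_size` (default 15) member
proteins, together with proteins that thereby lose all labels. Step 4 is a
single pass, not iterated to a fixed point: a class can in principle end up
slightly below the threshold if step 4 ever removed shared proteins, but
members are only removed when they lose *all* labels, so kept-class sizes are
unchanged and the operation is idempotent (tested).

## Text processing

Abstracts are lowercased, split on non-alphanumeric runs, and tokens shorter
than two characters or purely numeric are dropped (they are noise at corpus
scale and their removal is deterministic). Tokens are stemmed with the
classic Porter algorithm — implemented in `textfunc/_porter.py` and
validated against the algorithm's published example vocabulary — then
unigrams and bigrams of consecutive surviving tokens are formed. Bigrams are
built after stemming so the unigram and bigram vocabularies are consistent;
a bigram containing a stop word is dropped, and removed tokens (short/numeric)
do not block adjacency. Stop-word matching is done on stemmed forms of a
fixed English list shipped with the package, so "this" is caught even though
it stems to "thi".

Document-frequency pruning keeps terms present in at least `min_df_count`
(default 3) and at most `max_df_frac` (default 0.7) of the **training**
abstracts of the current fold — both the vocabulary and the characteristic
terms are recomputed per fold so no test-set information leaks into feature
selection. Abstracts linked to more than three labelled proteins whose label
sets are not all equal are excluded once, up front: such an abstract cannot
discriminate a single class. ("Not all equal" rather than "pairwise
different": the rule's purpose is discriminability, and requiring pairwise
distinctness would retain abstracts shared by, say, two classes.)

## Characteristic terms

Pr(t|f) is the maximum-likelihood estimate: the fraction of class-f training
abstracts containing t (presence, not multiplicity). An abstract linked to
proteins of several classes counts in each class's document set. The
significance of Pr(t|f) − Pr(t|f′) is the standard pooled two-proportion
z-statistic with pooled estimate
P̄ = (|D_f|·Pr(t|f) + |D_f′|·Pr(t|f′)) / (|D_f| + |D_f′|). When P̄ is 0 or 1
both proportions sit on the boundary, there is no discriminative evidence,
and Z is defined as 0. A term is characteristic for f iff |Z| > threshold
against every other class of the same namespace (molecular-function and
biological-process feature sets are built independently). The default
threshold 1.96 is the two-sided 5% normal quantile; it is a config knob, and
a signed mode (Z > threshold, i.e. over-representation only) is available
behind a flag, with the absolute-value test as the default.

## Protein vectors

Term weights are raw multiplicities: w(t_i) = count of t_i across the
protein's abstracts D_p divided by the total count of all union terms in D_p
("number of times", read literally, rather than per-abstract presence).
Non-zero vectors therefore sum to 1 (checked to 1e−9); a protein whose
abstracts contain no characteristic term is the all-zero vector.

Textless proteins take the three lowest-e-value homologs that have text
vectors (ties broken by subject id; score-descending ranking when the
backend has no e-values), scale each vector by fractional percent identity,
and divide by the number of homologs actually used — dividing by a fixed 3
when only 1–2 homologs exist would systematically shrink the vector for no
reason. The result is deliberately **not** renormalised: cosine similarity is
scale-invariant, so classification is unaffected, and the stored values
follow the combination formula exactly.

## Classification

Cosine similarity with the convention cosine(0, ·) = 0. The k=10 nearest
training proteins each vote for all of their labels; every class with
≥ `min_votes` = 3 votes is emitted, with confidence the mean cosine of its
voters. Ranking ties are broken by protein id ascending, which makes
predictions invariant to training-set iteration order (tested by
permutation). A zero query vector still yields vote-based predictions —
its top-k is the id-ordered prefix and all confidences are 0 — flagged
`zero_vector=true` so evaluation can segregate them. Search is exact; at the
scale this package targets an index structure would be noise.

Base-Prior fits label frequencies (multi-label proteins count once per
label) and samples one label per protein, confidence = class prior;
`assign_all` mode emits every class for every protein with the prior as
confidence. Base-Seq votes exactly as the text kNN over the top-10
similarity hits; its confidence is the mean percent identity of the voting
hits — no confidence is inherent to the vote, and mean identity mirrors how
sequence-only predictors report confidence, keeping threshold sweeps uniform
across classifiers. Fewer than 10 hits vote as they are; zero hits yield no
predictions (logged). The built-in backend is Smith–Waterman local alignment
(Biopython `PairwiseAligner`, BLOSUM62, gap open 11, extend 1) with percent
identity = identical columns / alignment length; it ranks by score because it
computes no e-value statistics. Precomputed BLAST `-outfmt 6` files and an
external `blastp` wrapper satisfy the same backend contract.

## Evaluation

Stratified folds group proteins by their full label set and split each group
±1 across folds — exact per-class stratification for single-label data, a
close approximation under multi-label (a class spread over several label-set
groups can deviate by the number of groups). Repeat r of the CV uses
seed + r. Metrics are decision-level: per class, TP/FP/FN/TN over all test
proteins, precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R),
specificity = TN/(TN+FP), all 0 on zero denominators (not NaN, so reports
aggregate cleanly). O_acc counts a protein as correct when its predicted and
true label sets intersect — consistent with a classifier that legitimately
assigns any shared label of a multi-function protein; an `all` mode
(every true label required) is a config switch. Confidence thresholds are
strict (kept iff confidence > τ).

## Synthetic data

The generator emulates the statistical structure the selection step assumes:
`planted_terms_per_class` marker tokens per class occur in a member's
abstract with probability `p_in` = 0.6 and elsewhere with `p_out` = 0.05, on
top of a Zipf(1.1) background vocabulary of 2,000 words — the heavy head
supplies the frequent, uninformative words a real corpus has (and that the
70% document-frequency cap prunes). Defaults: 5 classes × 100 proteins, 1–3
abstracts per protein (mean 2, the abstract-to-protein ratio of curated
protein databases), abstract length uniform 80–200 tokens, 10% two-label
proteins. Annotations are written at leaf terms of a three-level DAG so the
level-2 collapse is genuinely exercised. Sequence families are point-mutated
copies of one random ancestor per class at per-site rate
1 − `within_class_identity` (default 0.9); expected pairwise within-family
identity is (1−μ)² + μ²/19 for mutation rate μ. All randomness flows from
one seed; the sequence stream is seeded at seed+1 so corpora with and
without sequences are otherwise identical.

What the generator does **not** emulate: real PubMed syntax and named
entities, correlated term co-occurrence, citation structure, realistic GO
topology (depth, multiple parents across namespaces), domain architecture or
indels in sequences. Passing tests therefore demonstrate correctness of the
machinery and recoverability of a planted signal under clean conditions —
not performance on real UniProt/PubMed-scale data, where class imbalance and
vocabulary overlap are far harsher.

A note on the small-class regime: with these planted effect sizes the
z-statistic of a true marker term stays far above 1.96 even for a
15-protein class (~30 abstracts), so marker *recovery* does not degrade when
a class shrinks. What does reproduce is the dilution effect: a 15-protein
class passes more spurious background words as "characteristic"
(scarce in-class evidence inflates sampling noise past the threshold), which
is the qualitative failure mode observed for small function classes on real
corpora (tested as `test_small_class_accumulates_uninformative_terms`).

## Numerical and reproducibility choices

- All tie-breaks (neighbour ranking, homolog ranking, fold assignment order)
  are lexicographic on ids after the primary key, so every pipeline stage is
  deterministic under a fixed seed; the CLI writes a manifest (config hash,
  seed, version) per run.
- Feature axes are the lexicographically sorted union of per-class term
  sets, fixed before vectorisation.
- Vector normalisation tolerance 1e−9; oracle comparisons in tests use
  1e−12 for confidences and exact equality for neighbour sets and counts.
- Problem sizes in the test suite and `scripts/acceptance.py` — 1,000 random
  draws/instances/DAGs for the oracle equivalences, the 5×100 default fixture
  for end-to-end runs, one stratified fold (100 queries × 400 references) for
  the Base-Seq evaluation, a 10,000-protein fixture for the prior's
  closed-form check — were chosen as the smallest sizes at which the checked
  statistics are stable.

## Known limitations

- No e-value statistics for the built-in aligner; ranking is by raw
  Smith–Waterman score, which is length-biased for heterogeneous reference
  sets (the paper-grade alternative is importing real BLAST tabular output).
- `cellular_component` is parsed but not a supported classification
  namespace.
- Single-pass class filtering (see above) and the any-overlap O_acc
  definition are documented interpretation choices, switchable where a
  config option exists.
- The kNN is exact and in-memory; corpora beyond ~10⁵ proteins would want a
  blocked or approximate search.
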