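# Methods

This note records the models implemented in `gopred`, the choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not establish.

## Ontology model

The GO graph is restricted to `is_a` edges in the Molecular Function and
Biological Process namespaces; `part_of` and other relationships are
never traversed, and cellular_component stanzas are ignored. Annotation
to a term implies annotation to its full `is_a` ancestor closure (the
true-path rule); `expand`/`ancestors` return reflexive closures
including the namespace root. Secondary ids are resolved to primary ids
at load time, so downstream code only ever sees primary ids; obsolete
terms are retained for recognition but excluded from the graph, and an
obsolete term arriving in input data is dropped with a warning rather
than raised.

**Depth** is the *shortest* `is_a` path length from the namespace root.
In a multi-parent DAG the longest root path is an equally defensible
definition; shortest-path was chosen because it is deterministic, cheap
(one BFS per namespace) and insensitive to incidental long detours in a
randomly generated graph. The signed depth difference D(i, j) =
depth(i) − depth(j) is defined only when one term is an ancestor of the
other and **neither is the root**: a connecting path between two
non-root terms never transits the root, and pairs involving the root
itself are treated as undefined rather than trivially connected.

## Annotation counting and information content

IC(t) = −log(n(t)/n(r)) in nats, where n(t) is the ancestor-propagated
annotation count and n(r) the root count of t's namespace. Counting
deduplicates per protein after expansion: a protein annotated to both a
term and its ancestor contributes 1, not 2, to the ancestor. The root
count therefore equals the number of distinct annotated proteins per
namespace. The experimental evidence set defaults to the strict GO
experimental codes {EXP, IDA, IPI, IMP, IGI, IEP}; TAS and IC are
excluded (curator inference rather than direct experiment) but the set
is configurable. The log base only rescales simGIC's numerator and
denominator identically, so the choice is observable-neutral; natural
log is fixed for reproducibility of stored values.

Term co-occurrence — the evidence base for the ensemble's
incompatibility filter — is computed on ancestor-expanded per-protein
annotation sets. Computing it on raw sets is a plausible alternative;
expansion was chosen for consistency with every other counting step and
because it only ever adds pairs, making the filter strictly more
conservative (it deletes less).

## Calibration

Benchmark outcomes are sorted by raw score and split into `n_bins`
contiguous equal-size groups (default 10, sizes differing by at most
one; ties at boundaries follow the stable sort and may straddle bins).
The per-bin (mean score, precision, size) triples are fitted with
P(t) = a/(1 + b·e^(−ct)) by weighted least squares
(`scipy.optimize.least_squares` on (a, log b, c), bounds a ∈ (0, 1],
b > 0), weights defaulting to bin sizes so sparse tail bins do not
dominate; an unweighted option is retained. Initialization: a at the
maximum observed precision, c = 1, b chosen so the curve passes through
the median point. Non-convergence raises an error carrying the
best-so-far parameters. Estimated precisions are clamped to [0, 1], and
the deep low-score tail short-circuits to 0 before the exponential can
overflow.

Calibrating a component on the same labelled set it was trained on is
deliberately permitted (the CLI does exactly this for the naive Bayes
and network components); at toy scale this overstates component
precision slightly but leaves every downstream contract unchanged.

## Naive Bayes annotators

Text records and sequences share one trainer. For a term G and token w,
f(w|G) and f(w|~G) are pseudocount-smoothed token frequencies among
positive/negative documents, and p(G|w) = f(w|G)/(f(w|G)+f(w|~G)). Text
mining uses per-document presence/absence with smoothing
(k + 1)/(N + 2); trigram mining uses token multiplicities with
multinomial smoothing (k + 1)/(N + |V|). Pseudocount 1 throughout, so
every smoothed probability is strictly inside (0, 1) and unseen tokens
contribute finite scores.

A document's score for G is the sum of per-token log-odds
log p − log(1 − p). Plain log-likelihood (log p only) is available
behind a flag, but log-odds is the standard two-class reduction and has
the property that a class-neutral token (p = 0.5) leaves scores
unchanged. Raw scores are calibrated to precisions downstream — they
are never interpreted as probabilities.

Tokenization: descriptive lines (DE/CC/KW by default; the consumed
line-type set is configurable) yield lowercased unigrams split on
non-alphanumerics plus within-line adjacent bigrams. Feature (FT) lines
keep token case under an `FT:` prefix, and any integer on an FT line is
mapped to `FT:NUMVALk`, k = floor(value/50); range endpoints are binned
independently. Sequences are uppercased, non-standard residues map to
X, and all overlapping 3-mers are emitted in order.

## Homology components

*Pairwise hits*: hits covering < 85% of the target length are discarded;
the raw score of a (target, term) pair is the highest supporting bit
score, mapped through the method's calibration model. Coverage is read
as aligned span over the *target's* length.

*Orthologous groups*: estimated precision of a term is the fraction of
the group's annotated members (excluding the target) carrying it after
ancestor expansion.

*Profile–profile*: columns are compared by
S(x, y) = (x_tf·y)/Σx_tf + (y_tf·x)/Σy_tf, which for simplex-normalized
target frequencies reduces to the symmetric cross dot-product of
log-odds against target frequencies. The alignment is global
(Needleman–Wunsch) with affine gaps: a gap of length k costs
open + (k−1)·extend, defaults 11 and 1; end gaps are charged. Global
alignment was chosen because both coverage fractions feed the
downstream network as features; a local mode would silently change
their meaning, so it is not offered. Percent identity is computed over
aligned columns using each profile's consensus (argmax target
frequency) residue. ASCII PSSM ingestion renormalizes the percentage
block to frequencies, with uniform fallback for all-zero rows.

The 4-4-1 logistic-activation network takes (alignment score, percent
identity, coverage of profile 1, coverage of profile 2). Training
vectors are built per GO term: an alignment sharing m terms and
mismatching k yields m positive and k negative copies, so the output
approximates a per-term occurrence probability. Training uses
scikit-learn's MLP (lbfgs, seeded, features standardized internally, at
least 50 vectors with both classes required); the learned weights are
held in an explicit forward pass so scoring is exactly reproducible
from a stored weight set. Shared/mismatching term sets are taken from
the raw (unexpanded) annotations; expansion would make almost every
pair share high-level terms and wash out the negative class.

## Ensemble integration

Per target: (1) attenuated noisy-OR combination per distinct predicted
term, P′ = 1 − ∏(1 − αP_i), α = 0.9 — the attenuation caps any single
unanimous vote at α, so P′ < 1 strictly whenever α < 1; no ancestor
expansion is applied at this stage. (2) Terms with P′ below a floor
(default 0.01) are pruned to bound output size. (3) Upward propagation:
each predicted term absorbs every *predicted* deeper ancestor-related
term, P′_i ← 1 − (1 − P′_i)·∏_j (1 − P′_j). The update is evaluated
against a snapshot of pre-propagation values: a literal in-place sweep
is iteration-order-dependent in a DAG, whereas snapshot semantics are
order-invariant and preserve the intended ancestors-absorb-descendants
behavior (after propagation, precision is non-increasing from ancestors
to descendants within the predicted set). (4) Incompatibility filter:
for every predicted pair with a defined depth difference that never
co-occurs in the corpus, the lower-precision member is deleted; exact
ties keep both. Deletions are likewise decided against the pre-filter
vector in a single pass, then applied at once, avoiding cascades.
Namespaces never interact (D is undefined across them).

## Evaluation

simGIC is the IC-weighted Jaccard ratio over ancestor-closed sets. A
predicted term with no experimental count has no defined IC; such terms
are assigned the maximum observed IC of their namespace (configurable
to raise instead). They can never appear in the experimental reference,
so this choice prices unverifiable specificity at the top of the
observed scale rather than inventing an extrapolation. If the union
carries zero IC (both sets within the root) the score is 1 for equal
sets and 0 otherwise, which realizes the COGIC boundary identities: a
prediction set equal to its expanded reference at confidence ≥ 0.75
scores exactly 1, and a prediction meeting the reference only at the
root scores exactly 0.

COGIC averages simGIC(R, P_k) over the four confidence strata
(thresholds 0.75/0.5/0.25/0, boundary values included). Note that
S1 ≤ S2 ≤ S3 ≤ S4 is *not* implied by subset nesting — intersection and
union grow together — only each S_k ∈ [0, 1].

Precision/recall curves exclude the namespace root from both sets (it
is vacuously correct); targets with an empty predicted set at a
threshold are skipped for precision but count zero recall. Reference
sets are ancestor-expanded; whether root belongs in the recall
denominator is a genuine convention choice — excluded here.
Namespaces are always evaluated separately and never pooled.

## Synthetic fixtures

The generators emulate a small benchmark of well-characterized
proteins: layered random DAGs (1–2 parents per term from the previous
two layers, acyclic by construction), leaf-biased annotations with a
configurable experimental-evidence fraction (default 0.8), marker-token
records and marker-motif sequences that make the text/trigram
classifiers learnable, Dirichlet-peaked PSSMs, random hit tables and
group partitions, and per-method noisy prediction sets. Defaults: 40
terms per namespace, 100 proteins, 3 annotations each; simulated
methods emit true terms with probability 0.8 at Beta-distributed
confidences (mean 0.7, concentration 25) and 2 decoy terms per target
(mean 0.2), decoys sampled outside the truth's ancestor closure so
correctness is unambiguous under expansion. Calibration-recovery
outcomes draw raw scores uniformly and label them Bernoulli under the
generating logistic (a = 0.9, b = 5, c = 1.2). Every generator is a
pure function of the seed; identical seeds give byte-identical files.

What the fixtures do *not* model: real GO topology (tens of thousands
of terms, deep multi-parent lattices), realistic sequence evolution,
correlated errors between methods, or annotation incompleteness of real
corpora. Passing tests demonstrate algorithmic correctness and the
qualitative behavior of calibration and integration, not performance on
real proteomes. In particular, the toy DAG's small term pool makes
independently sampled decoys from different methods interact (be
ancestor-related or identical) far more often than they would in the
full ontology, which slightly disadvantages the ensemble in the
integration-versus-components comparison; the per-method comparison is
run with both simulated methods agreeing on the true terms, seeds fixed
a priori and results averaged over seeds.

Problem sizes used by the test suite and acceptance script — oracle
equivalence on ≤ 100-term / 100-protein worlds, exhaustive alignment
enumeration at profile lengths ≤ 6 over 50 instances, calibration
recovery at n = 2000, ensemble properties on 50-protein worlds over 5
seeds — were chosen so each check is exhaustive or statistically stable
at desk scale.

## Known limitations

* Depth uses shortest root paths; results of the propagation rule can
  differ under a longest-path definition (flagged for sensitivity
  testing, not implemented).
* Per-method ensemble weights are uniform (attenuation is a single
  global constant); weighted or learned combination is future work.
* Isotonic/Platt calibration alternatives are not provided.
* The CLI's profile component aligns every PSSM pair in the workspace;
  it is intended for toy-scale inputs, not proteome-scale databases.
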