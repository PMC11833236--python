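# Methods

## Problem setting

Given the set of literature sentences that mention one RNA identifier, the
pipeline produces a short summary in which every statement is traceable to
a PubMed Central article that the model actually saw. The design premise is
that an LLM's output can only be audited against what was put in front of
it, so the context — not the model — is the unit of provenance: checks
compare the summary to its context, never to the wider literature.

## Sentence harvesting

Mention matching is case-insensitive with word boundaries defined as any
character that is neither alphanumeric nor a hyphen (or a string edge).
Hyphens are treated as word-internal because serial identifiers
(`hsa-mir-21`, `hsa-mir-210`, `hsa-mir-212`) differ only by trailing
characters, and substring hits on such extensions are the dominant
false-positive mode. Whether upstream sentence miners match
case-sensitively is not documented anywhere we could rely on; the
convention here is an explicit choice.

Sentence boundaries come from a deterministic rule: a run of `.!?`
followed by whitespace and an uppercase letter or digit ends a sentence,
unless the preceding token is on an abbreviation guard list ("Fig.",
"et al.", "e.g.", …). The segmenter is a protocol, so a statistical
segmenter can be swapped in; the rule-based one is used everywhere by
default because identical segmentation in the harvester, the citation
parser and the bullet splitter is worth more to the audit trail than
marginally better boundary recall.

Aliases (cross-reference names for the same RNA) contribute sentences
under the primary identifier; each record stores which surface form
matched.

## Token accounting

All budgets are in tokens. The default counter is the estimator
`ceil(words / 0.75)` — the standard English rule of thumb of ~0.75 words
per token — behind a `Tokenizer` protocol; an exact BPE backend can be
plugged in where a tokenizer for the target model is installed. The
default window partition is 4096 total, 2560 for context, ~255 for the
summary, 60–140 for the prompt and ~1150 for a revision round trip, with a
documented slack of 109 tokens because the reservations are estimates, not
guarantees. `TokenBudget` rejects over-committed partitions at
construction.

## Context selection

Dispatch is total and ordered: fewer than five sentences → skip (five
sentences, possibly from a single paper, is the floor below which there is
nothing worth summarising); everything fits the 2560-token cap → take all;
over budget → topic selection if clustering is applicable, else
longest-first fill.

"Applicable" is not defined by any upstream description we could adopt,
so it is defined here: at least `2 × min_cluster_size` sentences (default
min_cluster_size 5) *and* the clusterer actually finds ≥ 2 clusters.
Density clustering below that floor is meaningless.

The topic stage embeds sentences into 384 dimensions, reduces to 20 with
UMAP (seeded; below 22 rows the reduction is ill-posed and input passes
through with a warning), and clusters with HDBSCAN. Exemplars are the top
10 % of each cluster (at least one point) by cluster-membership
probability, ties broken by index — a deterministic stand-in for the
density-core exemplar sets that clustering libraries variously expose.

Round-robin filling visits clusters cyclically, largest first (ties to the
lowest label), taking one unused sentence per visit — exemplars first,
then remaining members in a seeded uniform shuffle — and stops as soon as
the next candidate would overflow the cap. This guarantees every cluster
contributes one sentence before any contributes two, budget permitting.
Noise-labelled sentences become eligible only after every cluster is
exhausted: topical coverage outranks coverage of outliers.

When the exemplars alone overflow the cap, farthest-point greedy selection
runs over exemplars: seed at the largest cluster's exemplar, then
repeatedly add the candidate minimising the *maximum* cosine similarity
(on the reduced vectors) to the already-selected set. "Least similar to
the selected set" admits several aggregates; max-aggregation is the
standard farthest-point heuristic and is the one implemented and tested
against an exhaustive trace.

A single sentence longer than the whole cap is dropped with a logged
warning rather than truncated — truncation would fabricate text the model
could then cite. Selected sentences keep their cluster-interleaved
selection order in the prompt; provenance records the strategy either way.

## Embedding backends

The default embedder hashes lowercased word unigrams and bigrams into a
signed 384-dimensional vector (salted, seeded, L2-normalised). It is
bitwise reproducible, needs no model download, and separates sentences
drawn from distinct vocabularies, which is the property the clustering
stage consumes. A pretrained sentence-transformer backend satisfies the
same protocol for production use where that library is installed. The
hashed embedder is not a semantic model: paraphrases with disjoint
vocabulary will not cluster together, so passing tests demonstrate the
selection machinery, not embedding quality on real prose.

## Prompting

Prompt templates are editable text files with front-matter naming their
placeholders; rendering is literal substitution with no escaping (the
model must see context sentences verbatim to cite them), and a missing
binding is an error that names the missing placeholder.

The initial generation call uses temperature 0.1, presence penalty −2 and
frequency penalty 1: the negative presence penalty encourages restating
tokens from the context, the frequency penalty counteracts verbatim
looping, and the low temperature trades a little fluency for a lower
hallucination rate. Rescue, consistency and revision calls use neutral
penalties (0, 0) at the same temperature — checking and repair should be
conservative; no published setting exists for these calls and this is our
choice.

Five checks share four rescue templates. Formatting and realness failures
are both identifier-validity problems and share one template; the
concentration check (citation stacking) shares the placement template,
both being citation-distribution pathologies. Which check shares with
which is an assumption of this implementation, flagged as such.

## Reference checks

* **Adequacy**: cited identifiers (counted with multiplicity — a two-id
  instance contributes 2) per summary sentence must be ≥ 0.5. Multiplicity
  is used because the ratio is about reference density, not about distinct
  sources.
* **Formatting**: every citation-like token (bracket group, numeric `[1]`
  marker, PMID, DOI, bare `PMC…` token) must be a well-formed
  `PMC<digits>` citation. Parenthesised groups `(PMC1)` are a formatting
  failure in the default strict mode; a lenient mode accepts them.
* **Realness**: the cited PMCID set must be a subset of the context's
  PMCIDs. An empty citation set passes vacuously (adequacy owns absence).
* **Placement**: fails when the summary ends in a pure reference block
  holding every citation, or when more than 20 % of citation instances sit
  mid-sentence. The 0.2 tolerance operationalises "references usually end
  sentences" and is configurable.
* **Concentration**: no instance may hold more than 50 % of all cited
  identifiers. Summaries with fewer than 3 total citations are exempt — a
  literal reading would fail every single-citation summary, defeating the
  check's anti-dumping intent.

Checks run in the fixed order adequacy, formatting, realness, placement,
concentration; the first failure selects the rescue prompt. The order is a
design choice (most-informative-first), not an inherited fact.

Each check is validated two ways: against hand-derived boundary examples,
and against an independent brute-force re-implementation (pure regex and
set arithmetic, in `tests/oracles.py`) over 1000 seeded defect fixtures,
with the defect→detected-check confusion matrix required to be diagonal.

## Consistency checking

The summary is split into one bullet per sentence and the model is asked
for `<n>. TRUE|FALSE — explanation` lines judged only against the context.
Parsing is tolerant (case-insensitive, flexible separators) and
fail-closed: a missing or malformed line becomes UNPARSEABLE, which counts
as a failure and triggers revision. One revision round is performed per
consistency failure — not iterated to a fixed point — after which only the
reference checks are re-run; a revision that breaks the references flags
the item. The module never edits summary text itself; every edit is a
backend response, keeping provenance with the model. Known limitation:
"feedback hallucination" (a revision instruction that itself contains an
unsupported claim) is not detected, and neither are wrong inferences with
indirect support in the context — those require a stronger judge than
string-level checks.

## Orchestration

Per RNA: select context → generate → audit, with a rescue-prompted
regeneration per failure, at most **four total generation attempts**
(initial + up to three rescues — the cap is read literally as attempts to
produce a summary); then one consistency pass and a final reference check.
The attempt counter is global per item, not per check. Terminal statuses
partition into a reference stage (first pass / after revision / flagged
exhausted) and a consistency stage (clean / revised / flagged); skipped
items short-circuit. Flagged and skipped results are retained with full
provenance but excluded from the displayable export under the default
`hide_flagged` policy.

Batches run sequentially: with a deterministic backend, replayability was
judged worth more than parallelism at desk scale, and output order is
input order regardless. Batch statistics report the four stage pass rates
(first-pass references, references after revision, consistency clean,
consistency after revision) computed from the batch's own results, plus
mean attempts and token totals.

## Synthetic data

The fixture generator emulates the output of a literature sentence miner:
per-RNA sentence records tagged with PMC-style identifiers, every sentence
containing the RNA ID verbatim, corpus sizes spanning all selection
regimes. Sentences are templated English over four disjoint controlled
vocabularies (expression, disease association, localization, interaction),
cycled so planted topics are balanced. Default per-sentence length is
20–35 tokens, matching short literature statements; the regime presets use
~20 sentences (fits budget), 8 long sentences (length-sort fallback),
~200 sentences (round-robin) and ~400 longer sentences (greedy), sizes
chosen so each preset lands robustly in its regime under the 2560-token
cap. What the generator does *not* emulate: real scientific prose,
vocabulary overlap between topics, citation noise in the source sentences,
or corpus sizes in the thousands — so passing tests demonstrate the
machinery's contracts, not production-scale behaviour on real literature.

Defective summaries are constructed to violate exactly one named check
(verified internally before being returned); invented PMCIDs are drawn
from a numeric range (≥ 900 000 000) disjoint from every generated corpus.
The `unsupported_claim` defect passes all five reference checks by
construction — only the LLM-mediated consistency stage can catch it, which
is exactly the division of labour the checks are designed around.

Scripted transcripts realize four canonical pipeline paths
(`first_pass_clean`, `rescue_then_clean`, `exhaust_four`,
`consistency_revise`) whose expected terminal statuses and call counts are
table-driven in tests.

## Numerical and degenerate-input choices

Seeded randomness everywhere: corpus generation, within-cluster shuffles
and UMAP all take explicit seeds, and identical corpus + seed + config
reproduce byte-identical contexts. Ties break deterministically (document
order in length sorting, lowest label/index in cluster visiting and greedy
selection). Degenerate inputs degrade explicitly rather than crash: empty
corpora skip, sub-reduction-size matrices pass through with a warning,
nothing-fits selections are flagged degenerate, malformed verdict lines
fail closed, and per-item batch failures yield flagged results.

## Validation problem sizes

The validation suite uses 1000 defect fixtures for the dual-route check
comparison, 200 corpora (40 per regime) for selection properties with a
full re-selection for the determinism comparison, 200 random small
instances for the greedy-versus-exhaustive trace, and 50 seeds for planted
four-topic recovery. These sizes were chosen to exercise every branch and
regime boundary at desk scale while keeping a full run in minutes.
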