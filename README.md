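# litsumm

Referenced, self-audited literature summaries for noncoding RNAs.

Most ncRNAs — miRNAs, lncRNAs, snoRNAs and the rest — have their literature
scattered across hundreds of open-access articles, far more than a curator
can read per RNA. `litsumm` automates the curation step: it collects every
sentence in the literature that mentions a given RNA identifier, packs a
token-budgeted *context* of those sentences, and drives a large language
model through a chain of prompts that generate a summary, audit its
citations, repair specific citation mistakes, and fact-check the summary
against its own context — emitting a referenced summary plus a complete
machine-readable audit trail.

## The pipeline

1. **Harvest** — build the EuropePMC query
   `("<ID>" AND ("rna" OR "mrna" OR "ncrna" OR "lncrna" OR "rrna" OR "sncrna") AND IN_EPMC:Y AND OPEN_ACCESS:Y AND NOT SRC:PPR)`,
   validate the ID is mentioned in each article (case-insensitive,
   word-boundary matching so `hsa-mir-21` never matches `hsa-mir-210`), and
   extract every mentioning sentence. Only local article text is read; the
   network client is an interface with a file-backed stub.
2. **Context construction** — the LLM operates in a 4096-token window; the
   context is capped at 2560 tokens (~1920 words), leaving room for the
   prompt (60–140 tokens), the ~255-token summary, and a ~1150-token
   revision round trip. Corpora with fewer than five sentences are skipped;
   corpora that fit the cap are used whole. Oversized corpora are selected
   from by topic: each sentence is embedded into a 384-dimensional vector,
   reduced to 20 dimensions with UMAP, and clustered with HDBSCAN; cluster
   exemplars are taken round-robin (largest cluster first) until the cap is
   reached, falling through to cluster members. When even the exemplars
   overflow the cap, a farthest-point greedy selection over exemplars
   (minimising the maximum cosine similarity to the already-selected set)
   picks a maximally diverse subset. Small over-budget corpora where
   clustering is meaningless fall back to a longest-first fill.
3. **Generation and reference auditing** — the initial generation call uses
   temperature 0.1, presence penalty −2 (encouraging the model to restate
   context tokens) and frequency penalty 1. Each candidate summary passes
   five checks: *adequacy* (≥ 0.5 citations per sentence), *formatting*
   (PMC-style identifiers only), *realness* (every cited PMCID exists in
   the context), *placement* (citations end the sentences they support),
   and *concentration* (no citation instance holds > 50 % of all
   citations). A failing check selects a check-specific rescue prompt; at
   most four generation attempts are allowed before the item is flagged.
4. **Self-consistency** — the summary is split into one bullet per
   sentence and the model returns a TRUE/FALSE verdict with an explanation
   for each bullet, judged only against the context. Any FALSE triggers a
   single revision call, followed by a final reference check. Flagged
   summaries are retained but excluded from the displayable export.

Every LLM call is logged as one exchange record; results carry per-attempt
provenance, per-check reports, verdicts and batch pass-rate statistics.

A deterministic scripted backend (queued responses keyed by prompt
template) and a synthetic fixture generator make the whole chain testable
offline; an HTTP chat-completion backend targets real endpoints.

## Worked example

```python
from litsumm import *
from litsumm.fixtures import make_script, small_context

ident = RnaIdentifier("MALAT1", aliases=("NEAT2",))
print(build_query(ident))
# ("MALAT1" AND ("rna" OR "mrna" OR "ncrna" OR "lncrna" OR "rrna" OR "sncrna")
#  AND IN_EPMC:Y AND OPEN_ACCESS:Y AND NOT SRC:PPR)

art = ArticleText("PMC8675309",
    "MALAT1 is a conserved lncRNA. Elevated MALAT1 promotes metastasis in "
    "lung adenocarcinoma. Unrelated control sentence here. MALAT1 localizes "
    "to nuclear speckles.")
for r in extract_sentences(art, ident):
    print(r.pmcid, "|", r.sentence)
# PMC8675309 | MALAT1 is a conserved lncRNA.
# PMC8675309 | Elevated MALAT1 promotes metastasis in lung adenocarcinoma.
# PMC8675309 | MALAT1 localizes to nuclear speckles.

ctx = small_context(rna_id="MALAT1", seed=4)      # synthetic 8-sentence context
backend = make_script("first_pass_clean", ctx)    # deterministic scripted LLM
res = run_one("MALAT1", ctx.sentences, backend, PipelineConfig(seed=4), context=ctx)
print(res.status.value, res.displayable)
# consistency_clean True
print(res.pmcids_cited())
# ['PMC7000000', 'PMC7000001', 'PMC7000002', 'PMC7000003']
```

The status pair records that the summary passed all five reference checks
on the first attempt and every bullet was verified TRUE, so the item is
displayable; `res.final_summary` holds the four-sentence summary with one
terminal `[PMC…]` citation per sentence.

The same flow is available from the shell:

```
litsumm harvest   --articles articles/ --ids ids.tsv --out sentences.jsonl
litsumm context   --in sentences.jsonl --out contexts/ --config cfg.toml
litsumm summarize --contexts contexts/ --backend scripted --out results.jsonl
litsumm export    --results results.jsonl --out display.jsonl
litsumm audit     --summary s.txt --context c.json
litsumm fixtures  --out fixtures/ --seed 0
```

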