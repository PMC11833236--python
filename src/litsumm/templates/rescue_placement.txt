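---
name: rescue_placement
placeholders: rna_id, context, summary, issues
---
The summary below about {rna_id} places its references badly: references
should appear at the end of the sentence they support, and no single pair of
brackets should accumulate most of the references. Problem detail: {issues}

Summary:
{summary}

Context sentences (each preceded by its PubMed Central identifier):
{context}

Rewrite the summary so that each sentence ends with the citation(s)
supporting that sentence, formatted like PMCXXXXXX in square brackets.
Spread the citations over the sentences they support instead of collecting
them at the end of the summary or in one bracket. Use only identifiers from
the context and do not use external sources.
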