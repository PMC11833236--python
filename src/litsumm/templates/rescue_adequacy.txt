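---
name: rescue_adequacy
placeholders: rna_id, context, summary, issues
---
The summary below about {rna_id} does not contain enough references for the
number of sentences it has. Problem detail: {issues}

Summary:
{summary}

Context sentences (each preceded by its PubMed Central identifier):
{context}

Rewrite the summary so that each statement carries a citation to the article
that supports it, in square brackets at the end of the sentence, formatted
like PMCXXXXXX. Use only identifiers that appear in the context, do not use
external sources, and keep the summary concise.
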