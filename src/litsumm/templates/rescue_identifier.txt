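---
name: rescue_identifier
placeholders: rna_id, context, summary, issues
---
The summary below about {rna_id} cites its sources incorrectly: it uses
reference identifiers that are malformed or that do not appear in the
provided context. Problem detail: {issues}

Summary:
{summary}

Context sentences (each preceded by its PubMed Central identifier):
{context}

Rewrite the summary citing only PubMed Central identifiers that appear in
the context, formatted like PMCXXXXXX in square brackets at the end of each
supported sentence. Never invent an identifier and never use any other
citation style (no numeric markers, no PMIDs, no DOIs). Do not use external
sources.
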