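---
name: consistency_revise
placeholders: rna_id, context, summary, issues
---
The summary below about {rna_id} contains statements that are not supported
by the context it was generated from. A statement-by-statement verification
follows; statements marked FALSE are unsupported.

Summary:
{summary}

Verification:
{issues}

Context sentences (each preceded by its PubMed Central identifier):
{context}

Amend the summary: remove or correct every statement marked FALSE so that
everything remaining is supported by the context. Keep the citation style
(PubMed Central identifiers like PMCXXXXXX in square brackets at the end of
each supported sentence), cite only identifiers from the context, and do not
use external sources.
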