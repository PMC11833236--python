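---
name: consistency_check
placeholders: rna_id, context, bullets
---
Below is a summary about the RNA {rna_id}, broken into numbered statements,
followed by the context sentences it was generated from.

Statements:
{bullets}

Context sentences (each preceded by its PubMed Central identifier):
{context}

For each numbered statement, decide whether it is supported by the context.
Answer with one line per statement, in this exact format:

<number>. TRUE — <explanation quoting the supporting context sentence>
<number>. FALSE — <explanation of why the context does not support it>

Judge only against the context above; do not use external knowledge. A
statement that goes beyond what the context says is FALSE.
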