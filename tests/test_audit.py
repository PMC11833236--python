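import pytest
from hypothesis import given, settings, strategies as st

from litsumm.audit import (
    CHECK_ORDER,
    Check,
    CheckThresholds,
    check_adequacy,
    check_concentration,
    check_formatting,
    check_placement,
    check_realness,
    parse_citations,
    run_all,
)
from litsumm.context import Context
from litsumm.fixtures import Defect, DefectSpec, make_defective_summary, small_context
from litsumm.harvest import SentenceRecord

from oracles import (
    oracle_adequacy,
    oracle_concentration,
    oracle_formatting,
    oracle_placement,
    oracle_realness,
)


def ctx_with(pmcids, rna_id="rna-x"):
    return Context(
        rna_id=rna_id,
        sentences=[
            SentenceRecord(rna_id, p, f"{rna_id} does thing {i}.", token_count=5)
            for i, p in enumerate(pmcids)
        ],
        total_tokens=5 * len(pmcids),
        strategy="all",
    )


class TestParseCitations:
    def test_single_terminal_bracket(self):
        inst = parse_citations("X silences Y [PMC12345].")
        assert len(inst) == 1
        assert inst[0].pmcids == ["PMC12345"]
        assert inst[0].terminal

    def test_multi_id_group_is_one_instance(self):
        inst = parse_citations("Claim here [PMC1, PMC2, PMC3].")
        assert len(inst) == 1
        assert inst[0].pmcids == ["PMC1", "PMC2", "PMC3"]

    def test_malformed_group_yields_no_instance(self):
        assert parse_citations("Claim [PMCabc].") == []

    def test_bare_token_is_singleton_instance(self):
        inst = parse_citations("As shown in PMC99 earlier.")
        assert len(inst) == 1 and inst[0].pmcids == ["PMC99"]
        assert not inst[0].terminal

    def test_sentence_index_assignment(self):
        inst = parse_citations("First [PMC1]. Second claim [PMC2].")
        assert [i.sentence_index for i in inst] == [0, 1]

    def test_char_spans_within_summary(self):
        s = "A [PMC1]. B [PMC2, PMC3]."
        for i in parse_citations(s):
            a, b = i.char_span
            assert 0 <= a < b <= len(s)
            assert "PMC" in s[a:b]


class TestAdequacy:
    def test_boundary_ratio_exactly_half_passes(self):
        s = "One [PMC1]. Two. Three [PMC2]. Four."
        r = check_adequacy(s, parse_citations(s))
        assert r.passed and r.detail["ratio"] == 0.5

    def test_below_boundary_fails_with_ratio(self):
        s = "One [PMC1]. Two. Three. Four."
        r = check_adequacy(s, parse_citations(s))
        assert not r.passed and r.detail["ratio"] == 0.25
        assert r.rescue_template == "rescue_adequacy"

    def test_uncited_single_sentence_fails(self):
        s = "Only one sentence with no citation."
        assert not check_adequacy(s, parse_citations(s)).passed

    def test_multiplicity_counting(self):
        # one two-id instance over two sentences: ratio 1.0
        s = "One claim [PMC1, PMC2]. Second claim."
        assert check_adequacy(s, parse_citations(s)).detail["ratio"] == 1.0

    def test_empty_summary_is_an_error(self):
        with pytest.raises(ValueError):
            check_adequacy("", [])


class TestFormatting:
    def test_pmc_only_citations_pass(self):
        s = "A [PMC123]. B [PMC4, PMC5]."
        assert check_formatting(s, parse_citations(s)).passed

    def test_numeric_marker_fails_with_span(self):
        s = "A claim [1]. B [PMC2]."
        r = check_formatting(s, parse_citations(s))
        assert not r.passed
        assert any("[1]" in o["text"] for o in r.detail["offending"])

    def test_pmid_style_fails(self):
        s = "A claim (PMID: 12345). B [PMC2]."
        assert not check_formatting(s, parse_citations(s)).passed

    def test_malformed_pmc_token_fails(self):
        s = "A claim [PMCabc]."
        assert not check_formatting(s, parse_citations(s)).passed

    def test_parenthesized_strict_vs_lenient(self):
        s = "A claim (PMC123)."
        assert not check_formatting(s, parse_citations(s)).passed
        assert check_formatting(
            s, parse_citations(s, lenient_parentheses=True), lenient_parentheses=True
        ).passed


class TestRealness:
    def test_subset_passes(self):
        r = check_realness(parse_citations("A [PMC1]."), ctx_with(["PMC1", "PMC2"]))
        assert r.passed

    def test_invented_id_fails_and_is_named(self):
        r = check_realness(parse_citations("A [PMC9]."), ctx_with(["PMC1"]))
        assert not r.passed and r.detail["offending"] == ["PMC9"]

    def test_no_citations_pass_vacuously(self):
        assert check_realness([], ctx_with(["PMC1"])).passed


class TestPlacement:
    def test_all_terminal_passes(self):
        s = "A [PMC1]. B [PMC2]. C [PMC3]."
        assert check_placement(parse_citations(s), s).passed

    def test_trailing_block_fails(self):
        s = "A does X. B does Y. [PMC1] [PMC2] [PMC3]"
        r = check_placement(parse_citations(s), s)
        assert not r.passed and r.detail["trailing_block"]

    def test_one_of_ten_nonterminal_passes(self):
        sentences = [f"Claim number {i} [PMC{i}]." for i in range(9)]
        s = " ".join(sentences) + " Here PMC9 appears mid sentence nine."
        inst = parse_citations(s)
        assert len(inst) == 10
        assert check_placement(inst, s).passed

    def test_majority_nonterminal_fails(self):
        s = "Here [PMC1] is cited early. And [PMC2] again early."
        assert not check_placement(parse_citations(s), s).passed


class TestConcentration:
    def test_exactly_half_passes(self):
        s = "A [PMC1, PMC2]. B [PMC3]. C [PMC4]."
        r = check_concentration(parse_citations(s))
        assert r.passed and r.detail["max_instance"] == 2

    def test_three_quarters_fails(self):
        s = "A [PMC1, PMC2, PMC3]. B [PMC4]."
        assert not check_concentration(parse_citations(s)).passed

    def test_small_total_exempt(self):
        s = "A [PMC1]."
        r = check_concentration(parse_citations(s))
        assert r.passed and r.detail["exempt"]


class TestRunAll:
    def test_clean_summary_passes_all_five(self, base_context):
        s = make_defective_summary(DefectSpec(Defect.NONE, base_context))
        result = run_all(s, base_context)
        assert result.passed
        assert [r.check for r in result.reports] == list(CHECK_ORDER)

    def test_invented_pmcid_triggers_realness_rescue(self, base_context):
        s = make_defective_summary(DefectSpec(Defect.INVENTED_PMCID, base_context))
        result = run_all(s, base_context)
        assert not result.passed
        assert result.first_failure.check is Check.REALNESS
        assert result.rescue_template == "rescue_realness"

    def test_first_failing_check_selects_rescue(self, base_context):
        # fails adequacy (1 ref / 4 sentences) and placement (trailing block)
        s = "A does X. B does Y. C does Z. [PMC7000000]"
        result = run_all(s, base_context)
        failed = [r.check for r in result.reports if not r.passed]
        assert Check.ADEQUACY in failed and Check.PLACEMENT in failed
        assert result.rescue_template == "rescue_adequacy"

    def test_checks_are_pure(self, base_context):
        s = make_defective_summary(DefectSpec(Defect.STACKED_REFS, base_context))
        a = run_all(s, base_context)
        b = run_all(s, base_context)
        assert [r.passed for r in a.reports] == [r.passed for r in b.reports]
        assert a.to_json() == b.to_json()


class TestOracleEquivalence:
    """Each check agrees with an independent regex/set-arithmetic oracle on
    randomized defect fixtures, and each defect trips exactly its check."""

    N_FIXTURES = 1000

    def _fixtures(self):
        defects = [d for d in Defect if d is not Defect.UNSUPPORTED_CLAIM]
        ctxs = [small_context(seed=s) for s in range(4)]
        out = []
        i = 0
        while len(out) < self.N_FIXTURES:
            d = defects[i % len(defects)]
            ctx = ctxs[i % len(ctxs)]
            out.append((d, ctx, make_defective_summary(DefectSpec(d, ctx, seed=i))))
            i += 1
        return out

    def test_checks_agree_with_bruteforce_oracle(self):
        mismatches = []
        for d, ctx, s in self._fixtures():
            result = run_all(s, ctx)
            got = {r.check.value: r.passed for r in result.reports}
            want = {
                "adequacy": oracle_adequacy(s),
                "formatting": oracle_formatting(s),
                "realness": oracle_realness(s, ctx.pmcids),
                "placement": oracle_placement(s),
                "concentration": oracle_concentration(s),
            }
            if got != want:
                mismatches.append((d.value, got, want, s))
        assert not mismatches, mismatches[:3]

    def test_defect_confusion_matrix_is_diagonal(self):
        from litsumm.fixtures import DEFECT_TO_CHECK

        for d, ctx, s in self._fixtures():
            result = run_all(s, ctx)
            failed = {r.check for r in result.reports if not r.passed}
            intended = DEFECT_TO_CHECK[d]
            assert failed == ({intended} if intended else set()), (d, failed)


@settings(max_examples=60, deadline=None)
@given(n_cited=st.integers(0, 4))
def test_adding_terminal_citation_never_breaks_adequacy(n_cited):
    """Monotonicity: appending one more valid terminal citation can only
    raise the reference/sentence ratio."""
    sentences = [f"Claim number {i}" for i in range(4)]
    cited = [f"{s} [PMC{i}]." for i, s in enumerate(sentences[:n_cited])]
    cited += [f"{s}." for s in sentences[n_cited:]]
    before = " ".join(cited)
    after = before[:-1] + " [PMC9]."
    r_before = check_adequacy(before, parse_citations(before))
    r_after = check_adequacy(after, parse_citations(after))
    if r_before.passed:
        assert r_after.passed
    assert r_after.detail["ratio"] >= r_before.detail["ratio"]
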