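"""Consensus merging, TMB arithmetic, and immune-escape flagging."""

import pytest
from hypothesis import given, settings, strategies as st

from rrdkit.variants import (
    DEFAULT_IMMUNE_ESCAPE_GENES,
    ImmuneEscapePanel,
    TMBResult,
    VariantCall,
    compute_tmb,
    flag_immune_escape,
    merge_consensus,
    normalize_alleles,
)


def call(caller, pos=100, ref="A", alt="T", **kw):
    return VariantCall(chrom="chr1", pos=pos, ref=ref, alt=alt, caller=caller, **kw)


class TestVariantCall:
    def test_snv_and_indel_classes_follow_allele_lengths(self):
        assert call("c").vclass == "SNV"
        assert call("c", ref="AT", alt="A").vclass == "indel"

    @pytest.mark.parametrize(
        "kw",
        [
            dict(ref="A", alt="A"),
            dict(ref="", alt="T"),
            dict(pos=0),
            dict(vaf=1.5),
        ],
    )
    def test_invalid_calls_rejected(self, kw):
        base = dict(chrom="chr1", pos=5, ref="A", alt="T", caller="x")
        with pytest.raises(ValueError):
            VariantCall(**{**base, **kw})


class TestAlleleNormalization:
    @pytest.mark.parametrize(
        "given_, expected",
        [
            ((100, "A", "T"), (100, "A", "T")),  # SNV untouched
            ((100, "ATT", "AT"), (100, "AT", "A")),  # shared suffix trimmed
            ((100, "CAA", "CA"), (100, "CA", "C")),  # suffix then stop at len 1
            ((100, "GCAA", "GCA"), (101, "CA", "C")),  # suffix, then prefix
            ((100, "CTG", "CAG"), (101, "T", "A")),  # padded SNV reduced
            ((100, "A", "AT"), (100, "A", "AT")),  # already minimal
        ],
    )
    def test_parsimonious_representation(self, given_, expected):
        assert normalize_alleles(*given_) == expected

    @given(
        pos=st.integers(1, 10_000),
        core_ref=st.text("ACGT", min_size=1, max_size=4),
        core_alt=st.text("ACGT", min_size=1, max_size=4),
        pad_left=st.text("ACGT", max_size=3),
        pad_right=st.text("ACGT", max_size=3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_normalization_is_idempotent_and_padding_invariant(
        self, pos, core_ref, core_alt, pad_left, pad_right
    ):
        if core_ref == core_alt:
            return
        norm = normalize_alleles(
            pos - len(pad_left) + len(pad_left),  # 1-based anchor of padded ref
            pad_left + core_ref + pad_right,
            pad_left + core_alt + pad_right,
        )
        assert normalize_alleles(*norm) == norm  # idempotent


class TestConsensusMerge:
    def test_two_of_four_retained_one_of_four_dropped(self):
        callsets = {
            "callerA": [call("callerA"), call("callerA", pos=200)],
            "callerB": [call("callerB")],
            "callerC": [],
            "callerD": [],
        }
        merged = merge_consensus(callsets, min_callers=2)
        assert [v.key for v in merged] == [("chr1", 100, "A", "T")]
        assert merged.variants[0].callers == frozenset({"callerA", "callerB"})

    def test_duplicate_calls_by_one_caller_count_once(self):
        callsets = {
            "callerA": [call("callerA"), call("callerA")],
            "callerB": [call("callerB")],
            "callerC": [call("callerC")],
            "callerD": [call("callerD")],
        }
        merged = merge_consensus(callsets, min_callers=2)
        assert len(merged) == 1
        assert len(merged.variants[0].callers) == 4

    def test_discordant_indel_representations_match_after_normalization(self):
        # same 1-bp deletion written with and without redundant context
        callsets = {
            "callerA": [call("callerA", pos=100, ref="GCTT", alt="GCT")],
            "callerB": [call("callerB", pos=101, ref="CT", alt="C")],
        }
        merged = merge_consensus(callsets, min_callers=2)
        assert len(merged) == 1
        assert merged.variants[0].key == ("chr1", 101, "CT", "C")

    def test_consensus_vaf_and_depth_are_medians(self):
        callsets = {
            "callerA": [call("callerA", vaf=0.1, depth=100)],
            "callerB": [call("callerB", vaf=0.3, depth=200)],
            "callerC": [call("callerC", vaf=0.5, depth=300)],
        }
        merged = merge_consensus(callsets, min_callers=2)
        assert merged.variants[0].vaf == pytest.approx(0.3)
        assert merged.variants[0].depth == pytest.approx(200)

    def test_lowering_min_callers_never_removes_a_variant(self, rng):
        callsets = {
            c: [
                call(c, pos=int(p))
                for p in rng.choice(range(100, 2000, 10), size=40, replace=False)
            ]
            for c in ("callerA", "callerB", "callerC", "callerD")
        }
        kept = {
            k: {v.key for v in merge_consensus(callsets, min_callers=k)}
            for k in (1, 2, 3, 4)
        }
        assert kept[4] <= kept[3] <= kept[2] <= kept[1]

    def test_merge_is_idempotent(self):
        callsets = {
            "callerA": [call("callerA"), call("callerA", pos=300, ref="GT", alt="G")],
            "callerB": [call("callerB"), call("callerB", pos=300, ref="GT", alt="G")],
        }
        once = merge_consensus(callsets, min_callers=2)
        again = merge_consensus(
            {"consensus": [
                VariantCall(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                            caller="consensus", vaf=v.vaf, depth=v.depth)
                for v in once
            ]},
            min_callers=1,
        )
        assert {v.key for v in again} == {v.key for v in once}

    def test_empty_callsets_rejected(self):
        with pytest.raises(ValueError):
            merge_consensus({}, min_callers=2)


class TestTMB:
    def test_500_snvs_over_50_mb_is_10(self):
        callsets = {
            "callerA": [call("callerA", pos=100 + i) for i in range(500)],
            "callerB": [call("callerB", pos=100 + i) for i in range(500)],
        }
        res = compute_tmb(merge_consensus(callsets), callable_mb=50)
        assert res.tmb == pytest.approx(10.0)

    def test_zero_snvs_gives_zero(self):
        assert TMBResult(n_snv=0, callable_mb=50).tmb == 0.0

    def test_indels_excluded_from_numerator(self):
        # 9,982 SNVs + 1,000 indels over 50 Mb -> 199.64 mut/Mb
        snvs = [call("x", pos=10 + 2 * i) for i in range(9982)]
        indels = [call("x", pos=100_000 + 2 * i, ref="AT", alt="A")
                  for i in range(1000)]
        callsets = {"callerA": snvs + indels, "callerB": snvs + indels}
        res = compute_tmb(merge_consensus(callsets), callable_mb=50)
        assert res.n_snv == 9982
        assert res.tmb == pytest.approx(199.64)

    def test_tmb_linear_in_snv_count(self):
        tmbs = [TMBResult(n_snv=n, callable_mb=50).tmb for n in (100, 200, 400)]
        assert tmbs[1] == pytest.approx(2 * tmbs[0])
        assert tmbs[2] == pytest.approx(4 * tmbs[0])

    def test_nonpositive_callable_mb_rejected(self):
        with pytest.raises(ValueError):
            TMBResult(n_snv=5, callable_mb=0)


class TestImmuneEscape:
    def _consensus(self, genes):
        callsets = {
            "callerA": [call("callerA", pos=100 + 10 * i, gene=g)
                        for i, g in enumerate(genes)],
            "callerB": [call("callerB", pos=100 + 10 * i, gene=g)
                        for i, g in enumerate(genes)],
        }
        return merge_consensus(callsets)

    def test_default_panel_has_eleven_genes_and_zero_rows_kept(self):
        table = flag_immune_escape(self._consensus(["TP53"]))
        assert len(table) == 11
        assert set(table["gene"]) == set(DEFAULT_IMMUNE_ESCAPE_GENES)
        assert (table["n_variants"] == 0).all()

    def test_b2m_hit_counted_and_matching_case_insensitive(self):
        table = flag_immune_escape(self._consensus(["b2m ", "JAK1", "jak1"]))
        counts = dict(zip(table["gene"], table["n_variants"]))
        assert counts["B2M"] == 1
        assert counts["JAK1"] == 2

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            ImmuneEscapePanel(genes=())
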