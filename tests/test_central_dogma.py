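"""Edit scripts, recombination, and the DNA -> mature mRNA pipeline."""

import random
from collections import Counter

import pytest

from basefive.central_dogma import (
    DeleteE,
    EditScript,
    InsertE,
    PipelineTrace,
    Substitute,
    apply_edit_script,
    central_dogma_pipeline,
    codon_partition,
    invert_edit_script,
    mature,
    recombine,
    splice,
    transcribe,
)
from basefive.operator_vector import OpVector, inverse_op
from basefive.sequence_model import parse_explicit, random_seq


class TestEditScripts:
    def eq29_script(self):
        # change CGT -> GTA in places 1-3, then insert GC after place 3
        return EditScript(
            [
                Substitute(OpVector({1: 3, 2: 4, 3: 4})),
                InsertE(after_place=3, count=2),
                Substitute(OpVector({4: 4, 5: 1})),  # E->G, E->C
            ]
        )

    def test_substitution_plus_insertion_worked_example(self):
        d_j = parse_explicit("CGTATC")
        d_k = apply_edit_script(d_j, self.eq29_script())
        assert d_k.to_text("conventional") == "GTAGCATC"
        assert d_k.entries == parse_explicit("GTAGCATC").entries

    def test_empty_script_is_identity(self, eq2b):
        assert apply_edit_script(eq2b, EditScript()).entries == eq2b.entries

    def test_trace_returns_every_intermediate(self):
        d_j = parse_explicit("CGTATC")
        final, states = apply_edit_script(d_j, self.eq29_script(), trace=True)
        assert len(states) == 4
        assert states[0].entries == d_j.entries
        assert states[-1].entries == final.entries

    def test_inverted_script_undoes_the_edit(self):
        d_j = parse_explicit("CGTATC")
        script = self.eq29_script()
        d_k = apply_edit_script(d_j, script)
        back = apply_edit_script(d_k, invert_edit_script(script))
        assert back.entries == d_j.entries


class TestRecombination:
    def worked(self):
        d_c1 = parse_explicit("G1 E2 T3 A4 G5 T6")
        d_d1 = parse_explicit("ATAGCTA")
        return recombine(d_c1, (3, 6), d_d1, (3, 7))

    def test_worked_outputs(self):
        res = self.worked()
        assert res.out_c.entries == parse_explicit(
            "G1 E2 A3 G4 C5 T6 A7 E8 E9 E10 E11"
        ).entries
        assert res.out_d.entries == parse_explicit(
            "A1 T2 E3 E4 E5 E6 E7 T8 A9 G10 T11"
        ).entries
        assert res.out_c.to_text("conventional") == "GAGCTA"
        assert res.out_d.to_text("conventional") == "ATTAGT"

    def test_worked_operators_and_inverse_identity(self):
        res = self.worked()
        assert res.op_c.entries == OpVector.from_aliases(
            ["n", "n", "u", "l", "r", "d", "u", "u", "d", "r", "u"]
        ).entries
        assert res.op_d.entries == OpVector.from_aliases(
            ["n", "n", "d", "r", "l", "u", "d", "d", "u", "l", "d"]
        ).entries
        # the paired operators are componentwise inverses (segments aligned here)
        assert inverse_op(res.op_c).entries == res.op_d.entries

    def test_swapping_identical_content_changes_nothing_conventionally(self):
        s1 = parse_explicit("ACGTAC")
        s2 = parse_explicit("TTCGTA")
        res = recombine(s1, (2, 4), s2, (3, 5))  # both segments read CGT
        assert res.out_c.to_text("conventional") == s1.to_text("conventional")
        assert res.out_d.to_text("conventional") == s2.to_text("conventional")

    def test_base_content_is_conserved(self):
        rng = random.Random(42)
        for _ in range(50):
            s1 = random_seq(rng.randrange(2**31), rng.randint(3, 15), 0.2)
            s2 = random_seq(rng.randrange(2**31), rng.randint(3, 15), 0.2)
            f1 = rng.randint(1, s1.max_place)
            l1 = rng.randint(f1, s1.max_place)
            f2 = rng.randint(1, s2.max_place)
            l2 = rng.randint(f2, s2.max_place)
            res = recombine(s1, (f1, l1), s2, (f2, l2))
            before = Counter(s1.to_text("conventional")) + Counter(
                s2.to_text("conventional")
            )
            after = Counter(res.out_c.to_text("conventional")) + Counter(
                res.out_d.to_text("conventional")
            )
            assert before == after
            # pattern-level inverse pairing: re-anchor op_c's inverse at seg_d
            assert inverse_op(res.op_c).shift(f2 - f1).entries == res.op_d.entries

    def test_aligned_segments_satisfy_strict_inverse_identity(self):
        rng = random.Random(7)
        for _ in range(50):
            s1 = random_seq(rng.randrange(2**31), 12, 0.2)
            s2 = random_seq(rng.randrange(2**31), 12, 0.2)
            f = rng.randint(1, 8)
            res = recombine(s1, (f, rng.randint(f, 12)), s2, (f, rng.randint(f, 12)))
            assert inverse_op(res.op_c).entries == res.op_d.entries

    def test_invalid_segments_rejected(self):
        s = parse_explicit("ACGT")
        with pytest.raises(ValueError):
            recombine(s, (3, 2), s, (1, 2))  # length-0/invalid bounds
        with pytest.raises(ValueError):
            recombine(s, (1, 9), s, (1, 2))  # beyond explicit span
        with pytest.raises(ValueError):
            recombine(s, (1, 2), parse_explicit("ACGU", alphabet="RNA"), (1, 2))


class TestTranscription:
    def test_relabels_T_as_U(self):
        s = parse_explicit("A1 G2 T3 A4 E5 T6 C7 G8 A9 C10 T11")
        r = transcribe(s)
        assert r.alphabet == "RNA"
        assert r.to_text("conventional") == "AGUAUCGACU"
        assert r.entries == s.entries  # indices and places untouched
        assert r.length_N() == s.length_N()

    def test_all_E_vector(self):
        assert transcribe(parse_explicit("E1 E2")).alphabet == "RNA"

    def test_rna_input_rejected(self):
        with pytest.raises(ValueError):
            transcribe(parse_explicit("ACGU", alphabet="RNA"))


class TestSplicing:
    def pre_mrna(self):
        return parse_explicit("A1 G2 U3 A4 E5 U6 C7 G8 A9 C10 U11", alphabet="RNA")

    def test_intron_bases_become_explicit_Es(self):
        spliced = splice(self.pre_mrna(), [(2, 4)])
        assert spliced.entries == parse_explicit(
            "A1 E2 E3 E4 E5 U6 C7 G8 A9 C10 U11", alphabet="RNA"
        ).entries

    def test_empty_intron_list_is_identity(self):
        assert splice(self.pre_mrna(), []).entries == self.pre_mrna().entries

    def test_splice_preserves_span_and_only_mature_renumbers(self):
        s = self.pre_mrna()
        spliced = splice(s, [(2, 4)])
        assert spliced.max_place == s.max_place
        assert mature(spliced).entries == parse_explicit(
            "AUCGACU", alphabet="RNA"
        ).entries

    def test_bad_intervals_rejected(self):
        with pytest.raises(ValueError):
            splice(self.pre_mrna(), [(2, 4), (4, 6)])  # overlap
        with pytest.raises(ValueError):
            splice(self.pre_mrna(), [(10, 20)])  # outside span
        with pytest.raises(ValueError):
            splice(parse_explicit("ACGT"), [(1, 2)])  # DNA input


class TestMaturation:
    def test_worked_example_and_idempotence(self):
        s = parse_explicit("A1 E2 E3 E4 E5 U6 C7 G8 A9 C10 U11", alphabet="RNA")
        m = mature(s)
        assert m.entries == {1: 2, 2: 3, 3: 1, 4: 4, 5: 2, 6: 1, 7: 3}  # AUCGACU
        assert mature(m).entries == m.entries

    def test_all_E_matures_to_empty(self):
        assert mature(parse_explicit("E1 E2", alphabet="RNA")).entries == {}


class TestPipeline:
    def test_full_worked_chain(self):
        s = parse_explicit("TCATEAGCTGA")
        trace = central_dogma_pipeline(s, introns=[(2, 4)], trace=True)
        assert isinstance(trace, PipelineTrace)
        assert trace.antisense.entries == parse_explicit(
            "A1 G2 T3 A4 E5 T6 C7 G8 A9 C10 T11"
        ).entries
        assert trace.pre_mrna.to_text("conventional") == "AGUAUCGACU"
        assert trace.spliced.entries == parse_explicit(
            "A1 E2 E3 E4 E5 U6 C7 G8 A9 C10 U11", alphabet="RNA"
        ).entries
        assert trace.mrna.to_text("conventional") == "AUCGACU"

    def test_no_intron_all_E_input(self):
        out = central_dogma_pipeline(parse_explicit("E1 E2"))
        assert out.entries == {}
        assert out.alphabet == "RNA"

    def test_no_intron_output_is_complement_of_transcript(self):
        s = parse_explicit("TCGGATC")
        out = central_dogma_pipeline(s)
        direct = transcribe(s)
        from basefive.operator_vector import complement_seq

        assert out.to_text("conventional") == mature(
            transcribe(complement_seq(s))
        ).to_text("conventional")
        # skipping the complement transcribes the given strand directly
        assert central_dogma_pipeline(s, complement=False).to_text(
            "conventional"
        ) == direct.to_text("conventional")

    def test_output_never_contains_T_or_E(self):
        rng = random.Random(5)
        for _ in range(30):
            s = random_seq(rng.randrange(2**31), rng.randint(0, 20), 0.2)
            text = central_dogma_pipeline(s).to_text("conventional")
            assert "T" not in text and "E" not in text

    def test_rna_input_rejected(self):
        with pytest.raises(ValueError):
            central_dogma_pipeline(parse_explicit("ACGU", alphabet="RNA"))


class TestCodonPartition:
    @pytest.mark.parametrize(
        "frame,expected",
        [
            (0, ["AUC", "GAC", "U"]),
            (1, ["A", "UCG", "ACU"]),
            (2, ["AU", "CGA", "CU"]),
        ],
    )
    def test_reading_frames(self, frame, expected):
        mrna = parse_explicit("AUCGACU", alphabet="RNA")
        assert codon_partition(mrna, frame) == expected

    def test_empty_and_errors(self):
        assert codon_partition(parse_explicit("", alphabet="RNA")) == []
        with pytest.raises(ValueError):
            codon_partition(parse_explicit("A1 E2 C3", alphabet="RNA"))
        with pytest.raises(ValueError):
            codon_partition(parse_explicit("AUC", alphabet="RNA"), frame=3)
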