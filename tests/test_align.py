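import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amplimeth.align import (
    AmpliconTemplate,
    ScoringScheme,
    align_read,
    bisulfite_convert_template,
    filter_reads,
    local_alignment_score,
    max_attainable_score,
    revcomp,
)
from amplimeth.synthetic import default_template, gen_bisulfite_reads
from oracles import brute_force_local_affine

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestTemplateConversion:
    @pytest.mark.parametrize("seq,cpg,fwd", [
        ("CACGT", [2], "TAYGT"),
        ("CGCG", [0, 2], "YGYG"),
        ("ATTA", [], "ATTA"),  # no cytosines: unchanged
    ])
    def test_forward_forms(self, seq, cpg, fwd):
        assert bisulfite_convert_template(seq, cpg)[0] == fwd

    def test_reverse_form_is_converted_minus_strand(self):
        # converting the minus strand directly and mapping back to plus
        # coordinates must equal the reverse reference
        seq = "CACGTTGGACGA"
        cpg = [2, 9]
        _, rev = bisulfite_convert_template(seq, cpg)
        minus = revcomp(seq)
        minus_cpg = {len(seq) - 2 - p for p in cpg}
        conv_minus = "".join(
            "Y" if (b == "C" and i in minus_cpg) else ("T" if b == "C" else b)
            for i, b in enumerate(minus)
        )
        assert revcomp(conv_minus) == rev

    def test_bad_position_rejected(self):
        with pytest.raises(ValueError):
            bisulfite_convert_template("CACGT", [1])

    def test_lengths_preserved(self, template):
        assert len(template.forward_ref) == len(template.seq)
        assert len(template.reverse_ref) == len(template.seq)


class TestScoringScheme:
    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=0)
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=-1, gap_extend=-2)

    def test_wildcards_score_as_match(self):
        m = ScoringScheme().matrix()
        code = {"A": 0, "C": 1, "G": 2, "T": 3, "Y": 4, "R": 5}
        assert m[code["C"], code["Y"]] == 1 and m[code["T"], code["Y"]] == 1
        assert m[code["A"], code["R"]] == 1 and m[code["G"], code["R"]] == 1
        assert m[code["A"], code["Y"]] == -1


class TestMaxAttainable:
    def test_definition(self):
        assert max_attainable_score(100, ScoringScheme()) == 100
        assert max_attainable_score(1, ScoringScheme(match=2.0)) == 2

    def test_error_free_reads_attain_it(self, template):
        reads, _ = gen_bisulfite_reads(template, [0.5] * 3, n_reads=20, seed=1)
        for rid, seq in reads:
            aln = align_read(seq, template, read_id=rid)
            assert aln.score == max_attainable_score(len(seq), ScoringScheme())
            assert aln.score_fraction == 1.0


class TestAlignRead:
    def test_identity_alignment(self):
        tmpl = AmpliconTemplate("t", "ATTAGGTTAGGATTTAGGATTAGGTTAGGATTAGGTTTAGGATTAGGTTAGGATTAGGTA")
        read = tmpl.forward_ref
        aln = align_read(read, tmpl)
        assert aln.score == len(read)
        assert aln.score_fraction == 1.0
        assert aln.orientation == "forward"
        assert (aln.start, aln.end) == (0, len(read))

    def test_reverse_orientation_wins_for_minus_strand_read(self, template):
        minus = revcomp(template.seq)
        mcpg = {len(template.seq) - 2 - p for p in template.cpg_positions}
        read = "".join(
            "C" if (b == "C" and i in mcpg) else ("T" if b == "C" else b)
            for i, b in enumerate(minus)
        )
        aln = align_read(read, template)
        assert aln.orientation == "reverse"
        assert aln.score_fraction == 1.0

    def test_empty_read_rejected(self, template):
        with pytest.raises(ValueError):
            align_read("", template)

    def test_all_n_read_unalignable(self, template):
        aln = align_read("N" * 30, template)
        assert aln.unalignable and aln.score == 0.0

    def test_single_mismatch_drops_score_by_match_minus_mismatch(self, template):
        read = list(template.forward_ref.replace("Y", "C"))
        read[60] = "A" if read[60] != "A" else "G"
        aln = align_read("".join(read), template)
        assert aln.score == len(read) - 2  # match 1 -> mismatch −1

    def test_monotonicity_extra_mismatch_never_helps(self, template):
        base = template.forward_ref.replace("Y", "C")
        prev = align_read(base, template).score
        read = list(base)
        rng = np.random.default_rng(0)
        for pos in rng.choice(len(read), size=5, replace=False):
            read[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[pos]]
            score = align_read("".join(read), template).score
            assert score <= prev
            prev = score

    def test_pair_indices_strictly_increasing(self, template):
        reads, _ = gen_bisulfite_reads(
            template, [0.5] * 3, n_reads=10, sub_rate=0.05, indel_rate=0.05,
            seed=9)
        for rid, seq in reads:
            aln = align_read(seq, template, read_id=rid)
            ri = [i for i, _ in aln.pairs if i is not None]
            tj = [j for _, j in aln.pairs if j is not None]
            assert ri == sorted(set(ri)) and tj == sorted(set(tj))
            assert aln.score <= aln.max_attainable


class TestOracleEquivalence:
    @given(dna, dna)
    @settings(max_examples=150)
    def test_dp_equals_exhaustive_enumeration(self, read, ref):
        got = local_alignment_score(read, ref)
        expected = brute_force_local_affine(read, ref)
        assert got == pytest.approx(expected)

    @given(dna, dna)
    @settings(max_examples=60)
    def test_score_invariant_under_joint_revcomp(self, read, ref):
        a = local_alignment_score(read, ref)
        b = local_alignment_score(revcomp(read), revcomp(ref))
        assert a == pytest.approx(b)

    def test_agrees_with_biopython_pairwise_aligner(self):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            expected = aligner.score(b, a) if aligner.score(b, a) > 0 else 0.0
            assert local_alignment_score(a, b) == pytest.approx(expected)


class TestFilter:
    def test_boundary_is_inclusive(self, template):
        aln = align_read(template.forward_ref.replace("Y", "T"), template)
        aln.score = 0.80 * aln.max_attainable
        assert filter_reads([aln], 0.80) == [aln]
        assert aln.passed

    def test_perfect_read_passes(self, template):
        aln = align_read(template.forward_ref.replace("Y", "T"), template)
        assert filter_reads([aln]) == [aln]

    def test_random_reads_rarely_pass(self, template):
        rng = np.random.default_rng(3)
        alns = []
        for i in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=len(template.seq)))
            alns.append(align_read(seq, template, read_id=f"r{i}"))
        passing = filter_reads(alns, 0.80)
        assert len(passing) / len(alns) <= 0.05

    def test_pass_rate_nonincreasing_in_substitution_rate(self, template):
        rates = [0.0, 0.05, 0.15, 0.3]
        pass_rates = []
        for sub in rates:
            reads, _ = gen_bisulfite_reads(
                template, [0.5] * 3, n_reads=60, sub_rate=sub, seed=21)
            alns = [align_read(s, template, read_id=r) for r, s in reads]
            pass_rates.append(len(filter_reads(alns)) / len(alns))
        assert pass_rates == sorted(pass_rates, reverse=True)
        assert pass_rates[0] == 1.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            filter_reads([], 0.0)
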