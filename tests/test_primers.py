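"""Thermodynamics and constraint-based primer pair selection."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

from msatselect.msat import MicrosatelliteLocus, find_perfect_repeats, primary_locus
from msatselect.primers import (
    PrimerConstraints,
    design_pairs,
    gc_content,
    max_homopolymer,
    melting_temp,
)
from msatselect.seqio import revcomp


def bio_tm(oligo):
    # same conditions: 50 mM Na+, 50 nM total oligo.  For palindromic
    # duplexes Biopython takes the duplex concentration from dnac1 alone.
    selfcomp = str(Seq(oligo).reverse_complement()) == oligo
    if selfcomp:
        return mt.Tm_NN(oligo, nn_table=mt.DNA_NN3, Na=50, dnac1=50, dnac2=0,
                        saltcorr=5, selfcomp=True)
    return mt.Tm_NN(oligo, nn_table=mt.DNA_NN3, Na=50, dnac1=25, dnac2=25,
                    saltcorr=5, selfcomp=False)


class TestMeltingTemp:
    def test_agrees_with_independent_nn_reference(self, rng):
        """Within 0.5 °C of Biopython's SantaLucia NN implementation at
        the same salt/oligo concentrations (incl. palindromic oligos)."""
        oligos = ["ACGTACGTACGTACGTACGT", "ATGCATGCATGCATGCAT"]  # palindromes
        for _ in range(40):
            n = int(rng.integers(15, 31))
            oligos.append("".join(rng.choice(list("ACGT"), n)))
        for o in oligos:
            assert melting_temp(o) == pytest.approx(bio_tm(o), abs=0.5)

    def test_gc_raises_tm(self):
        assert melting_temp("ATATATATATATATATATAT") < melting_temp(
            "GCGCGCGCGCGCGCGCGCGC"
        )

    def test_deterministic(self):
        o = "ACCTGGTTAACCGGATCAGT"
        assert melting_temp(o) == melting_temp(o)

    def test_strand_symmetry(self, rng):
        """Duplex Tm of an oligo equals that of its reverse complement,
        so right primers can be evaluated on the forward strand."""
        for _ in range(10):
            o = "".join(rng.choice(list("ACGT"), 22))
            assert melting_temp(o) == pytest.approx(melting_temp(revcomp(o)), abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTACGT")  # too short
        with pytest.raises(ValueError):
            melting_temp("ACGTACGTNACGTACGT")  # N


def test_gc_content_examples():
    assert gc_content("ATGC") == 50.0
    assert gc_content("AAAA") == 0.0
    assert gc_content("GGCC") == 100.0
    with pytest.raises(ValueError):
        gc_content("")


def test_max_homopolymer():
    assert max_homopolymer("ACGT") == 1
    assert max_homopolymer("AAAGGGGGT") == 5


def mk_locus(template, start, end, motif="AC"):
    units = (end - start) // len(motif)
    return MicrosatelliteLocus("t", motif, units, start, end,
                               start, len(template) - end)


def balanced_flank(rng, n):
    """Random flank with ~50% GC and no homopolymer runs over 4."""
    while True:
        s = "".join(rng.choice(list("ACGT"), n))
        if max_homopolymer(s) <= 4 and 40 <= gc_content(s) <= 60:
            return s


class TestDesignPairs:
    def test_every_emitted_pair_satisfies_every_constraint(self, rng):
        c = PrimerConstraints()
        checked = 0
        for i in range(30):
            template = balanced_flank(rng, 150) + "AC" * 8 + balanced_flank(rng, 150)
            locus = primary_locus(find_perfect_repeats(template))
            for pair in design_pairs(template, locus, c):
                checked += 1
                for oligo in (pair.left, pair.right):
                    assert c.primer_len[0] <= oligo.length <= c.primer_len[2]
                    assert c.tm_celsius[0] <= oligo.tm <= c.tm_celsius[2]
                    assert c.gc_percent[0] <= oligo.gc <= c.gc_percent[2]
                    assert max_homopolymer(oligo.seq) <= c.max_polyx
                    assert "N" not in oligo.seq
                assert abs(pair.left.tm - pair.right.tm) <= c.max_tm_diff
                assert c.product_len[0] <= pair.product_len <= c.product_len[1]
                # product covers the full repeat array
                assert pair.left.start + pair.left.length <= locus.start
                assert pair.right.start >= locus.end
                # primer sequences come from the right strands
                assert template[pair.left.start:
                                pair.left.start + pair.left.length] == pair.left.seq
                bind = template[pair.right.start:
                                pair.right.start + pair.right.length]
                assert revcomp(bind) == pair.right.seq
        assert checked > 20

    def test_engineered_perfect_site_ranks_first(self, rng):
        """A template built around near-ideal 20-mers (Tm within 0.3 of
        the 60 °C optimum) flanking the repeat must return a best pair at
        least as good as the engineered one, with penalty close to 0."""

        def ideal_20mer():
            # Tm 60 at these conditions needs GC-rich 20-mers
            while True:
                o = "".join(rng.choice(list("ACGT"), 20, p=[0.15, 0.35, 0.35, 0.15]))
                if max_homopolymer(o) > 4:
                    continue
                if abs(melting_temp(o) - 60.0) <= 0.3:
                    return o

        for _ in range(3):
            left, right = ideal_20mer(), ideal_20mer()
            # product: left(20) + 40 + repeat(16) + 34 + right(20) = 130
            template = ("ACGT" + left + balanced_flank(rng, 40) + "AC" * 8
                        + balanced_flank(rng, 34) + revcomp(right) + "ACGT")
            locus = primary_locus(find_perfect_repeats(template))
            pairs = design_pairs(template, locus)
            assert pairs, "engineered template must be designable"
            engineered_pen = (
                abs(melting_temp(left) - 60.0) + 0.01 * abs(gc_content(left) - 50.0)
                + abs(melting_temp(right) - 60.0) + 0.01 * abs(gc_content(right) - 50.0)
            )
            assert pairs[0].penalty <= engineered_pen + 1e-9
            assert pairs[0].penalty < 1.5

    def test_short_flank_geometrically_impossible(self):
        template = "ACGTACGTAC" + "AC" * 8 + "T" * 150  # left flank 10 bp
        locus = mk_locus(template, 10, 26)
        assert design_pairs(template, locus) == []

    def test_polyx_wall_blocks_design(self, rng):
        # every possible left primer crosses a 5-base run
        left = ("GGGGG" + "ACT" * 5) * 10
        template = left[:150] + "AC" * 8 + balanced_flank(rng, 150)
        locus = primary_locus(find_perfect_repeats(template))
        pairs = design_pairs(template, locus)
        for pair in pairs:
            assert max_homopolymer(pair.left.seq) <= 4

    def test_n_in_flank_excluded_from_primers(self, rng):
        flank = balanced_flank(rng, 150)
        template = flank[:70] + "N" + flank[71:150] + "AC" * 8 + balanced_flank(rng, 150)
        locus = primary_locus(find_perfect_repeats(template))
        for pair in design_pairs(template, locus):
            assert "N" not in pair.left.seq and "N" not in pair.right.seq

    def test_ranking_is_deterministic_and_ascending(self, rng):
        template = balanced_flank(rng, 160) + "AAG" * 7 + balanced_flank(rng, 160)
        locus = primary_locus(find_perfect_repeats(template))
        a = design_pairs(template, locus, top_k=3)
        b = design_pairs(template, locus, top_k=3)
        assert [(p.left.start, p.right.start, p.penalty) for p in a] == [
            (p.left.start, p.right.start, p.penalty) for p in b
        ]
        pens = [p.penalty for p in a]
        assert pens == sorted(pens)

    def test_designability_agrees_with_naive_oracle(self, rng):
        """Spot check against the independent enumerator built on
        Biopython's Tm (full 50-template check in the acceptance suite)."""
        from .oracles import naive_designable

        agree = total = 0
        for i in range(12):
            template = balanced_flank(rng, 110) + "AC" * 8 + balanced_flank(rng, 110)
            locus = primary_locus(find_perfect_repeats(template))
            mine = bool(design_pairs(template, locus))
            ref = naive_designable(template, locus.start, locus.end)
            total += 1
            agree += mine == ref
        assert agree / total >= 0.8


def test_constraint_validation():
    with pytest.raises(ValueError):
        PrimerConstraints(primer_len=(27, 20, 18))
    with pytest.raises(ValueError):
        PrimerConstraints(product_len=(300, 90))
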