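"""Generator determinism, planted truth, and error calibration."""

import numpy as np
import pytest

from msatselect.msat import canonical_motif, find_perfect_repeats
from msatselect.seqio import revcomp
from msatselect.simulate import (
    SimConfig,
    calibration_report,
    simulate,
    simulate_library,
)


def test_fixed_seed_gives_byte_identical_output(tmp_path):
    cfg = SimConfig(n_templates=40, seed=7)
    f1, _, r1 = simulate_library(cfg, tmp_path / "a")
    f2, _, r2 = simulate_library(SimConfig(n_templates=40, seed=7), tmp_path / "b")
    assert f1.read_bytes() == f2.read_bytes()
    assert r1.read_bytes() == r2.read_bytes()
    f3, _, _ = simulate_library(SimConfig(n_templates=40, seed=8), tmp_path / "c")
    assert f1.read_bytes() != f3.read_bytes()


def test_reads_equal_templates_except_at_recorded_errors():
    """At flat Q40 (error probability 1e-4) reads reproduce their
    template verbatim after the MID, apart from exactly the substitution
    positions the truth table records."""
    cfg = SimConfig(n_templates=40, seed=3, q_start=40, q_end=40, q_jitter_sd=0.0,
                    homopolymer_indel_rate=0.0, mid_error=False)
    reads, truth, _ = simulate(cfg)
    mids = dict(cfg.mids)
    total_subs = 0
    for r in reads:
        rt = truth.reads[r.id]
        t = truth.templates[rt.template_id]
        off = len(mids[rt.sample])
        expect = mids[rt.sample] + (
            t.sequence if rt.strand == "+" else revcomp(t.sequence)
        )
        diffs = tuple(i for i, (a, b) in enumerate(zip(r.bases, expect)) if a != b)
        assert diffs == rt.sub_positions
        assert rt.indels == ()
        total_subs += len(diffs)
    total_bases = sum(len(r) for r in reads)
    assert total_subs <= max(10, 5 * 1e-4 * total_bases)  # ~Q40 rate


def test_planted_fraction_matches_truth_exactly_when_error_free():
    cfg = SimConfig(n_templates=400, seed=11, q_start=40, q_end=40,
                    q_jitter_sd=0.0, homopolymer_indel_rate=0.0, mid_error=False,
                    re_fraction=0.0, singleton_fraction=1.0)
    reads, truth, _ = simulate(cfg)
    planted = sum(1 for t in truth.templates.values() if t.msat)
    mined = 0
    for r in reads:
        mid = dict(cfg.mids)[truth.reads[r.id].sample]
        if find_perfect_repeats(r.bases[len(mid):]):
            mined += 1
    assert mined == planted


def test_planted_repeats_are_perfect_and_in_zone():
    cfg = SimConfig(n_templates=150, seed=19)
    _, truth, _ = simulate(cfg)
    n_msat = 0
    for t in truth.templates.values():
        if not t.msat:
            continue
        n_msat += 1
        motif, units, s, e = t.msat
        assert t.sequence[s:e] == motif * units
        assert units >= cfg.unit_count_range[0]
        found = find_perfect_repeats(t.sequence)
        assert any(
            (l.start, l.end, l.motif) == (s, e, canonical_motif(motif)) for l in found
        )
        lo, hi = cfg.feature_zone
        L = len(t.sequence)
        assert s >= max(cfg.min_flank, int(lo * L)) - 1
        assert e <= int(hi * L)
    assert n_msat > 20


def test_decoys_are_subthreshold():
    cfg = SimConfig(n_templates=300, seed=23, msat_fraction=0.0, decoy_fraction=1.0)
    _, truth, _ = simulate(cfg)
    n_decoy = 0
    for t in truth.templates.values():
        if not t.decoy:
            continue
        n_decoy += 1
        motif, units, s, e = t.decoy
        assert units == 4
        assert find_perfect_repeats(t.sequence, min_units=5) == []
    assert n_decoy > 200


def test_enriched_mode_oversamples_msat_templates():
    shot = SimConfig(n_templates=500, seed=31)
    enr = SimConfig(n_templates=500, seed=31, mode="enriched")
    _, ts, _ = simulate(shot)
    _, te, _ = simulate(enr)
    f_shot = np.mean([bool(t.msat) for t in ts.templates.values()])
    f_enr = np.mean([bool(t.msat) for t in te.templates.values()])
    assert f_enr > f_shot + 0.15


def test_re_copies_carry_requested_divergence():
    cfg = SimConfig(n_templates=100, seed=37, msat_fraction=0.0, decoy_fraction=0.0,
                    re_fraction=1.0, re_divergence_range=(20.0, 20.0),
                    singleton_fraction=1.0)
    _, truth, relib = simulate(cfg)
    lib = dict((n.split("\t")[0], s) for n, s in relib)
    divs = []
    for t in truth.templates.values():
        if not t.re:
            continue
        name, div, s, e = t.re
        copy = t.sequence[s:e]
        # measure actual mismatch fraction against the best-matching
        # library window (substitution-only divergence -> same length)
        element = lib[name]
        best = min(
            sum(a != b for a, b in zip(copy, element[o : o + len(copy)]))
            for o in range(0, len(element) - len(copy) + 1)
        )
        divs.append(best / len(copy))
    assert divs
    # single-pass substitution to a different base realizes the rate directly
    assert abs(float(np.mean(divs)) - 0.20) < 0.03


def test_homolog_pairs_share_a_segment():
    cfg = SimConfig(n_templates=100, seed=41, homolog_fraction=0.5,
                    re_fraction=0.0, q_start=30, q_end=30)
    _, truth, _ = simulate(cfg)
    pairs = [(t.template_id, t.homolog_partner)
             for t in truth.templates.values() if t.homolog_partner]
    assert len(pairs) >= 10
    for tid, pid in pairs[:5]:
        assert truth.templates[pid].homolog_partner == tid


def test_calibration_near_error_free_run():
    cfg = SimConfig(n_templates=30, seed=5, q_start=40, q_end=40, q_jitter_sd=0.0,
                    homopolymer_indel_rate=0.0, mid_error=False)
    reads, truth, _ = simulate(cfg)
    total_bases = sum(len(r) for r in reads)
    total_errs = sum(len(truth.reads[r.id].sub_positions) for r in reads)
    assert total_errs / total_bases <= 1e-3  # Q40 => 1e-4 expected


def test_calibration_flat_q20():
    """Stated Q20 must produce ~1% empirical substitutions."""
    cfg = SimConfig(n_templates=300, seed=13, q_start=20, q_end=20, q_jitter_sd=0.0,
                    homopolymer_indel_rate=0.0, singleton_fraction=1.0)
    reads, truth, _ = simulate(cfg)
    rep = calibration_report(reads, truth)
    total_bases = sum(len(r) for r in reads)
    total_errs = sum(len(truth.reads[r.id].sub_positions) for r in reads)
    rate = total_errs / total_bases
    sd = np.sqrt(0.01 * 0.99 / total_bases)
    assert abs(rate - 0.01) < 5 * sd
    assert rep["pvalue"] > 1e-4  # chi-square consistent with calibration


def test_calibration_decaying_curve_monotone():
    cfg = SimConfig(n_templates=400, seed=17, homopolymer_indel_rate=0.0,
                    singleton_fraction=1.0)
    reads, truth, _ = simulate(cfg)
    rep = calibration_report(reads, truth)
    emp = np.array(rep["empirical_rate"][:300])
    # smooth in 50-position bins: error rate must rise along the read
    bins = emp[: 6 * 50].reshape(6, 50).mean(axis=1)
    assert all(np.diff(bins) > -0.002)
    assert bins[-1] > bins[0]


def test_calibration_requires_matching_truth():
    cfg = SimConfig(n_templates=5, seed=1)
    reads, truth, _ = simulate(cfg)
    truth.reads.pop(reads[0].id)
    with pytest.raises(ValueError):
        calibration_report(reads, truth)


def test_contradictory_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(unit_count_range=(1, 4))
    with pytest.raises(ValueError):
        SimConfig(msat_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(mode="nanopore")
    with pytest.raises(ValueError):
        SimConfig(feature_zone=(0.8, 0.2))


def test_homopolymer_indels_recorded():
    cfg = SimConfig(n_templates=200, seed=29, homopolymer_indel_rate=0.2,
                    q_start=40, q_end=40, q_jitter_sd=0.0, mid_error=False)
    reads, truth, _ = simulate(cfg)
    n_events = sum(len(truth.reads[r.id].indels) for r in reads)
    assert n_events > 50
    for r in reads[:50]:
        rt = truth.reads[r.id]
        t = truth.templates[rt.template_id]
        expected_len = len(dict(cfg.mids)[rt.sample]) + len(t.sequence)
        delta = sum(d for _, d in rt.indels)
        assert len(r) == expected_len + delta
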