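"""Redundancy resolution over microsatellite-flanking regions.

All-against-all local alignment groups near-identical reads (>95%
identity) into contigs, flags partial homologs (80-95% identity —
likely members of multicopy families, risky as markers) for
elimination, and leaves the rest as singletons.  Identity is computed
along the repeat *flanks* only: microsatellite spans are lowercase-
masked and excluded from the identity and length of a hit, since any
two reads sharing a motif would otherwise look similar.

Contigs are single-linkage components of the >95% hits; each gets a
majority-rule consensus in which a base is accepted only when at least
66% of members agree at that column, 'N' otherwise.

Alignment scoring (match +1, mismatch -2, gap open -5, gap extend -2)
is exact dynamic programming via Bio.Align.PairwiseAligner — no
heuristic seeding — which is feasible at the scale left after quality
control and repeat mining.  An optional exact-16-mer prefilter (off by
default) skips pairs that share no flank 16-mer in either orientation.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import Align

from .seqio import revcomp, write_fasta, read_fasta


@dataclass(frozen=True)
class PairwiseHit:
    query_id: str
    subject_id: str
    identity: float  # percent over unmasked alignment columns
    length: int  # unmasked alignment columns
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    score: float
    orientation: str = "forward"  # or "reverse"

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


@dataclass(frozen=True)
class SequenceClass:
    read_id: str
    verdict: str  # contig_member | eliminated | singleton
    contig_id: str = ""


@dataclass
class Contig:
    contig_id: str
    member_ids: list[str]
    consensus: str
    depth_per_column: list[int]


def make_aligner(
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    mode: str = "local",
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _mask_array(seq: str) -> list[bool]:
    return [c.islower() for c in seq]


def alignment_stats(alignment, qmask, smask):
    """(matches, unmasked_cols, total_cols, q_span, s_span) of an alignment.

    A column is excluded when any residue it contains is masked; a gap
    column counts toward the residue-bearing side's mask only.
    """
    tblocks, qblocks = alignment.aligned
    tseq = str(alignment.target)
    sseq = str(alignment.query)
    matches = 0
    cols = 0
    total = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            for p in range(prev_t, ts):  # gap in subject
                total += 1
                if not qmask[p]:
                    cols += 1
            for p in range(prev_q, qs):  # gap in query
                total += 1
                if not smask[p]:
                    cols += 1
        for o in range(te - ts):
            total += 1
            if not (qmask[ts + o] or smask[qs + o]):
                cols += 1
                if tseq[ts + o] == sseq[qs + o]:
                    matches += 1
        prev_t, prev_q = te, qe
    q_span = (int(tblocks[0][0]), int(tblocks[-1][1]))
    s_span = (int(qblocks[0][0]), int(qblocks[-1][1]))
    return matches, cols, total, q_span, s_span


def _pair_hit(aligner, ida, sa, maska, idb, sb, maskb, min_identity, min_aln_len, min_score):
    """Best-orientation hit between two sequences, or None."""
    ua, ub = sa.upper(), sb.upper()
    rb = revcomp(ub)
    score_f = aligner.score(ua, ub)
    score_r = aligner.score(ua, rb)
    best_score = max(score_f, score_r)
    if best_score < min_score:
        return None
    if score_r > score_f:
        aln = aligner.align(ua, rb)[0]
        stats = alignment_stats(aln, maska, maskb[::-1])
        matches, cols, _, q_span, s_span_rc = stats
        n = len(sb)
        s_span = (n - s_span_rc[1], n - s_span_rc[0])
        orientation = "reverse"
        score = score_r
    else:
        aln = aligner.align(ua, ub)[0]
        matches, cols, _, q_span, s_span = alignment_stats(aln, maska, maskb)
        orientation = "forward"
        score = score_f
    if cols < min_aln_len:
        return None
    identity = 100.0 * matches / cols
    if identity < min_identity:
        return None
    return PairwiseHit(ida, idb, identity, cols, q_span, s_span, float(score), orientation)


def _unmasked_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if w.isupper() and "N" not in w:
            out.add(w)
            out.add(revcomp(w))
    return out


def all_vs_all(
    seqs: dict[str, str],
    min_identity_report: float = 80.0,
    min_aln_len: int = 20,
    kmer_prefilter: bool = False,
    prefilter_k: int = 16,
    min_score: float | None = None,
    scoring: tuple[float, float, float, float] = (1.0, -2.0, -5.0, -2.0),
) -> list[PairwiseHit]:
    """Best local alignment for every ordered pair of sequences.

    Masked (lowercase) spans are excluded from identity and hit length.
    Both orientations are tried; the higher-scoring one is reported.
    Hits are emitted symmetrically: hit(a, b) iff hit(b, a).  Self-hits
    are recorded (trivially, identity 100 over the unmasked length) but
    downstream classification ignores them.

    ``min_score`` skips the full traceback for pairs whose best local
    score cannot belong to a qualifying hit; the default 0.4 *
    ``min_aln_len`` assumes substitution-dominated divergence (a gapless
    hit at 80% identity scores 0.4 per column).
    """
    if min_aln_len < 20:
        raise ValueError("min_aln_len must be >= 20 (noise floor)")
    if not seqs:
        raise ValueError("all_vs_all needs at least one sequence")
    if min_score is None:
        min_score = 0.4 * min_aln_len
    aligner = make_aligner(*scoring)
    ids = sorted(seqs)
    masks = {i: _mask_array(seqs[i]) for i in ids}
    hits: list[PairwiseHit] = []
    for i in ids:  # self-hits
        cols = sum(not m for m in masks[i])
        hits.append(PairwiseHit(i, i, 100.0, cols, (0, len(seqs[i])), (0, len(seqs[i])), float(cols)))
    kmer_sets = (
        {i: _unmasked_kmers(seqs[i], prefilter_k) for i in ids} if kmer_prefilter else None
    )
    for a_idx, ida in enumerate(ids):
        for idb in ids[a_idx + 1 :]:
            if kmer_sets is not None and kmer_sets[ida].isdisjoint(kmer_sets[idb]):
                continue
            hit = _pair_hit(
                aligner,
                ida,
                seqs[ida],
                masks[ida],
                idb,
                seqs[idb],
                masks[idb],
                min_identity_report,
                min_aln_len,
                min_score,
            )
            if hit is not None:
                hits.append(hit)
                hits.append(
                    PairwiseHit(
                        idb,
                        ida,
                        hit.identity,
                        hit.length,
                        hit.subject_span,
                        hit.query_span,
                        hit.score,
                        hit.orientation,
                    )
                )
    return hits


@dataclass
class ClassifyResult:
    contigs: dict[str, list[str]]  # contig_id -> sorted member ids
    eliminated: list[str]
    singletons: list[str]
    records: list[SequenceClass]


def classify(
    seqs: dict[str, str],
    hits: list[PairwiseHit],
    contig_min_identity: float = 95.0,
    eliminate_band: tuple[float, float] = (80.0, 95.0),
) -> ClassifyResult:
    """Sort sequences into contig members, eliminated, and singletons.

    Single-linkage components over strictly-greater-than-95% hits become
    contigs (size >= 2).  Contig membership is decided first; sequences
    outside every contig that have any non-self hit with identity in the
    closed band [80, 95] are eliminated (boundary 95.0 eliminates).
    Sequences with only self-hits are singletons.  The three classes
    partition the input exactly.
    """
    ids = sorted(seqs)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    band_hit: set[str] = set()
    for h in hits:
        if h.is_self:
            continue
        if h.identity > contig_min_identity:
            union(h.query_id, h.subject_id)
        elif eliminate_band[0] <= h.identity <= eliminate_band[1]:
            band_hit.add(h.query_id)
            band_hit.add(h.subject_id)
    components: dict[str, list[str]] = {}
    for i in ids:
        components.setdefault(find(i), []).append(i)
    contigs: dict[str, list[str]] = {}
    in_contig: set[str] = set()
    for n, root in enumerate(sorted(r for r, mem in components.items() if len(mem) >= 2)):
        cid = f"contig_{n + 1:05d}"
        contigs[cid] = sorted(components[root])
        in_contig.update(components[root])
    eliminated = [i for i in ids if i not in in_contig and i in band_hit]
    singletons = [i for i in ids if i not in in_contig and i not in band_hit]
    records = []
    member_to_contig = {m: cid for cid, mem in contigs.items() for m in mem}
    for i in ids:
        if i in member_to_contig:
            records.append(SequenceClass(i, "contig_member", member_to_contig[i]))
        elif i in band_hit:
            records.append(SequenceClass(i, "eliminated"))
        else:
            records.append(SequenceClass(i, "singleton"))
    return ClassifyResult(contigs, sorted(eliminated), sorted(singletons), records)


def majority_consensus(
    aligned: list[str], threshold: float = 0.66
) -> tuple[str, list[int]]:
    """Majority-rule consensus of pre-aligned, equal-length sequences.

    Per column: if the modal symbol (gap included) reaches the threshold
    fraction of members, it is accepted — a modal gap drops the column,
    a modal base is emitted; otherwise the column becomes 'N'.  Returns
    the consensus and the per-emitted-column depth (non-gap members).
    """
    if not aligned:
        raise ValueError("empty alignment")
    n = len(aligned)
    length = len(aligned[0])
    if any(len(s) != length for s in aligned):
        raise ValueError("alignment rows differ in length")
    out = []
    depths = []
    for col in range(length):
        symbols = [s[col].upper() for s in aligned]
        counts = Counter(symbols)
        # unique modal symbol whenever threshold >= 0.5 is met; tie-break
        # (sub-threshold) is deterministic but lands on 'N' anyway
        modal, count = max(counts.items(), key=lambda kv: (kv[1], kv[0] != "-", kv[0]))
        depth = n - counts.get("-", 0)
        if count / n >= threshold:
            if modal == "-":
                continue
            out.append(modal)
        else:
            out.append("N")
        depths.append(depth)
    return "".join(out), depths


def _mafft_align(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Multiple-align records with mafft (deterministic given input order)."""
    mafft = shutil.which("mafft")
    if mafft is None:
        raise RuntimeError("mafft not found on PATH; required for consensus building")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "members.fasta"
        write_fasta(records, infile)
        proc = subprocess.run(
            [mafft, "--quiet", "--retree", "2", "--inputorder", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
        outfile = Path(tmp) / "aligned.fasta"
        outfile.write_text(proc.stdout)
        return [(rid, seq.upper()) for rid, seq in read_fasta(outfile)]


def build_consensus(
    member_seqs: dict[str, str],
    contig_id: str = "contig",
    threshold: float = 0.66,
) -> Contig:
    """Orient, multiple-align and collapse contig members to a consensus.

    The longest member anchors the orientation; any member aligning
    better as its reverse complement is flipped first.  Members are then
    multiple-aligned (mafft) in sorted-id order and collapsed with the
    66% majority rule.
    """
    if len(member_seqs) < 2:
        raise ValueError("a contig needs at least 2 members")
    ids = sorted(member_seqs)
    ref_id = sorted(ids, key=lambda i: (-len(member_seqs[i]), i))[0]
    ref = member_seqs[ref_id].upper()
    aligner = make_aligner()
    oriented: list[tuple[str, str]] = []
    for i in ids:
        s = member_seqs[i].upper()
        if i == ref_id:
            oriented.append((i, s))
            continue
        if aligner.score(ref, revcomp(s)) > aligner.score(ref, s):
            s = revcomp(s)
        oriented.append((i, s))
    aligned = _mafft_align(oriented)
    consensus, depths = majority_consensus([seq for _, seq in aligned], threshold)
    if not consensus:
        raise ValueError(f"contig {contig_id}: members do not overlap")
    return Contig(contig_id, ids, consensus, depths)
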