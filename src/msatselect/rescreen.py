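"""Repetitive-element screening.

Candidate marker sequences (contig consensuses and singletons alike)
are compared by local alignment against a library of known repetitive
elements (transposons, pseudogenes, integrated viruses — e.g. a Repbase
export in FASTA form).  A sequence showing more than 65% identity to
any element over at least ``min_hit_len`` alignment columns is flagged
and excluded from marker design: microsatellites embedded in multicopy
DNA amplify many loci at once.

Unlike the redundancy stage, masked (lowercase) microsatellite spans DO
take part in the comparison here — repetitive elements routinely
contain repeats of their own.

The screen uses a milder scoring matrix (match +2, mismatch -3, gap
open -8, gap extend -3) than the redundancy stage: homology detection
at the 65% level needs alignments that extend across the whole
divergent region, whereas the redundancy stage's +1/-2 scheme (tuned
for near-identical reads) trims such alignments to short
high-identity cores and makes the 65% threshold meaningless.  With a
break-even identity of 60% (=3/5), alignments dissolve below the
threshold and span the element copy above it, so measured identity
tracks true homology.
"""

from __future__ import annotations

from dataclasses import dataclass

from .redundancy import alignment_stats, make_aligner
from .seqio import read_fasta, revcomp


@dataclass(frozen=True)
class REElement:
    name: str
    bases: str
    family: str = ""


@dataclass
class RELibrary:
    elements: list[REElement]

    def __post_init__(self):
        if not self.elements:
            raise ValueError(
                "RE screening requires a non-empty library; "
                "pass --re-lib none to skip the screen explicitly"
            )
        names = [e.name for e in self.elements]
        if len(set(names)) != len(names):
            raise ValueError("duplicate element names in RE library")
        if any(not e.bases for e in self.elements):
            raise ValueError("empty element sequence in RE library")

    @classmethod
    def from_fasta(cls, path) -> "RELibrary":
        """Load a FASTA library; Repbase-style tab- (or whitespace-)
        separated headers give the element name in field 1 and the
        family in field 2."""
        from Bio import SeqIO

        elements = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = rec.description.split("\t")
            if len(fields) == 1:
                fields = rec.description.split()
            name = fields[0]
            family = fields[1] if len(fields) > 1 else ""
            elements.append(REElement(name, str(rec.seq).upper(), family))
        return cls(elements)


@dataclass(frozen=True)
class REHit:
    query_id: str
    element_name: str
    identity: float
    length: int  # alignment columns
    query_span: tuple[int, int]
    element_span: tuple[int, int]
    score: float
    orientation: str


@dataclass
class ScreenResult:
    clean: dict[str, str]
    flagged: dict[str, REHit]


def screen(
    seqs: dict[str, str],
    library: RELibrary,
    min_identity: float = 65.0,
    min_hit_len: int = 90,
    min_score: float = 10.0,
    scoring: tuple[float, float, float, float] = (2.0, -3.0, -8.0, -3.0),
) -> ScreenResult:
    """Partition sequences into RE-clean and RE-flagged.

    A sequence is flagged iff some local alignment against a library
    element (either orientation) has identity strictly above
    ``min_identity`` AND spans at least ``min_hit_len`` columns; the
    highest-scoring qualifying hit is reported.  ``clean`` and
    ``flagged`` partition the input exactly.
    """
    aligner = make_aligner(*scoring)
    clean: dict[str, str] = {}
    flagged: dict[str, REHit] = {}
    no_mask_cache: dict[int, list[bool]] = {}

    def nomask(n: int) -> list[bool]:
        if n not in no_mask_cache:
            no_mask_cache[n] = [False] * n
        return no_mask_cache[n]

    for qid in sorted(seqs):
        q = seqs[qid].upper()
        best: REHit | None = None
        for element in library.elements:
            e = element.bases.upper()
            for orientation, target in (("forward", e), ("reverse", revcomp(e))):
                if aligner.score(q, target) < min_score:
                    continue
                aln = aligner.align(q, target)[0]
                matches, cols, _, q_span, e_span = alignment_stats(
                    aln, nomask(len(q)), nomask(len(e))
                )
                if cols < min_hit_len or cols == 0:
                    continue
                identity = 100.0 * matches / cols
                if identity <= min_identity:
                    continue
                if orientation == "reverse":
                    e_span = (len(e) - e_span[1], len(e) - e_span[0])
                hit = REHit(
                    qid, element.name, identity, cols, q_span, e_span,
                    float(aln.score), orientation,
                )
                if best is None or hit.score > best.score:
                    best = hit
        if best is None:
            clean[qid] = seqs[qid]
        else:
            flagged[qid] = best
    return ScreenResult(clean, flagged)
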