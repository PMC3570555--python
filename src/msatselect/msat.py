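"""Perfect microsatellite (SSR) detection.

Finds every maximal perfect tandem array of a di- to hexanucleotide
motif with at least ``min_units`` repetitions.  Motifs are reported in a
canonical form: the lexicographically smallest string among all
rotations of the motif and of its reverse complement, so e.g. TG, GT,
CA and AC arrays all report motif "AC".  Only *primitive* motifs
qualify ("ACAC" is a doubled "AC", not a tetranucleotide motif), which
also excludes homopolymer runs.  Interrupted or compound repeats are
never merged: adjacent arrays separated by at least one non-repeat base
are distinct loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Read, revcomp


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A perfect tandem repeat inside a host sequence.

    ``start``/``end`` are 0-based half-open coordinates in the host
    sequence (for reads: in the clipped/trimmed sequence).
    """

    host_id: str
    motif: str
    unit_count: int
    start: int
    end: int
    left_flank_len: int
    right_flank_len: int

    def __post_init__(self):
        if not (2 <= len(self.motif) <= 6):
            raise ValueError("motif length outside 2..6")
        if self.unit_count < 1:
            raise ValueError("unit_count must be positive")
        if self.end - self.start != self.unit_count * len(self.motif):
            raise ValueError("span length != unit_count * motif length")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def is_primitive(motif: str) -> bool:
    """True if the motif is not itself a tandem repeat of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Smallest rotation among the motif and its reverse complement."""
    rc = revcomp(motif.upper())
    m = motif.upper()
    candidates = [m[i:] + m[:i] for i in range(len(m))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def find_perfect_repeats(
    bases: str,
    min_units: int = 5,
    motif_lens=range(2, 7),
    host_id: str = "",
) -> list[MicrosatelliteLocus]:
    """Every maximal perfect tandem array in ``bases``.

    N (or any non-ACGT symbol) never participates in a repeat.
    Overlapping arrays with different motifs are all reported; each
    array is reported once, anchored at its leftmost start, with its
    span truncated to whole motif units.
    """
    b = bases.upper()
    n = len(b)
    loci: list[MicrosatelliteLocus] = []
    if n == 0:
        return loci
    arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    is_acgt = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    for k in sorted(set(motif_lens)):
        if k < 2 or k > 6 or n < 2 * k:
            continue
        eq = (arr[:-k] == arr[k:]) & is_acgt[:-k]
        # maximal runs of True in eq; a run [rs, re) means b[rs : re + k]
        # has period k
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)
        for rs, re_ in zip(run_starts, run_ends):
            total = (re_ - rs) + k  # period-k length of the array
            units = total // k
            if units < min_units:
                continue
            motif = b[rs : rs + k]
            if not is_primitive(motif):
                continue
            loci.append(
                MicrosatelliteLocus(
                    host_id=host_id,
                    motif=canonical_motif(motif),
                    unit_count=int(units),
                    start=int(rs),
                    end=int(rs + units * k),
                    left_flank_len=int(rs),
                    right_flank_len=int(n - (rs + units * k)),
                )
            )
    loci.sort(key=lambda l: (l.start, len(l.motif), l.motif))
    return loci


def primary_locus(loci: list[MicrosatelliteLocus]) -> MicrosatelliteLocus:
    """The primer-target locus of a multi-locus host: most units wins.

    More repeat units means more potential length polymorphism; ties go
    to the leftmost array.
    """
    if not loci:
        raise ValueError("no loci")
    return min(loci, key=lambda l: (-l.unit_count, l.start))


def classify_reads(
    reads, min_units: int = 5
) -> tuple[list[tuple[Read, list[MicrosatelliteLocus]]], list[Read]]:
    """Partition reads into microsatellite-bearing and repeat-free.

    Mining runs on the clipped region only; locus coordinates are
    relative to the clipped sequence.  A repeat lying outside the clip
    does not count.
    """
    with_msat: list[tuple[Read, list[MicrosatelliteLocus]]] = []
    without: list[Read] = []
    for read in reads:
        loci = find_perfect_repeats(
            read.clipped_bases, min_units=min_units, host_id=read.id
        )
        if loci:
            with_msat.append((read, loci))
        else:
            without.append(read)
    return with_msat, without


def mask_repeats(bases: str, loci: list[MicrosatelliteLocus]) -> str:
    """Lowercase-mask repeat spans so alignment identity can skip them."""
    chars = list(bases.upper())
    for locus in loci:
        for i in range(locus.start, locus.end):
            chars[i] = chars[i].lower()
    return "".join(chars)
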