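"""Library splitting by MID barcode and adaptor/linker removal.

Pooled 454-style runs carry a short Multiplex Identifier (MID) at the
start of every read, optionally preceded by a ligated adaptor.  Reads are
assigned to the sample whose MID matches the read prefix best; the
matched prefix (adaptor + MID) is then cut away, qualities in lockstep.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import Read

_DNA = set("ACGT")


@dataclass(frozen=True)
class BarcodeEntry:
    sample: str
    mid: str
    adaptor: str = ""


@dataclass
class BarcodeTable:
    """Per-sample MID (and optional adaptor) sequences.

    MIDs must be pairwise distinct, at least 4 bp, and no MID may be a
    prefix of another (a prefix relation would make assignment ambiguous
    at mismatch 0).
    """

    entries: list[BarcodeEntry]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("barcode table is empty")
        mids = [e.mid for e in self.entries]
        for e in self.entries:
            if len(e.mid) < 4:
                raise ValueError(f"MID {e.mid!r} shorter than 4 bp")
            if set(e.mid) - _DNA or (e.adaptor and set(e.adaptor) - _DNA):
                raise ValueError(f"non-ACGT character in barcode entry for {e.sample!r}")
        if len(set(mids)) != len(mids):
            raise ValueError("MID sequences are not pairwise distinct")
        for a in mids:
            for b in mids:
                if a != b and b.startswith(a):
                    raise ValueError(f"MID {a!r} is a prefix of MID {b!r}")

    @classmethod
    def from_tsv(cls, path) -> "BarcodeTable":
        """Load ``sample<TAB>mid[<TAB>adaptor]`` lines; '#' comments allowed."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"barcode line needs sample<TAB>mid: {line!r}")
                sample, mid = parts[0], parts[1].upper()
                adaptor = parts[2].upper() if len(parts) > 2 else ""
                entries.append(BarcodeEntry(sample, mid, adaptor))
        return cls(entries)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads, table: BarcodeTable, max_mismatch: int = 0
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Split reads by MID prefix.

    A read is assigned to the unique sample whose MID matches the read
    prefix with the fewest mismatches, provided that count is at most
    ``max_mismatch``; when two samples tie at the minimum the read stays
    unassigned.  If an entry carries an adaptor and the read begins with
    it verbatim, the MID is matched after the adaptor.  Assigned reads
    have the adaptor and MID removed from bases and qualities.

    The default ``max_mismatch=0`` reproduces exact barcode splitting:
    reads whose barcode itself holds a sequencing error stay unassigned.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    assigned: dict[str, list[Read]] = {e.sample: [] for e in table.entries}
    unassigned: list[Read] = []
    for read in reads:
        candidates = []  # (mismatches, entry, cut_length)
        for entry in table.entries:
            off = 0
            if entry.adaptor and read.bases.startswith(entry.adaptor):
                off = len(entry.adaptor)
            prefix = read.bases[off : off + len(entry.mid)]
            if len(prefix) < len(entry.mid):
                continue
            mm = _mismatches(prefix, entry.mid)
            if mm <= max_mismatch:
                candidates.append((mm, entry, off + len(entry.mid)))
        if not candidates:
            unassigned.append(read)
            continue
        best = min(c[0] for c in candidates)
        winners = [c for c in candidates if c[0] == best]
        if len(winners) != 1:
            unassigned.append(read)
            continue
        _, entry, cut = winners[0]
        assigned[entry.sample].append(
            Read(read.id, read.bases[cut:], read.quals[cut:], sample=entry.sample)
        )
    return assigned, unassigned


def strip_linkers(read: Read, linkers: list[str]) -> Read:
    """Remove exact linker occurrences from the clipped region.

    A linker at either end of the clipped region is clipped off; an
    interior occurrence truncates the read at the nearer end, keeping the
    longer flank.  Applied repeatedly until no linker remains.  With no
    linkers the read is returned unchanged.
    """
    if not linkers:
        return read
    linkers = sorted({l.upper() for l in linkers}, key=lambda l: (-len(l), l))
    start, end = read.clip
    changed = True
    while changed and start < end:
        changed = False
        region = read.bases[start:end]
        hit = None  # (pos_in_region, linker)
        for linker in linkers:
            p = region.find(linker)
            if p != -1 and (hit is None or p < hit[0]):
                hit = (p, linker)
        if hit is None:
            break
        p, linker = hit
        if p == 0:
            start += len(linker)
        elif p + len(linker) == len(region):
            end -= len(linker)
        else:
            left_len = p
            right_len = len(region) - (p + len(linker))
            if right_len >= left_len:
                start += p + len(linker)
            else:
                end = start + p
        changed = True
    return Read(read.id, read.bases, read.quals, read.sample, (start, end))
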