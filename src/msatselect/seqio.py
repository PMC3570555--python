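"""FASTQ/FASTA input and output and Phred quality handling.

Single-end reads enter the pipeline as 4-line FASTQ with Phred+33
qualities.  A :class:`Read` keeps the full original sequence and quality
string for the whole of its life in the pipeline; trimming stages narrow
the ``clip`` interval instead of discarding bases, so provenance
coordinates stay stable until a stage explicitly materializes the clipped
sequence.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger("msatselect")

MAX_PHRED = 62  # Phred+33 scores above this indicate a Phred+64 file

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N self-paired)."""
    return seq.translate(_COMPLEMENT)[::-1]


def phred_to_error(q):
    """Error probability for a Phred score: ``10**(-q/10)``.

    Accepts a scalar or an array; negative scores are a hard error.
    """
    arr = np.asarray(q, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative Phred score")
    out = np.power(10.0, -arr / 10.0)
    if np.isscalar(q) or arr.ndim == 0:
        return float(out)
    return out


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities and provenance.

    ``clip`` is the half-open interval of ``bases`` currently considered
    valid; freshly parsed reads have ``clip == (0, len(bases))``.
    """

    id: str
    bases: str
    quals: tuple[int, ...]
    sample: str = "unassigned"
    clip: tuple[int, int] | None = None

    def __post_init__(self):
        self.quals = tuple(int(q) for q in self.quals)
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.quals):
            raise ValueError(f"read {self.id!r}: Phred score outside [0, {MAX_PHRED}]")
        if self.clip is None:
            self.clip = (0, len(self.bases))
        s, e = self.clip
        if not (0 <= s <= e <= len(self.bases)):
            raise ValueError(f"read {self.id!r}: clip {self.clip} out of bounds")
        self.clip = (int(s), int(e))

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def clipped_bases(self) -> str:
        s, e = self.clip
        return self.bases[s:e]

    @property
    def clipped_quals(self) -> tuple[int, ...]:
        s, e = self.clip
        return self.quals[s:e]

    def error_probs(self) -> np.ndarray:
        """Per-base error probabilities over the FULL read.

        'N' calls are explicit base-calling failures and are assigned
        probability 1.0 regardless of their stated quality.
        """
        p = phred_to_error(np.asarray(self.quals, dtype=float))
        if "N" in self.bases:
            idx = [i for i, b in enumerate(self.bases) if b not in "ACGT"]
            p[idx] = 1.0
        return p

    def materialize_clip(self) -> "Read":
        """Return a new Read whose bases/quals are the clipped region."""
        s, e = self.clip
        return Read(self.id, self.bases[s:e], self.quals[s:e], self.sample)


def read_fastq(path) -> list[Read]:
    """Parse a 4-line Phred+33 FASTQ file into a list of Reads.

    Record order is preserved.  Duplicate identifiers are made unique with
    a deterministic ``.2``, ``.3`` ... suffix and a logged warning.  A
    record whose quality string length differs from its sequence length is
    a hard error naming the record.  An empty file yields an empty list.
    """
    reads: list[Read] = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            rid = title.split()[0] if title.split() else title
            quals = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 for q in quals):
                raise ValueError(f"read {rid!r}: quality character below '!' (not Phred+33)")
            if any(q > MAX_PHRED for q in quals):
                raise ValueError(
                    f"read {rid!r}: Phred score above {MAX_PHRED}; "
                    "input looks Phred+64 encoded, which is not supported"
                )
            if rid in seen:
                seen[rid] += 1
                new_id = f"{rid}.{seen[rid]}"
                log.warning("duplicate read id %r renamed to %r", rid, new_id)
                rid = new_id
            else:
                seen[rid] = 1
            reads.append(Read(rid, seq.upper(), quals))
    return reads


def write_fastq(reads: Iterable[Read], path, clipped: bool = False) -> None:
    """Write reads as 4-line Phred+33 FASTQ (clipped region only if asked)."""
    with open(path, "w") as out:
        for r in reads:
            bases = r.clipped_bases if clipped else r.bases
            quals = r.clipped_quals if clipped else r.quals
            qstr = "".join(chr(q + 33) for q in quals)
            out.write(f"@{r.id}\n{bases}\n+\n{qstr}\n")


def write_fasta(records: Iterable[tuple[str, str]], path, wrap: int = 80) -> None:
    """Write (id, sequence) pairs as 80-column-wrapped FASTA."""
    records = list(records)
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in FASTA output")
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                out.write(seq[i : i + wrap] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, sequence) pairs, order preserved."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
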