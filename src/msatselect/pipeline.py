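"""Two-track marker-selection pipeline and summary ledger.

Track A (*low stringency → contigs*): a permissive quality trim keeps
most of each read, repeats are mined, near-identical reads are grouped,
and only the majority-rule contig consensuses go forward — depth
compensates for base-calling errors.  Track B (*high stringency →
singletons*): a strict quality trim keeps only high-accuracy regions
and only singleton reads go forward — accuracy comes from the quality
gate itself.  Both tracks then drop candidates resembling repetitive
elements and design primer pairs around the surviving loci.

Loci recovered by both tracks (cross-track identity >95%) are reported
once in the primer table, preferring the contig version (consensus
accuracy); the ledger's per-track counts and their total keep the plain
sum convention, with the deduplicated count reported separately.

Every stage writes its artifact to the output directory, and a run can
resume from any stage's artifact; fixed inputs give byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .demux import BarcodeTable, demultiplex
from .msat import classify_reads, find_perfect_repeats, mask_repeats, primary_locus
from .primers import PrimerConstraints, boulder_record, design_pairs
from .qc import preset, trim_read
from .redundancy import all_vs_all, build_consensus, classify
from .rescreen import RELibrary, screen
from .seqio import read_fastq, write_fasta, write_fastq

log = logging.getLogger("msatselect")

LEDGER_ROWS = ("Sequences", "µsats", "µsats without RE", "Primer pairs")


@dataclass
class PipelineConfig:
    min_units: int = 5
    contig_identity: float = 95.0
    eliminate_band: tuple[float, float] = (80.0, 95.0)
    consensus_threshold: float = 0.66
    cluster_min_identity: float = 80.0
    cluster_min_aln_len: int = 50
    kmer_prefilter: bool = True
    re_min_identity: float = 65.0
    re_min_hit_len: int = 90
    primers_per_locus: int = 3
    max_mismatch: int = 0
    min_len: int = 100
    dedup_cross_track: bool = True
    constraints: PrimerConstraints = field(default_factory=PrimerConstraints)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cons = data.pop("constraints", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
        if cons:
            cfg.constraints = PrimerConstraints(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in cons.items()}
            )
        return cfg


@dataclass
class TrackLedger:
    sequences_after_qc: int = 0
    n_msat: int = 0
    n_msat_without_re: int = 0
    n_primer_pairs: int = 0


@dataclass
class PipelineLedger:
    sequences_before_qc: int = 0
    msat_before_qc: int = 0
    pct_with_msat: float = 0.0
    low: TrackLedger = field(default_factory=TrackLedger)
    high: TrackLedger = field(default_factory=TrackLedger)
    total_primer_pairs: int = 0
    n_deduplicated: int = 0

    def validate(self) -> None:
        for t in (self.low, self.high):
            assert t.n_msat_without_re <= t.n_msat
            assert t.n_primer_pairs <= t.n_msat_without_re
        assert self.total_primer_pairs == self.low.n_primer_pairs + self.high.n_primer_pairs

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "PipelineLedger":
        data = json.loads(text)
        low = TrackLedger(**data.pop("low"))
        high = TrackLedger(**data.pop("high"))
        return cls(low=low, high=high, **data)


def ledger_report(ledger: PipelineLedger) -> str:
    """Fixed-width human-readable summary table."""
    lines = []
    w = 26

    def row(label, value):
        lines.append(f"  {label:<{w}}{value}")

    lines.append("Before Quality Control")
    row("Sequences", ledger.sequences_before_qc)
    row("µsats", ledger.msat_before_qc)
    row("% with µsats", f"{ledger.pct_with_msat:.1f}")
    lines.append("After Quality Control")
    for name, track in (("Low Stringency - consensus", ledger.low),
                        ("High Stringency - singletons", ledger.high)):
        lines.append(name)
        row("Sequences", track.sequences_after_qc)
        row("µsats", track.n_msat)
        row("µsats without RE", track.n_msat_without_re)
        row("Primer pairs", track.n_primer_pairs)
    lines.append(f"{'Total primer pairs':<{w + 2}}{ledger.total_primer_pairs}")
    if ledger.n_deduplicated:
        lines.append(f"{'Cross-track duplicates':<{w + 2}}{ledger.n_deduplicated}")
    return "\n".join(lines) + "\n"


@dataclass
class TrackResult:
    track: str
    ledger: TrackLedger
    candidates: dict[str, str]  # candidate id -> sequence (clean, with loci)
    loci: dict[str, object]  # candidate id -> primary MicrosatelliteLocus
    pairs: dict[str, list]  # candidate id -> ranked PrimerPair list
    flagged: dict[str, object]
    eliminated: list[str]


def _qc_stage(reads, preset_name, min_len, out_path: Path, resume: bool):
    if resume and out_path.exists():
        return read_fastq(out_path)
    params = preset(preset_name)
    if min_len != params.min_len:
        from dataclasses import replace

        params = replace(params, min_len=min_len)
    kept = []
    for r in reads:
        t = trim_read(r, params)
        if t is not None:
            kept.append(t.materialize_clip())
    write_fastq(kept, out_path)
    return kept


def _run_track(reads, track: str, config: PipelineConfig, re_library,
               out_dir: Path, resume: bool) -> TrackResult:
    preset_name = "low" if track == "low" else "high"
    clean = _qc_stage(reads, preset_name, config.min_len,
                      out_dir / f"qc_{track}.fastq", resume)
    ledger = TrackLedger(sequences_after_qc=len(clean))
    with_msat, _ = classify_reads(clean, config.min_units)
    log.info("[%s] %d reads after QC, %d with microsatellites",
             track, len(clean), len(with_msat))

    masked = {r.id: mask_repeats(r.bases, loci) for r, loci in with_msat}
    raw = {r.id: r.bases for r, _ in with_msat}
    if masked:
        hits = all_vs_all(
            masked,
            min_identity_report=config.cluster_min_identity,
            min_aln_len=config.cluster_min_aln_len,
            kmer_prefilter=config.kmer_prefilter,
        )
        result = classify(masked, hits, config.contig_identity, config.eliminate_band)
    else:
        hits = []
        result = classify({}, []) if masked else None

    candidates: dict[str, str] = {}
    eliminated: list[str] = []
    if result is not None:
        eliminated = result.eliminated
        for rid in eliminated:
            log.debug("reject %s: band_80_95", rid)
        if track == "low":
            with open(out_dir / f"contig_members_{track}.tsv", "w") as fh:
                fh.write("contig_id\tmember_ids\n")
                for cid, members in sorted(result.contigs.items()):
                    fh.write(f"{cid}\t{','.join(members)}\n")
            for cid, members in result.contigs.items():
                contig = build_consensus({m: raw[m] for m in members}, cid,
                                         config.consensus_threshold)
                candidates[cid] = contig.consensus
        else:
            for rid in result.singletons:
                candidates[rid] = raw[rid]

    # candidates must still carry a detectable repeat (a consensus can
    # lose one to 'N' columns)
    loci = {}
    for cid in sorted(candidates):
        found = find_perfect_repeats(candidates[cid], config.min_units, host_id=cid)
        if found:
            loci[cid] = primary_locus(found)
    candidates = {cid: candidates[cid] for cid in loci}
    ledger.n_msat = len(candidates)
    write_fasta(sorted(candidates.items()), out_dir / f"candidates_{track}.fasta")

    if re_library is not None and candidates:
        screened = screen(candidates, re_library,
                          config.re_min_identity, config.re_min_hit_len)
        clean_cands = screened.clean
        flagged = screened.flagged
        for rid in flagged:
            log.debug("reject %s: re_hit", rid)
    else:
        clean_cands = dict(candidates)
        flagged = {}
    ledger.n_msat_without_re = len(clean_cands)
    write_fasta(sorted(clean_cands.items()), out_dir / f"clean_{track}.fasta")

    pairs = {}
    for cid in sorted(clean_cands):
        designed = design_pairs(clean_cands[cid], loci[cid], config.constraints,
                                config.primers_per_locus)
        if designed:
            pairs[cid] = designed
        else:
            log.debug("reject %s: no_primer", cid)
    ledger.n_primer_pairs = len(pairs)
    return TrackResult(track, ledger, clean_cands, loci, pairs, flagged, eliminated)


def _write_primers(path: Path, rows: list[dict]) -> None:
    cols = ["locus_id", "track", "motif", "units", "left_seq", "right_seq",
            "left_tm", "right_tm", "product_len", "penalty"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


@dataclass
class PipelineResult:
    ledger: PipelineLedger
    primers_path: Path
    ledger_path: Path
    out_dir: Path


def run_pipeline(
    fastq,
    out_dir,
    barcodes: BarcodeTable | None = None,
    re_library: RELibrary | None = None,
    config: PipelineConfig | None = None,
    resume: bool = False,
) -> PipelineResult:
    """Run both selection tracks end to end and write all artifacts."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    reads = read_fastq(fastq)
    if barcodes is not None:
        demux_path = out_dir / "assigned.fastq"
        if resume and demux_path.exists():
            assigned_reads = read_fastq(demux_path)
        else:
            assigned, unassigned = demultiplex(reads, barcodes, config.max_mismatch)
            assigned_reads = [r for s in sorted(assigned) for r in assigned[s]]
            assigned_reads.sort(key=lambda r: r.id)
            write_fastq(assigned_reads, demux_path)
            log.info("demux: %d assigned, %d unassigned", len(assigned_reads),
                     len(unassigned))
        reads = assigned_reads

    ledger = PipelineLedger(sequences_before_qc=len(reads))
    with_msat_raw, _ = classify_reads(reads, config.min_units)
    ledger.msat_before_qc = len(with_msat_raw)
    ledger.pct_with_msat = (
        100.0 * len(with_msat_raw) / len(reads) if reads else 0.0
    )

    low = _run_track(reads, "low", config, re_library, out_dir, resume)
    high = _run_track(reads, "high", config, re_library, out_dir, resume)
    ledger.low = low.ledger
    ledger.high = high.ledger
    ledger.total_primer_pairs = low.ledger.n_primer_pairs + high.ledger.n_primer_pairs

    # cross-track deduplication of the primer table (contig wins)
    dropped: set[str] = set()
    if config.dedup_cross_track and low.pairs and high.pairs:
        combined = {}
        for cid in low.pairs:
            combined[f"L::{cid}"] = mask_repeats(
                low.candidates[cid],
                find_perfect_repeats(low.candidates[cid], config.min_units),
            )
        for cid in high.pairs:
            combined[f"H::{cid}"] = mask_repeats(
                high.candidates[cid],
                find_perfect_repeats(high.candidates[cid], config.min_units),
            )
        xhits = all_vs_all(
            combined,
            min_identity_report=config.cluster_min_identity,
            min_aln_len=config.cluster_min_aln_len,
            kmer_prefilter=config.kmer_prefilter,
        )
        for h in xhits:
            if (h.identity > config.contig_identity
                    and h.query_id.startswith("H::") and h.subject_id.startswith("L::")):
                dropped.add(h.query_id[3:])
    ledger.n_deduplicated = len(dropped)

    rows = []
    boulder = []
    for result in (low, high):
        track_name = "contig" if result.track == "low" else "singleton"
        for cid in sorted(result.pairs):
            if result.track == "high" and cid in dropped:
                continue
            locus = result.loci[cid]
            boulder.append(boulder_record(cid, result.candidates[cid], locus,
                                          config.constraints))
            for pair in result.pairs[cid]:
                rows.append({
                    "locus_id": cid,
                    "track": track_name,
                    "motif": locus.motif,
                    "units": locus.unit_count,
                    "left_seq": pair.left.seq,
                    "right_seq": pair.right.seq,
                    "left_tm": f"{pair.left.tm:.2f}",
                    "right_tm": f"{pair.right.tm:.2f}",
                    "product_len": pair.product_len,
                    "penalty": f"{pair.penalty:.4f}",
                })
    primers_path = out_dir / "primers.tsv"
    _write_primers(primers_path, rows)
    (out_dir / "primers.boulder").write_text("".join(boulder))

    ledger.validate()
    ledger_path = out_dir / "ledger.json"
    ledger_path.write_text(ledger.to_json() + "\n", encoding="utf-8")
    (out_dir / "ledger.txt").write_text(ledger_report(ledger), encoding="utf-8")
    return PipelineResult(ledger, primers_path, ledger_path, out_dir)
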