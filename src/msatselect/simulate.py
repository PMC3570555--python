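"""Synthetic 454-style read generator with ground truth.

Emulates the two library preparations the pipeline targets — shotgun
(microsatellite templates at the genomic background rate) and
enrichment (msat-bearing templates oversampled) — and the error
behavior of pyrosequencing: 3' quality decay, quality-calibrated
substitution errors and homopolymer-length miscalls (±1-base indels at
mononucleotide runs of 3+, the dominant 454 error mode).

Every template and read is recorded in a machine-readable truth table
so each pipeline stage can be scored against planted ground truth:
planted perfect repeats (plus sub-threshold 4-unit decoys), planted
repetitive-element segments copied from a generated RE library at a
configurable divergence, optional pairs of templates sharing a
partially homologous flank segment, per-read MID barcodes, strands,
and the exact error positions introduced.

Planted features are placed in the central ``feature_zone`` of the
template (away from both ends), so that whichever strand a read is
sampled from, ground truth stays inside the region a stringent quality
trim retains — truth-based recovery rates then measure the pipeline's
filters rather than trim geometry.  The 3' decay tail still exercises
the trimmer on every read.

Fixing the seed makes the generated FASTQ byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .demux import BarcodeEntry, BarcodeTable
from .msat import find_perfect_repeats, is_primitive
from .seqio import Read, revcomp, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Default MIDs: standard 454 multiplex identifier adaptor sequences
DEFAULT_MIDS = [
    ("sampleA", "ACGCGTCTAGT"),
    ("sampleB", "ACGAGTAGACT"),
]


@dataclass
class SimConfig:
    n_templates: int = 2000
    template_len: tuple[int, int] = (340, 460)
    mode: str = "shotgun"  # or "enriched"
    msat_fraction: float = 0.3
    enriched_msat_fraction: float = 0.6
    motif_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.50, 3: 0.25, 4: 0.12, 5: 0.08, 6: 0.05}
    )
    unit_count_range: tuple[int, int] = (5, 14)
    decoy_fraction: float = 0.05  # 4-unit sub-threshold arrays in repeat-free templates
    re_fraction: float = 0.12
    re_divergence_range: tuple[float, float] = (0.0, 50.0)  # percent substitutions
    re_segment_len: tuple[int, int] = (150, 300)
    n_re_elements: int = 5
    re_element_len: tuple[int, int] = (400, 800)
    homolog_fraction: float = 0.0  # fraction of templates built as partial-homolog pairs
    homolog_divergence: float = 15.0  # percent; pairwise identity ~ 100 - this
    singleton_fraction: float = 0.7
    contig_depth: int = 3
    q_start: float = 40.0
    q_end: float = 24.0
    q_jitter_sd: float = 1.5
    homopolymer_indel_rate: float = 0.001  # per run of >= 3 identical bases
    mids: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_MIDS))
    mid_error: bool = True  # subject barcode bases to the same error process
    feature_zone: tuple[float, float] = (0.20, 0.80)
    min_flank: int = 60
    seed: int = 0

    def __post_init__(self):
        for p in (self.msat_fraction, self.enriched_msat_fraction, self.re_fraction,
                  self.decoy_fraction, self.singleton_fraction, self.homolog_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.unit_count_range[0] < 2:
            raise ValueError("unit_count_range below 2 is contradictory")
        lo, hi = self.feature_zone
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("feature_zone must satisfy 0 <= lo < hi <= 1")
        if self.mode not in ("shotgun", "enriched"):
            raise ValueError(f"unknown library mode {self.mode!r}")
        if self.template_len[0] < 4 * self.min_flank:
            raise ValueError("templates too short for the configured min_flank")

    @property
    def effective_msat_fraction(self) -> float:
        return self.enriched_msat_fraction if self.mode == "enriched" else self.msat_fraction


@dataclass
class TemplateTruth:
    template_id: str
    sample: str
    sequence: str
    depth: int
    msat: tuple[str, int, int, int] | None = None  # motif, units, start, end
    decoy: tuple[str, int, int, int] | None = None
    re: tuple[str, float, int, int] | None = None  # name, divergence%, start, end
    homolog_partner: str | None = None


@dataclass
class ReadTruth:
    read_id: str
    template_id: str
    sample: str
    strand: str  # '+' or '-'
    sub_positions: tuple[int, ...]  # read coordinates (after any indels)
    indels: tuple[tuple[int, int], ...]  # (read position, +1 insertion / -1 deletion)


@dataclass
class TruthTable:
    templates: dict[str, TemplateTruth]
    reads: dict[str, ReadTruth]

    def write(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        with open(out_dir / "truth_templates.tsv", "w") as fh:
            fh.write(
                "template_id\tsample\tdepth\tlength\tmsat_motif\tmsat_units\t"
                "msat_start\tmsat_end\tdecoy_motif\tdecoy_start\tdecoy_end\t"
                "re_name\tre_divergence\tre_start\tre_end\thomolog_partner\tsequence\n"
            )
            for t in self.templates.values():
                msat = t.msat or ("", "", "", "")
                decoy = (t.decoy[0], t.decoy[2], t.decoy[3]) if t.decoy else ("", "", "")
                re_ = t.re or ("", "", "", "")
                fields = [
                    t.template_id, t.sample, t.depth, len(t.sequence),
                    *msat, *decoy, *re_, t.homolog_partner or "", t.sequence,
                ]
                fh.write("\t".join(str(f) for f in fields) + "\n")
        with open(out_dir / "truth_reads.tsv", "w") as fh:
            fh.write("read_id\ttemplate_id\tsample\tstrand\tsub_positions\tindels\n")
            for r in self.reads.values():
                subs = ",".join(str(p) for p in r.sub_positions)
                ind = ";".join(f"{p}:{d:+d}" for p, d in r.indels)
                fh.write(f"{r.read_id}\t{r.template_id}\t{r.sample}\t{r.strand}\t{subs}\t{ind}\n")


def _random_bases(rng, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _random_motif(rng, k: int) -> str:
    while True:
        m = _random_bases(rng, k)
        if is_primitive(m):
            return m


def _other_base(rng, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _scrub_accidental_repeats(rng, seq: list[str], protected: list[tuple[int, int]],
                              min_units: int = 4, rounds: int = 20) -> None:
    """Re-randomize accidental tandem arrays outside protected spans."""
    for _ in range(rounds):
        dirty = False
        for locus in find_perfect_repeats("".join(seq), min_units=min_units):
            span = set(range(locus.start, locus.end))
            prot = set()
            for s, e in protected:
                prot.update(range(s, e))
            outside = sorted(span - prot)
            if not outside:
                continue  # the planted feature itself
            dirty = True
            for i in outside:
                seq[i] = _other_base(rng, seq[i])
        if not dirty:
            return


def make_re_library(rng, config: SimConfig) -> list[tuple[str, str]]:
    """Generate a small synthetic repetitive-element library."""
    elements = []
    for i in range(config.n_re_elements):
        n = int(rng.integers(config.re_element_len[0], config.re_element_len[1] + 1))
        seq = list(_random_bases(rng, n))
        _scrub_accidental_repeats(rng, seq, [])
        elements.append((f"RE_elem_{i + 1}\tsimulated", "".join(seq)))
    return elements


def _diverged_copy(rng, segment: str, divergence_pct: float) -> str:
    out = list(segment)
    hits = np.flatnonzero(rng.random(len(out)) < divergence_pct / 100.0)
    for i in hits:
        out[i] = _other_base(rng, out[i])
    return "".join(out)


def _build_template(rng, config: SimConfig, tid: str, sample: str, depth: int,
                    re_library, plant_msat: bool, plant_re: bool,
                    plant_decoy: bool) -> TemplateTruth:
    L = int(rng.integers(config.template_len[0], config.template_len[1] + 1))
    seq = list(_random_bases(rng, L))
    zone_lo = max(config.min_flank, int(config.feature_zone[0] * L))
    zone_end = int(config.feature_zone[1] * L)
    protected: list[tuple[int, int]] = []
    msat = decoy = re_truth = None

    def plant_repeat(units: int):
        ks = sorted(config.motif_distribution)
        weights = np.array([config.motif_distribution[k] for k in ks], dtype=float)
        k = int(rng.choice(ks, p=weights / weights.sum()))
        motif = _random_motif(rng, k)
        replen = k * units
        lo, hi = zone_lo, zone_end - replen
        if hi <= lo:
            return None
        start = int(rng.integers(lo, hi + 1))
        end = start + replen
        seq[start:end] = list(motif * units)
        # guard bases: block accidental extension of the planted array
        if seq[start - 1] == motif[-1]:
            seq[start - 1] = _other_base(rng, motif[-1])
        if end < L and seq[end] == motif[0]:
            seq[end] = _other_base(rng, motif[0])
        protected.append((start, end))
        return motif, units, start, end

    if plant_msat:
        lo, hi = config.unit_count_range
        msat = plant_repeat(int(rng.integers(lo, hi + 1)))
    elif plant_decoy:
        decoy = plant_repeat(4)

    if plant_re:
        element_idx = int(rng.integers(0, len(re_library)))
        name = re_library[element_idx][0].split("\t")[0]
        ebases = re_library[element_idx][1]
        div = float(rng.uniform(*config.re_divergence_range))
        want = int(rng.integers(config.re_segment_len[0], config.re_segment_len[1] + 1))
        anchor = protected[-1][1] + 10 if protected else zone_lo
        avail = zone_end - anchor
        floor = min(100, config.re_segment_len[0])
        if avail < floor and protected:
            # no room after the repeat; try the left flank
            anchor, avail = zone_lo, protected[-1][0] - 10 - zone_lo
        if avail >= floor:
            seg_len = min(want, avail)
            e_start = int(rng.integers(0, len(ebases) - seg_len + 1))
            copy = _diverged_copy(rng, ebases[e_start : e_start + seg_len], div)
            seq[anchor : anchor + seg_len] = list(copy)
            protected.append((anchor, anchor + seg_len))
            re_truth = (name, div, anchor, anchor + seg_len)

    _scrub_accidental_repeats(rng, seq, protected)
    return TemplateTruth(tid, sample, "".join(seq), depth, msat, decoy, re_truth)


def _apply_homopolymer_indels(rng, bases: list[str], quals: list[int],
                              rate: float) -> list[tuple[int, int]]:
    events = []
    runs = []
    i = 0
    while i < len(bases):
        j = i
        while j < len(bases) and bases[j] == bases[i]:
            j += 1
        if j - i >= 3:
            runs.append((i, j))
        i = j
    for start, end in reversed(runs):  # right-to-left keeps positions valid
        if rng.random() < rate:
            if rng.random() < 0.5:
                bases.insert(end, bases[start])
                quals.insert(end, quals[end - 1])
                events.append((end, +1))
            else:
                del bases[end - 1]
                del quals[end - 1]
                events.append((end - 1, -1))
    return sorted(events)


def _simulate_read(rng, config: SimConfig, template: TemplateTruth,
                   read_id: str, mid: str) -> tuple[Read, ReadTruth]:
    strand = "+" if rng.random() < 0.5 else "-"
    tseq = template.sequence if strand == "+" else revcomp(template.sequence)
    bases = list(mid + tseq)
    n = len(bases)
    pos = np.arange(n)
    q = config.q_start + (config.q_end - config.q_start) * pos / max(n - 1, 1)
    q = q + rng.normal(0.0, config.q_jitter_sd, size=n)
    quals = list(np.clip(np.rint(q), 2, 40).astype(int))
    indels = _apply_homopolymer_indels(rng, bases, quals, config.homopolymer_indel_rate)
    p_err = np.power(10.0, -np.asarray(quals, dtype=float) / 10.0)
    draw = rng.random(len(bases))
    subs = []
    for i in np.flatnonzero(draw < p_err):
        i = int(i)
        if not config.mid_error and i < len(mid):
            continue
        bases[i] = _other_base(rng, bases[i])
        subs.append(i)
    read = Read(read_id, "".join(bases), tuple(int(x) for x in quals))
    truth = ReadTruth(read_id, template.template_id, template.sample, strand,
                      tuple(subs), tuple(indels))
    return read, truth


def simulate(config: SimConfig):
    """Generate reads in memory.

    Returns ``(reads, truth, re_library)`` where ``re_library`` is a
    list of (name, sequence) FASTA-ready records.
    """
    rng = np.random.default_rng(config.seed)
    re_library = make_re_library(rng, config)
    mids = dict(config.mids)
    samples = sorted(mids)
    templates: dict[str, TemplateTruth] = {}
    reads: list[Read] = []
    read_truths: dict[str, ReadTruth] = {}

    pending_homolog: TemplateTruth | None = None
    for i in range(config.n_templates):
        tid = f"tmpl_{i + 1:06d}"
        sample = samples[int(rng.integers(0, len(samples)))]
        depth = 1 if rng.random() < config.singleton_fraction else config.contig_depth
        plant_msat = rng.random() < config.effective_msat_fraction
        plant_decoy = (not plant_msat) and rng.random() < config.decoy_fraction
        plant_re = rng.random() < config.re_fraction
        as_homolog = rng.random() < config.homolog_fraction

        if pending_homolog is not None:
            # partner template: copy a flank segment from the previous one
            t = _build_template(rng, config, tid, sample, 1, re_library,
                                plant_msat=True, plant_re=False, plant_decoy=False)
            src = pending_homolog
            if t.msat and src.msat:
                seg_start = src.msat[3] + 10
                seg_len = min(
                    len(src.sequence) - seg_start,
                    int(config.feature_zone[1] * len(t.sequence)) - (t.msat[3] + 10),
                    200,
                )
                if seg_len >= 100:
                    segment = _diverged_copy(
                        rng, src.sequence[seg_start : seg_start + seg_len],
                        config.homolog_divergence,
                    )
                    chars = list(t.sequence)
                    dst = t.msat[3] + 10
                    chars[dst : dst + seg_len] = list(segment)
                    t.sequence = "".join(chars)
                    t.homolog_partner = src.template_id
                    src.homolog_partner = t.template_id
            templates[tid] = t
            pending_homolog = None
        else:
            forced_depth = 1 if as_homolog else depth
            t = _build_template(rng, config, tid, sample, forced_depth, re_library,
                                plant_msat=plant_msat or as_homolog,
                                plant_re=plant_re and not as_homolog,
                                plant_decoy=plant_decoy)
            templates[tid] = t
            if as_homolog:
                pending_homolog = t

        for j in range(templates[tid].depth):
            rid = f"{tid}_r{j + 1}"
            read, rtruth = _simulate_read(rng, config, templates[tid], rid,
                                          mids[templates[tid].sample])
            reads.append(read)
            read_truths[rid] = rtruth

    return reads, TruthTable(templates, read_truths), re_library


def simulate_library(config: SimConfig, out_dir):
    """Generate a library on disk: FASTQ + truth tables + RE library FASTA.

    Deterministic under the config seed (byte-identical output files).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads, truth, re_library = simulate(config)
    fastq = out_dir / "reads.fastq"
    write_fastq(reads, fastq)
    truth.write(out_dir)
    re_fasta = out_dir / "re_library.fasta"
    write_fasta(re_library, re_fasta)
    mids_tsv = out_dir / "mids.tsv"
    with open(mids_tsv, "w") as fh:
        for sample, mid in config.mids:
            fh.write(f"{sample}\t{mid}\n")
    return fastq, truth, re_fasta


def barcode_table(config: SimConfig) -> BarcodeTable:
    return BarcodeTable([BarcodeEntry(s, m) for s, m in config.mids])


def calibration_report(fastq_reads: list[Read], truth: TruthTable) -> dict:
    """Per-position stated vs empirical substitution-error calibration.

    Bins bases by read position, compares the empirical substitution
    count against the expectation from the stated Phred scores, and
    summarizes the agreement with a chi-square statistic over positions
    with an expected count of at least 5.
    """
    from scipy import stats

    ids = {r.id for r in fastq_reads}
    missing = ids - set(truth.reads)
    if missing:
        raise ValueError(f"truth table does not cover reads: {sorted(missing)[:3]} ...")
    max_len = max((len(r) for r in fastq_reads), default=0)
    n = np.zeros(max_len)
    exp_p = np.zeros(max_len)
    obs = np.zeros(max_len)
    for r in fastq_reads:
        p = np.power(10.0, -np.asarray(r.quals, dtype=float) / 10.0)
        n[: len(r)] += 1
        exp_p[: len(r)] += p
        for pos in truth.reads[r.id].sub_positions:
            obs[pos] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        emp_rate = np.where(n > 0, obs / n, 0.0)
        stated_rate = np.where(n > 0, exp_p / n, 0.0)
    mask = exp_p >= 5
    chi2 = float(np.sum((obs[mask] - exp_p[mask]) ** 2 / exp_p[mask])) if mask.any() else 0.0
    dof = int(mask.sum())
    pvalue = float(stats.chi2.sf(chi2, dof)) if dof else 1.0
    return {
        "positions": int(max_len),
        "stated_rate": stated_rate.tolist(),
        "empirical_rate": emp_rate.tolist(),
        "chi2": chi2,
        "dof": dof,
        "pvalue": pvalue,
    }
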