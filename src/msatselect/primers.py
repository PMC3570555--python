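"""Constraint-based PCR primer-pair selection around microsatellite loci.

Primer pairs must bracket the *entire* repeat array and produce a
product of 90-300 bp, with oligo lengths 18-27 (optimum 20), melting
temperatures 57-63 °C (optimum 60) differing by at most 1 °C, GC
content 20-80% (optimum 50), no GC clamp requirement, and no
mononucleotide run longer than 4 bases inside a primer (homopolymer
lengths are the dominant pyrosequencing error mode, so priming sites
must avoid them).  Positions called 'N' (consensus ambiguities) are
allowed inside the product but never inside a primer.

Melting temperatures use the unified nearest-neighbor thermodynamic
parameters (SantaLucia 1998) with the matching entropic salt
correction, at 50 mM monovalent cation and 50 nM oligo — the classic
primer-design defaults.

Candidate pairs are ranked by a penalty that sums each primer's
weighted deviation from the optima (1 per bp of length, 1 per °C of
Tm, 0.01 per % GC); ties break deterministically by leftmost left
primer, then shortest product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .msat import MicrosatelliteLocus
from .seqio import revcomp

# Unified NN parameters: enthalpy kcal/mol, entropy cal/(mol*K)
NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
_INIT = {  # terminal base-pair initiation terms
    "G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1),
}
_R = 1.987  # cal/(mol*K)


@dataclass(frozen=True)
class PrimerConstraints:
    product_len: tuple[int, int] = (90, 300)
    primer_len: tuple[int, int, int] = (18, 20, 27)  # min, opt, max
    tm_celsius: tuple[float, float, float] = (57.0, 60.0, 63.0)
    max_tm_diff: float = 1.0
    gc_percent: tuple[float, float, float] = (20.0, 50.0, 80.0)
    gc_clamp: int = 0
    max_polyx: int = 4
    wt_len: float = 1.0
    wt_tm: float = 1.0
    wt_gc: float = 0.01

    def __post_init__(self):
        for lo, opt, hi in (self.primer_len, self.tm_celsius, self.gc_percent):
            if not lo <= opt <= hi:
                raise ValueError("constraint triples must satisfy min <= opt <= max")
        if self.product_len[0] > self.product_len[1]:
            raise ValueError("empty product-length interval")


@dataclass(frozen=True)
class PrimerOligo:
    seq: str  # 5'->3' (right primer: on the reverse strand)
    start: int  # binding-site start on the forward strand
    length: int
    tm: float
    gc: float


@dataclass(frozen=True)
class PrimerPair:
    locus: MicrosatelliteLocus
    left: PrimerOligo
    right: PrimerOligo
    product_len: int
    penalty: float


def _thermo_sums(oligo: str) -> tuple[float, float]:
    dh = _INIT[oligo[0]][0] + _INIT[oligo[-1]][0]
    ds = _INIT[oligo[0]][1] + _INIT[oligo[-1]][1]
    for i in range(len(oligo) - 1):
        step = oligo[i : i + 2]
        dh += NN_DH[step]
        ds += NN_DS[step]
    return dh, ds


def _tm_from_sums(dh: float, ds: float, n: int, selfcomp: bool,
                  na_mM: float, oligo_nM: float) -> float:
    ds = ds + 0.368 * (n - 1) * math.log(na_mM / 1000.0)
    x = 1.0 if selfcomp else 4.0
    if selfcomp:
        ds += -1.4  # symmetry correction
    ct = oligo_nM * 1e-9
    return 1000.0 * dh / (ds + _R * math.log(ct / x)) - 273.15


def melting_temp(oligo: str, na_mM: float = 50.0, oligo_nM: float = 50.0) -> float:
    """Nearest-neighbor duplex melting temperature in Celsius."""
    oligo = oligo.upper()
    if not 10 <= len(oligo) <= 36:
        raise ValueError("oligo length must be in [10, 36]")
    if set(oligo) - set("ACGT"):
        raise ValueError("oligo contains non-ACGT characters (N not allowed)")
    dh, ds = _thermo_sums(oligo)
    return _tm_from_sums(dh, ds, len(oligo), oligo == revcomp(oligo), na_mM, oligo_nM)


def gc_content(oligo: str) -> float:
    """GC percentage of an oligo."""
    if not oligo:
        raise ValueError("empty oligo")
    o = oligo.upper()
    return 100.0 * (o.count("G") + o.count("C")) / len(o)


def max_homopolymer(oligo: str) -> int:
    best = run = 1
    for a, b in zip(oligo, oligo[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


class _TemplateThermo:
    """O(1) per-substring Tm/GC/poly-X/N evaluation via prefix arrays.

    The nearest-neighbor model is strand symmetric, so the Tm of the
    reverse-complement oligo equals the Tm of the forward substring;
    right primers are therefore evaluated on the forward strand.
    """

    def __init__(self, template: str):
        self.seq = template.upper()
        n = len(self.seq)
        dh = np.zeros(n)  # step i = dinucleotide (i, i+1)
        ds = np.zeros(n)
        for i in range(n - 1):
            step = self.seq[i : i + 2]
            if step in NN_DH:
                dh[i] = NN_DH[step]
                ds[i] = NN_DS[step]
        self.dh_cum = np.concatenate(([0.0], np.cumsum(dh)))
        self.ds_cum = np.concatenate(([0.0], np.cumsum(ds)))
        isgc = np.array([c in "GC" for c in self.seq], dtype=np.int64)
        self.gc_cum = np.concatenate(([0], np.cumsum(isgc)))
        isn = np.array([c not in "ACGT" for c in self.seq], dtype=np.int64)
        self.n_cum = np.concatenate(([0], np.cumsum(isn)))

    def has_n(self, s: int, e: int) -> bool:
        return bool(self.n_cum[e] - self.n_cum[s])

    def gc(self, s: int, e: int) -> float:
        return 100.0 * (self.gc_cum[e] - self.gc_cum[s]) / (e - s)

    def run_prefix(self, max_polyx: int) -> np.ndarray:
        """Prefix counts of starts of (max_polyx+1)-long homopolymer runs."""
        L = max_polyx + 1
        n = len(self.seq)
        viol = np.zeros(n, dtype=np.int64)
        run = 1
        for i in range(1, n):
            run = run + 1 if self.seq[i] == self.seq[i - 1] else 1
            if run >= L:
                viol[i - L + 1] = 1
        return np.concatenate(([0], np.cumsum(viol)))

    def tm(self, s: int, e: int) -> float:
        dh = self.dh_cum[e - 1] - self.dh_cum[s]
        ds = self.ds_cum[e - 1] - self.ds_cum[s]
        first, last = self.seq[s], self.seq[e - 1]
        dh += _INIT[first][0] + _INIT[last][0]
        ds += _INIT[first][1] + _INIT[last][1]
        sub = self.seq[s:e]
        return _tm_from_sums(dh, ds, e - s, sub == revcomp(sub), 50.0, 50.0)


def _candidates(thermo, viol_cum, s_lo, s_hi, e_lo, e_hi, c: PrimerConstraints):
    """All single primers [s, e) with s in [s_lo, s_hi), e in [e_lo, e_hi)."""
    len_min, len_opt, len_max = c.primer_len
    tm_min, tm_opt, tm_max = c.tm_celsius
    gc_min, gc_opt, gc_max = c.gc_percent
    L5 = c.max_polyx + 1
    out = []
    for s in range(s_lo, s_hi):
        for length in range(len_min, len_max + 1):
            e = s + length
            if e < e_lo or e > e_hi:
                continue
            if thermo.has_n(s, e):
                continue
            if e - L5 + 1 > s and viol_cum[e - L5 + 1] - viol_cum[s] > 0:
                continue
            gc = thermo.gc(s, e)
            if not gc_min <= gc <= gc_max:
                continue
            tm = thermo.tm(s, e)
            if not tm_min <= tm <= tm_max:
                continue
            pen = (
                c.wt_len * abs(length - len_opt)
                + c.wt_tm * abs(tm - tm_opt)
                + c.wt_gc * abs(gc - gc_opt)
            )
            out.append((s, e, tm, gc, pen))
    return out


def design_pairs(
    template: str,
    locus: MicrosatelliteLocus,
    constraints: PrimerConstraints | None = None,
    top_k: int = 3,
) -> list[PrimerPair]:
    """Best primer pairs bracketing a locus, ascending penalty.

    Enumerates every left/right placement whose product covers the full
    repeat span and satisfies all constraints; returns up to ``top_k``
    pairs (possibly none).  Ranking is total and deterministic: penalty,
    then leftmost left primer, then shortest product.
    """
    c = constraints or PrimerConstraints()
    n = len(template)
    if not (0 <= locus.start <= locus.end <= n):
        raise ValueError("locus outside template")
    thermo = _TemplateThermo(template)
    viol_cum = thermo.run_prefix(c.max_polyx)
    prod_min, prod_max = c.product_len
    len_min, len_max = c.primer_len[0], c.primer_len[2]

    left_s_lo = max(0, locus.end - prod_max)
    left_s_hi = max(0, locus.start - len_min + 1)
    lefts = _candidates(thermo, viol_cum, left_s_lo, left_s_hi, 0, locus.start, c)
    if not lefts:
        return []
    # rightmost admissible product end: largest valid left start + max product
    right_e_hi = min(n, (left_s_hi - 1) + prod_max)
    rights = _candidates(
        thermo, viol_cum, locus.end, max(locus.end, right_e_hi - len_min + 1),
        locus.end + len_min, right_e_hi, c,
    )
    if c.gc_clamp > 0:
        lefts = [t for t in lefts if all(b in "GC" for b in thermo.seq[t[1] - c.gc_clamp : t[1]])]
        rights = [t for t in rights if all(b in "GC" for b in thermo.seq[t[0] : t[0] + c.gc_clamp])]
    if not lefts or not rights:
        return []

    lefts.sort(key=lambda t: t[4])
    rights_by_pen = sorted(rights, key=lambda t: t[4])
    min_right_pen = rights_by_pen[0][4]
    best: list[tuple] = []  # (penalty, left_s, product_len, right_e, left, right)

    def worst() -> float:
        return best[-1][0] if len(best) >= top_k else math.inf

    for left in lefts:
        ls, le, ltm, lgc, lpen = left
        if lpen + min_right_pen > worst():
            break
        for right in rights_by_pen:
            rs, re_, rtm, rgc, rpen = right
            pen = lpen + rpen
            if pen > worst():
                break
            prod = re_ - ls
            if not prod_min <= prod <= prod_max:
                continue
            if abs(ltm - rtm) > c.max_tm_diff:
                continue
            entry = (pen, ls, prod, re_, left, right)
            best.append(entry)
            best.sort(key=lambda t: t[:4])
            del best[top_k:]
    pairs = []
    for pen, ls, prod, re_, left, right in best:
        ls, le, ltm, lgc, lpen = left
        rs, re2, rtm, rgc, rpen = right
        pairs.append(
            PrimerPair(
                locus=locus,
                left=PrimerOligo(thermo.seq[ls:le], ls, le - ls, ltm, lgc),
                right=PrimerOligo(revcomp(thermo.seq[rs:re2]), rs, re2 - rs, rtm, rgc),
                product_len=prod,
                penalty=pen,
            )
        )
    return pairs


def boulder_record(seq_id: str, template: str, locus: MicrosatelliteLocus,
                   c: PrimerConstraints | None = None) -> str:
    """Primer3-compatible Boulder-IO input record for one locus."""
    c = c or PrimerConstraints()
    lines = [
        f"SEQUENCE_ID={seq_id}",
        f"SEQUENCE_TEMPLATE={template}",
        f"SEQUENCE_TARGET={locus.start},{locus.end - locus.start}",
        f"PRIMER_PRODUCT_SIZE_RANGE={c.product_len[0]}-{c.product_len[1]}",
        f"PRIMER_MIN_SIZE={c.primer_len[0]}",
        f"PRIMER_OPT_SIZE={c.primer_len[1]}",
        f"PRIMER_MAX_SIZE={c.primer_len[2]}",
        f"PRIMER_MIN_TM={c.tm_celsius[0]}",
        f"PRIMER_OPT_TM={c.tm_celsius[1]}",
        f"PRIMER_MAX_TM={c.tm_celsius[2]}",
        f"PRIMER_PAIR_MAX_DIFF_TM={c.max_tm_diff}",
        f"PRIMER_MIN_GC={c.gc_percent[0]}",
        f"PRIMER_OPT_GC_PERCENT={c.gc_percent[1]}",
        f"PRIMER_MAX_GC={c.gc_percent[2]}",
        f"PRIMER_GC_CLAMP={c.gc_clamp}",
        f"PRIMER_MAX_POLY_X={c.max_polyx}",
        "=",
    ]
    return "\n".join(lines) + "\n"
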