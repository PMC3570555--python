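"""Sliding-window quality trimming (lucy-style three-step procedure).

The trimmer selects, for each read, the largest contiguous region whose
base-call accuracy satisfies three nested conditions:

1. *bracket*: leading and trailing bases are shaved off while the
   terminal window of ``bracket_window`` bases has an average error
   probability above ``bracket_max_err``;
2. *window*: every sliding window of each configured length inside the
   candidate region must have an average error probability no greater
   than that window's cap;
3. *region*: among regions passing step 2, keep the longest one whose
   overall average error probability is at most ``global_max_err`` and
   whose two terminal ``bracket_window``-sized windows are each at or
   below ``tail_max_err``.

Ties on length are broken by the smaller average error, then by the
leftmost start, so trimming is fully deterministic.  Regions shorter
than ``min_len`` after trimming are rejected outright.

Two presets reproduce the stringency settings used for marker
selection from 454 data: a *high* stringency (bracket 10 bp / 0.003,
window 10 bp / 0.003, region 0.003 with 0.02 tails) and a *low*
stringency (bracket 10 bp / 0.02, window 50 bp / 0.08, region 0.025
with 0.02 tails).

Windows operate on error probabilities (``10**(-Q/10)``), never on raw
Phred scores; 'N' bases carry probability 1.0, so any window containing
an N fails every threshold.  When a candidate region is shorter than a
configured window length, the whole region is evaluated as a single
truncated window of its actual length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .seqio import Read


@dataclass(frozen=True)
class QCParams:
    bracket_window: int
    bracket_max_err: float
    windows: tuple[tuple[int, float], ...]
    global_max_err: float
    tail_max_err: float
    min_len: int = 100

    def __post_init__(self):
        probs = [self.bracket_max_err, self.global_max_err, self.tail_max_err] + [
            e for _, e in self.windows
        ]
        if any(not (0 < p <= 1) for p in probs):
            raise ValueError("error-probability thresholds must be in (0, 1]")
        if self.bracket_window < 1 or any(w < 1 for w, _ in self.windows):
            raise ValueError("window lengths must be >= 1")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


PRESETS = {
    # bracket 10bp/0.003; window 10bp/0.003; region cap 0.003, tails 0.02
    "high": QCParams(10, 0.003, ((10, 0.003),), 0.003, 0.02),
    # bracket 10bp/0.02; window 50bp/0.08; region cap 0.025, tails 0.02
    "low": QCParams(10, 0.02, ((50, 0.08),), 0.025, 0.02),
}


def preset(name: str) -> QCParams:
    """Return a named stringency preset ('high' or 'low')."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown QC preset {name!r}; available presets: {sorted(PRESETS)}"
        ) from None


def bracket_trim(p: np.ndarray, start: int, end: int, window: int, max_err: float) -> tuple[int, int]:
    """Step 1: shave terminal bases while a terminal window is too noisy."""
    cp = np.concatenate(([0.0], np.cumsum(p)))
    i, j = start, end
    while i < j:
        w = min(window, j - i)
        if (cp[i + w] - cp[i]) / w > max_err:
            i += 1
            continue
        w = min(window, j - i)
        if (cp[j] - cp[j - w]) / w > max_err:
            j -= 1
            continue
        break
    return i, j


def trim_read(read: Read, params: QCParams) -> Read | None:
    """Trim one read; returns the read with ``clip`` narrowed, or None.

    ``None`` signals rejection (no qualifying region of at least
    ``min_len`` bases); it is a return state, not an error.
    """
    if len(read) == 0:
        return None
    p = read.error_probs()
    i, j = bracket_trim(p, read.clip[0], read.clip[1], params.bracket_window, params.bracket_max_err)
    if j - i < params.min_len:
        return None

    cp = np.concatenate(([0.0], np.cumsum(p)))
    n = j - i
    # Per window config: cumulative count of *bad* full-window start
    # positions within [i, j), so "all windows in a range pass" is O(1).
    badcum = []
    for w, emax in params.windows:
        if n >= w:
            means = (cp[i + w : j + 1] - cp[i : j - w + 1]) / w  # starts i .. j-w
            bad = (means > emax).astype(np.int64)
            badcum.append(np.concatenate(([0], np.cumsum(bad))))
        else:
            badcum.append(None)

    bw = params.bracket_window
    for L in range(n, 0, -1):
        starts = np.arange(i, j - L + 1)
        means = (cp[starts + L] - cp[starts]) / L
        valid = means <= params.global_max_err
        # terminal windows of the candidate region
        wl = min(bw, L)
        valid &= (cp[starts + wl] - cp[starts]) / wl <= params.tail_max_err
        valid &= (cp[starts + L] - cp[starts + L - wl]) / wl <= params.tail_max_err
        for (w, emax), bc in zip(params.windows, badcum):
            if L >= w:
                lo = starts - i
                valid &= (bc[lo + (L - w) + 1] - bc[lo]) == 0
            else:
                valid &= (cp[starts + L] - cp[starts]) / L <= emax
        if valid.any():
            if L < params.min_len:
                return None
            vm = np.where(valid, means, np.inf)
            k = int(np.argmin(vm))  # first minimum -> leftmost tie-break
            return replace(read, clip=(int(starts[k]), int(starts[k]) + L))
    return None


def qc_summary(reads_before, reads_after) -> dict:
    """Per-position quality quartiles before/after trimming (report payload)."""

    def quartiles(reads, clipped):
        cols: dict[int, list[int]] = {}
        for r in reads:
            quals = r.clipped_quals if clipped else r.quals
            for pos, q in enumerate(quals):
                cols.setdefault(pos, []).append(q)
        out = []
        for pos in sorted(cols):
            q1, q2, q3 = np.percentile(cols[pos], [25, 50, 75])
            out.append({"pos": pos, "q25": float(q1), "median": float(q2), "q75": float(q3)})
        return out

    return {
        "n_before": len(reads_before),
        "n_after": len(reads_after),
        "quartiles_before": quartiles(reads_before, clipped=False),
        "quartiles_after": quartiles(reads_after, clipped=True),
    }
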