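"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the expected result by direct enumeration,
deliberately sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


# --- quality trimming ------------------------------------------------------

def _mean(p, a, b):
    return float(np.mean(p[a:b]))


def brute_bracket(p, start, end, window, max_err):
    i, j = start, end
    while i < j:
        w = min(window, j - i)
        if _mean(p, i, i + w) > max_err:
            i += 1
            continue
        w = min(window, j - i)
        if _mean(p, j - w, j) > max_err:
            j -= 1
            continue
        break
    return i, j


def brute_trim(read, params):
    """Exhaustive O(n^2)-subinterval reference for the three-step trimmer.

    Evaluates every subinterval of the bracket-trimmed region against
    the window and region predicates by direct recomputation, then
    applies the longest / lowest-mean-error / leftmost tie-break.
    Returns a (start, end) clip or None.
    """
    p = read.error_probs()
    i0, j0 = brute_bracket(p, read.clip[0], read.clip[1],
                           params.bracket_window, params.bracket_max_err)

    cp = np.concatenate(([0.0], np.cumsum(p)))

    def mean(a, b):
        return (cp[b] - cp[a]) / (b - a)

    # all window means precomputed once per window length (the search
    # itself remains a plain scan over every subinterval)
    wmeans = {w: (cp[w:] - cp[:-w]) / w for w, _ in params.windows}

    def window_ok(a, b):
        for w, emax in params.windows:
            if b - a < w:
                if mean(a, b) > emax:
                    return False
            elif wmeans[w][a : b - w + 1].max() > emax:
                return False
        return True

    def region_ok(a, b):
        if mean(a, b) > params.global_max_err:
            return False
        wl = min(params.bracket_window, b - a)
        if mean(a, a + wl) > params.tail_max_err:
            return False
        if mean(b - wl, b) > params.tail_max_err:
            return False
        return True

    best = None  # (length, -mean, -start) maximized -> use explicit compare
    for L in range(j0 - i0, 0, -1):
        found = None
        for a in range(i0, j0 - L + 1):
            if window_ok(a, a + L) and region_ok(a, a + L):
                m = mean(a, a + L)
                if found is None or m < found[0]:
                    found = (m, a)
        if found is not None:
            best = (found[1], found[1] + L)
            break
    if best is None or best[1] - best[0] < params.min_len:
        return None
    return best


# --- perfect-repeat mining -------------------------------------------------

def _primitive(m):
    return all(m != m[:d] * (len(m) // d)
               for d in range(1, len(m)) if len(m) % d == 0)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _canon(m):
    rc = "".join(_COMP[c] for c in reversed(m))
    rots = [m[i:] + m[:i] for i in range(len(m))]
    rots += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rots)


def brute_repeats(bases, min_units=5, motif_lens=range(2, 7)):
    """Enumerate every (start, motif length) pair and extend directly.

    Returns a set of (canonical motif, unit_count, start, end).
    """
    b = bases.upper()
    n = len(b)
    out = set()
    for k in motif_lens:
        for start in range(n - 2 * k + 1):
            motif = b[start : start + k]
            if set(motif) - set("ACGT") or not _primitive(motif):
                continue
            # maximality on the left: the period must break at start-1
            if start >= 1 and b[start - 1] == b[start - 1 + k]:
                continue
            j = start + k
            while j < n and b[j] == b[j - k] and b[j] in "ACGT":
                j += 1
            units = (j - start) // k
            if units >= min_units:
                out.add((_canon(motif), units, start, start + units * k))
    return out


# --- local alignment (Gotoh affine DP) -------------------------------------

def gotoh_local(a: str, b: str, match=1.0, mismatch=-2.0,
                gap_open=-5.0, gap_extend=-2.0):
    """Exhaustive affine-gap local alignment.

    Returns (best score, matches, columns) of one optimal alignment,
    recovered by traceback.  Gap-open cost applies to the first gap
    position and gap-extend to each further position, matching the
    aligner convention under test.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[:, 0] = M[0, :] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    best = float(max(M.max(), 0.0))
    if best == 0.0:
        return 0.0, 0, 0
    i, j = np.unravel_index(int(np.argmax(M)), M.shape)
    state = "M"
    matches = cols = 0
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] <= 0:
                break
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = M[i, j] - s
            matches += a[i - 1] == b[j - 1]
            cols += 1
            if abs(prev) < 1e-9 and not (
                abs(M[i - 1, j - 1] - prev) < 1e-9
                or abs(X[i - 1, j - 1] - prev) < 1e-9
                or abs(Y[i - 1, j - 1] - prev) < 1e-9
            ):
                i, j = i - 1, j - 1
                break
            if abs(M[i - 1, j - 1] - prev) < 1e-9:
                state = "M"
            elif abs(X[i - 1, j - 1] - prev) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            cols += 1
            if abs(M[i - 1, j] + gap_open - X[i, j]) < 1e-9:
                state = "M"
            i -= 1
        else:
            cols += 1
            if abs(M[i, j - 1] + gap_open - Y[i, j]) < 1e-9:
                state = "M"
            j -= 1
    return best, matches, cols


# --- primer designability ---------------------------------------------------

def naive_designable(template: str, locus_start: int, locus_end: int) -> bool:
    """Is any constraint-satisfying primer pair available for the locus?

    Direct enumeration with Biopython's nearest-neighbor Tm as the
    thermodynamic authority; stops at the first qualifying pair.
    Constraints: product 90-300, primer 18-27 nt, Tm 57-63 with
    pairwise difference <= 1, GC 20-80%, homopolymer runs <= 4, no N.
    """
    from Bio.Seq import Seq
    from Bio.SeqUtils import MeltingTemp as mt

    def tm(oligo):
        selfcomp = str(Seq(oligo).reverse_complement()) == oligo
        return mt.Tm_NN(oligo, nn_table=mt.DNA_NN3, Na=50, dnac1=25, dnac2=25,
                        saltcorr=5, selfcomp=selfcomp)

    def ok(oligo):
        if "N" in oligo:
            return None
        gc = 100.0 * (oligo.count("G") + oligo.count("C")) / len(oligo)
        if not 20.0 <= gc <= 80.0:
            return None
        run = 1
        for x, y in zip(oligo, oligo[1:]):
            run = run + 1 if x == y else 1
            if run > 4:
                return None
        t = tm(oligo)
        if not 57.0 <= t <= 63.0:
            return None
        return t

    n = len(template)
    lefts = []
    for e in range(locus_start, 17, -1):
        for length in range(18, 28):
            s = e - length
            if s < 0:
                continue
            t = ok(template[s:e])
            if t is not None:
                lefts.append((s, t))
    if not lefts:
        return False
    for s2 in range(locus_end, n - 17):
        for length in range(18, 28):
            e2 = s2 + length
            if e2 > n:
                continue
            t2 = ok(template[s2:e2])
            if t2 is None:
                continue
            for s, t1 in lefts:
                if 90 <= e2 - s <= 300 and abs(t1 - t2) <= 1.0:
                    return True
    return False
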