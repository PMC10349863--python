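"""Independent brute-force oracles used to validate the implementations.

Each oracle is deliberately naive (LP feasibility, exhaustive scanning,
grid search, direct summation) and shares no code with the library paths
it checks.
"""

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# dip statistic: LP over piecewise-linear unimodal CDFs (distinct values)
# ---------------------------------------------------------------------------

def dip_oracle(values) -> float:
    """min over unimodal G of sup|F_n - G|, by LP per candidate mode knot.

    Valid for samples with distinct values (a unimodal CDF may only jump
    at its mode; tied coordinates would let the LP cheat).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0
    best = np.inf
    for k in range(n):
        res = _solve_mode(x, k)
        if res is not None:
            best = min(best, res)
    return best


def _solve_mode(x, k):
    n = len(x)
    nv = n + 2  # g_0..g_{n-1}, u (left limit at mode), eps
    iu, ie = n, n + 1
    c = np.zeros(nv)
    c[ie] = 1.0
    A, b = [], []

    def leq(coefs, rhs):
        row = np.zeros(nv)
        for idx, co in coefs:
            row[idx] += co
        A.append(row)
        b.append(rhs)

    for i in range(n):
        left_idx = iu if i == k else i
        leq([(left_idx, 1.0), (ie, -1.0)], i / n)  # left limit <= i/n + eps
        leq([(i, -1.0), (ie, -1.0)], -(i + 1) / n)  # value >= (i+1)/n - eps
    leq([(ie, -1.0)], 0.0)
    seq = list(range(k)) + [iu, k] + list(range(k + 1, n))
    for a_idx, b_idx in zip(seq, seq[1:]):
        leq([(a_idx, 1.0), (b_idx, -1.0)], 0.0)  # monotone
    leq([(0, -1.0)], 0.0)  # g_0 >= 0
    leq([(n - 1, 1.0)], 1.0)  # g_{n-1} <= 1
    left_pts = [(x[i], i) for i in range(k)] + [(x[k], iu)]
    for (xa, ia), (xb, ib), (xc, ic) in zip(left_pts, left_pts[1:], left_pts[2:]):
        leq([(ib, xc - xb), (ia, -(xc - xb)), (ic, -(xb - xa)), (ib, xb - xa)], 0.0)
    right_pts = [(x[i], i) for i in range(k, n)]
    for (xa, ia), (xb, ib), (xc, ic) in zip(right_pts, right_pts[1:], right_pts[2:]):
        leq([(ib, -(xc - xb)), (ia, xc - xb), (ic, xb - xa), (ib, -(xb - xa))], 0.0)
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                  bounds=[(None, None)] * nv, method="highs")
    return res.x[ie] if res.success else None


# ---------------------------------------------------------------------------
# ID-83 classification: exhaustive repeat / homology scan
# ---------------------------------------------------------------------------

def indel_channel_oracle(seq: str, pos: int, ref: str, alt: str) -> str:
    """Classify a VCF-style indel by exhaustive scanning on the sequence."""
    # minimal representation by trimming
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    if ref:  # deletion
        start, allele = pos, ref
        # exhaustive left-alignment: smallest start' whose deletion gives the
        # same resulting sequence
        result = seq[:start] + seq[start + len(allele):]
        L = len(allele)
        for cand in range(max(0, start - 200), start + 1):
            if seq[:cand] + seq[cand + L:] == result:
                start, allele = cand, seq[cand:cand + L]
                break
        return _classify_del(seq, start, allele)
    start, allele = pos, alt
    result = seq[:start] + allele + seq[start:]
    L = len(allele)
    for cand in range(max(0, start - 200), start + 1):
        ins = seq[cand:cand + 0]
        for rot in range(L):
            a = allele[rot:] + allele[:rot]
            if seq[:cand] + a + seq[cand:] == result:
                start, allele = cand, a
                break
        else:
            continue
        break
    return _classify_ins(seq, start, allele)


def _fold(b):
    return {"A": "T", "G": "C"}.get(b, b)


def _classify_del(seq, start, allele):
    L = len(allele)
    end = start + L
    if L == 1:
        run = 0
        i = start
        while i < len(seq) and seq[i] == allele:
            run += 1
            i += 1
        j = start - 1
        while j >= 0 and seq[j] == allele:
            run += 1
            j -= 1
        return f"1:Del:{_fold(allele)}:{min(run, 6) - 1}"
    # tandem copies containing the deleted block (scan both directions)
    copies = 1
    i = end
    while seq[i:i + L] == allele:
        copies += 1
        i += L
    j = start - L
    while j >= 0 and seq[j:j + L] == allele:
        copies += 1
        j -= L
    size = min(L, 5)
    if copies >= 2:
        return f"{size}:Del:R:{min(copies, 6) - 1}"
    hom = 0
    while hom < L - 1 and end + hom < len(seq) and seq[end + hom] == allele[hom]:
        hom += 1
    hom_left = 0
    while hom_left < L - 1 and start - 1 - hom_left >= 0 and \
            seq[start - 1 - hom_left] == allele[L - 1 - hom_left]:
        hom_left += 1
    hom = max(hom, hom_left)
    if hom >= 1:
        caps = {2: 1, 3: 2, 4: 3, 5: 5}
        return f"{size}:Del:M:{min(hom, caps[size])}"
    return f"{size}:Del:R:0"


def _classify_ins(seq, start, allele):
    L = len(allele)
    if L == 1:
        run = 0
        i = start
        while i < len(seq) and seq[i] == allele:
            run += 1
            i += 1
        j = start - 1
        while j >= 0 and seq[j] == allele:
            run += 1
            j -= 1
        return f"1:Ins:{_fold(allele)}:{min(run, 5)}"
    copies = 0
    i = start
    while seq[i:i + L] == allele:
        copies += 1
        i += L
    j = start - L
    while j >= 0 and seq[j:j + L] == allele:
        copies += 1
        j -= L
    return f"{min(L, 5)}:Ins:R:{min(copies, 5)}"


# ---------------------------------------------------------------------------
# two-signature simplex grid search for exposure fitting
# ---------------------------------------------------------------------------

def simplex_grid_oracle(counts, profile_a, profile_b, resolution=0.01):
    """Best mixture weight of profile_a on a weight grid (L2 on fractions)."""
    v = np.asarray(counts, dtype=float)
    v = v / v.sum()
    ws = np.arange(0.0, 1.0 + resolution / 2, resolution)
    errs = [np.linalg.norm(v - (w * profile_a + (1 - w) * profile_b)) for w in ws]
    return ws[int(np.argmin(errs))]


# ---------------------------------------------------------------------------
# direct-sum periodogram
# ---------------------------------------------------------------------------

def periodogram_direct(x, y, periods):
    """Power by naive python summation."""
    out = []
    for T in periods:
        re = sum(yy * np.cos(-2 * np.pi * xx / T) for xx, yy in zip(x, y))
        im = sum(yy * np.sin(-2 * np.pi * xx / T) for xx, yy in zip(x, y))
        out.append(re * re + im * im)
    return np.array(out)
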