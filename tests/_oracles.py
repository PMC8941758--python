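"""Independent brute-force reference implementations used only by the tests."""

import math

import numpy as np


def brute_cpg_ratio(seq: str) -> float:
    seq = seq.upper()
    n_c = sum(1 for b in seq if b == "C")
    n_g = sum(1 for b in seq if b == "G")
    n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
    length = sum(1 for b in seq if b in "ACGT")
    if n_c == 0 or n_g == 0:
        return 0.0
    return n_cpg * length / (n_c * n_g)


def brute_umrs(pos, frac, meth_cutoff=0.5, n_cpg_cutoff=5, smooth_k=3, masked=None):
    """Run enumeration over every CpG, mirroring the stated UMR definition."""
    n = len(pos)
    if masked is None:
        masked = [False] * n
    half = smooth_k // 2
    smooth = []
    for i in range(n):
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        smooth.append(round(sum(frac[lo:hi]) / (hi - lo), 12))
    low = [smooth[i] < meth_cutoff and not masked[i] for i in range(n)]
    out = []
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and low[j + 1]:
            j += 1
        run = j - i + 1
        if run >= n_cpg_cutoff:
            seg = frac[i : j + 1]
            out.append((int(pos[i]), int(pos[j]) + 1, run, float(np.mean(seg))))
        i = j + 1
    return out


def brute_hypergeom_upper_tail(k, N, K, n) -> float:
    """P(X >= k) by full enumeration of the hypergeometric pmf."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom if denom else 1.0


def brute_bh(pvals):
    """Benjamini-Hochberg step-up, written from the definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def brute_window_gates(row, mean_range=(30, 60), min_pct_full=90, max_delta=40, min_reads=5):
    """Literal re-evaluation of the allelic window gates."""
    import math as _m

    if row["n_reads"] < min_reads:
        return False
    m = row["mean_meth"]
    if m is None or (isinstance(m, float) and _m.isnan(m)):
        return False
    if not (mean_range[0] <= m <= mean_range[1]):
        return False
    if not (row["pct_full"] > min_pct_full):
        return False
    if not (row["delta"] < max_delta):
        return False
    return True
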