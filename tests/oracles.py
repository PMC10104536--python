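"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the junction oracle
enumerates every split point with exact string matching, the sRNA oracle
scans every reference position, and the rank-sum oracle enumerates group
assignments exhaustively.
"""

from itertools import combinations
from math import comb


def find_all(hay, needle):
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def oracle_resolve(seq, ref, k=20, window_upstream=200):
    """Exhaustive split-point enumeration with exact matching.

    A candidate split is [3' arm][tail][5' arm]: the 5' arm is a read
    suffix occurring exactly in the reference, the 3' arm a read prefix
    extended maximally (a base equal to the next reference base is always
    templated), its end inside [D - window_upstream, A3].  Preference:
    maximal total templated length, then shorter tail, then a 5' arm
    anchored at P2, then the longest 5' arm.  Returns the unique best
    anatomy ``(five, three, tail)`` or ``None`` when no candidate exists
    or the best is tied between distinct anatomies.
    """
    refseq = ref.sequence
    n = len(seq)
    d, p2 = ref.sites["D"], ref.sites["P2"]
    lo, hi = max(0, d - window_upstream), ref.sites["A3"]
    cands = []
    for jj in range(k, n - k + 1):
        suffix_hits = find_all(refseq, seq[jj:])
        if not suffix_hits:
            continue
        prefix = seq[:jj]
        three_opts = []
        for b in find_all(refseq, prefix[:k]):
            L = k
            while L < jj and b + L < len(refseq) and prefix[L] == refseq[b + L]:
                L += 1
            e = b + L - 1
            if lo <= e <= hi:
                three_opts.append((L, e))
        for s in suffix_hits:
            for L, e in three_opts:
                key = (-(n - jj + L), jj - L, 0 if s == p2 else 1, jj)
                cands.append((key, (s, e, prefix[L:])))
    if not cands:
        return None
    cands.sort(key=lambda c: c[0])
    best_key, best = cands[0]
    for key, anatomy in cands[1:]:
        if key != best_key:
            break
        if anatomy != best:
            return None  # tied between distinct anatomies
    return best


def oracle_map(read, refseq, refseq_rc, max_mm=0):
    """All-positions scan mapper: returns the minimal-mismatch hits as
    ``(start_in_forward_coords, strand, mismatches)`` tuples."""
    n, m = len(refseq), len(read)
    hits = []
    for strand, target in (("+", refseq), ("-", refseq_rc)):
        for i in range(n - m + 1):
            mm = sum(1 for a, b in zip(target[i : i + m], read) if a != b)
            if mm <= max_mm:
                start = i if strand == "+" else n - i - m
                hits.append((start, strand, mm))
    if not hits:
        return []
    best = min(h[2] for h in hits)
    return sorted(h for h in hits if h[2] == best)


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    return ranks


def oracle_mannwhitney_exact(a, b):
    """Two-sided exact Mann-Whitney p value by exhaustive enumeration of
    group-label assignments over the pooled sample (midranks for ties)."""
    pooled = list(a) + list(b)
    ranks = _midranks(pooled)
    n_a, n = len(a), len(pooled)
    mean_u = n_a * len(b) / 2

    def u_of(idx):
        return sum(ranks[i] for i in idx) - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    count = 0
    total = comb(n, n_a)
    for subset in combinations(range(n), n_a):
        if abs(u_of(subset) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total
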