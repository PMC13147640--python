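"""Independent reference implementations used only by the tests.

These deliberately re-derive each quantity from its definition (direct
enumeration, per-site loops, pairwise differences) rather than calling
the package's own code paths.
"""
import numpy as np

MISSING = -1


def brute_force_roh(row, pos, params):
    """All maximal qualifying SNP-index intervals, greedily disjoint.

    Enumerates every interval, keeps those satisfying all constraints,
    keeps those whose one-step extensions fail, then resolves overlaps
    by earliest start then longest.  Vectorised over right endpoints
    for tolerable speed, but structurally a full enumeration.
    """
    row = np.asarray(row)
    pos = np.asarray(pos, dtype=np.int64)
    m = pos.size
    het = np.concatenate(([0], np.cumsum(row == 1)))
    mis = np.concatenate(([0], np.cumsum(row == MISSING)))
    big_gap = np.concatenate(
        ([0], np.cumsum((np.diff(pos) >= params.max_gap_bp).astype(int)))
    ) if m > 1 else np.zeros(1, dtype=int)

    def qual_matrix(l):
        """Boolean over r = l..m-1: does [l, r] qualify?"""
        rs_ = np.arange(l, m)
        cnt = rs_ - l + 1
        ok = (het[rs_ + 1] - het[l]) <= params.max_het
        ok &= (mis[rs_ + 1] - mis[l]) <= params.max_missing
        if m > 1:
            ok &= (big_gap[rs_] - big_gap[l]) == 0  # no internal gap >= max
        length = pos[rs_] + 1 - pos[l]
        ok &= cnt >= params.min_snps
        ok &= length >= params.min_length_bp
        ok &= (length / 1000.0) <= params.max_density_kb_per_snp * cnt
        return ok

    quals = [qual_matrix(l) for l in range(m)]

    def q(l, r):
        if l < 0 or r >= m or r < l:
            return False
        return bool(quals[l][r - l])

    maximal = [
        (l, r)
        for l in range(m)
        for r in range(l, m)
        if q(l, r) and not q(l - 1, r) and not q(l, r + 1)
    ]
    chosen, last = [], -1
    for l, r in sorted(maximal, key=lambda c: (c[0], -c[1])):
        if l > last:
            chosen.append((l, r))
            last = r
    return chosen


def pairwise_pi(calls, pos, start, end):
    """Average pairwise allele differences per bp inside [start, end).

    Treats each individual's two (unphased) alleles separately and
    averages the per-site mismatch count over all allele pairs drawn
    from distinct or identical individuals (the standard unbiased
    estimator's enumeration form).  Missing genotypes drop that
    individual's alleles at the site.
    """
    total = 0.0
    for j in range(calls.shape[1]):
        if not (start <= pos[j] < end):
            continue
        alleles = []
        for g in calls[:, j]:
            if g == MISSING:
                continue
            alleles.extend([1, 1] if g == 2 else ([0, 1] if g == 1 else [0, 0]))
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(
            1
            for a in range(n)
            for b in range(a + 1, n)
            if alleles[a] != alleles[b]
        )
        total += diffs / (n * (n - 1) / 2)
    return total / (end - start)


def direct_f_hom(calls):
    """Per-individual excess-homozygosity F from the defining formula."""
    calls = np.asarray(calls)
    n_ind, m = calls.shape
    out = []
    for i in range(n_ind):
        o_hom = 0.0
        e_hom = 0.0
        used = 0
        for j in range(m):
            col = calls[:, j]
            # alt-allele expansion: 0 -> 0,0 ; 1 -> 0,1 ; 2 -> 1,1
            alleles = []
            for g in col:
                if g == MISSING:
                    continue
                alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)]
            n = len(alleles)
            if n < 2 or calls[i, j] == MISSING:
                continue
            p = sum(alleles) / n
            used += 1
            o_hom += 1.0 if calls[i, j] in (0, 2) else 0.0
            e_hom += 1.0 - 2.0 * p * (1 - p) * (n / (n - 1))
        out.append((o_hom - e_hom) / (used - e_hom))
    return np.array(out)


def direct_f_grm_uni(calls):
    """Per-individual GRM-diagonal and uniting-gametes F by site loops."""
    calls = np.asarray(calls)
    n_ind, m = calls.shape
    grm = np.zeros(n_ind)
    uni = np.zeros(n_ind)
    for i in range(n_ind):
        vals_g, vals_u = [], []
        for j in range(m):
            col = calls[:, j]
            alleles = []
            for g in col:
                if g == MISSING:
                    continue
                alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)]
            n = len(alleles)
            if n < 2:
                continue
            p = sum(alleles) / n
            if p in (0.0, 1.0) or calls[i, j] == MISSING:
                continue
            x = float(calls[i, j])
            h = 2 * p * (1 - p)
            vals_g.append((x - 2 * p) ** 2 / h - 1.0)
            vals_u.append((x * x - (1 + 2 * p) * x + 2 * p * p) / h)
        grm[i] = np.mean(vals_g)
        uni[i] = np.mean(vals_u)
    return grm, uni


def union_intervals(ivals):
    out = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def jaccard_bp(a, b):
    """Jaccard index of two interval collections keyed by chromosome."""
    keys = set(a) | set(b)
    inter = 0
    total_a = 0
    total_b = 0
    for k in keys:
        ua = union_intervals(a.get(k, []))
        ub = union_intervals(b.get(k, []))
        total_a += sum(e - s for s, e in ua)
        total_b += sum(e - s for s, e in ub)
        i = j = 0
        while i < len(ua) and j < len(ub):
            s = max(ua[i][0], ub[j][0])
            e = min(ua[i][1], ub[j][1])
            if e > s:
                inter += e - s
            if ua[i][1] < ub[j][1]:
                i += 1
            else:
                j += 1
    union = total_a + total_b - inter
    return inter / union if union else 1.0
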