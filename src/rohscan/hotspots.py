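"""Permutation-based ROH hotspot identification with FWER control.

The scan statistic is the SNP-wise ROH frequency within a group: at
each SNP, the fraction of group members with a run covering it (every
group member counts in the denominator, carriers or not).  Under the
null hypothesis that runs are placed uniformly at random along their
chromosomes, each permutation redistributes every individual's segments
within their chromosomes — preserving per-individual, per-chromosome
segment counts and lengths — and records the genome-wide maximum
SNP-wise frequency.  The empirical (1 - alpha) quantile of these maxima
is a single genome-wide threshold controlling the family-wise error
rate at alpha; SNPs whose observed frequency strictly exceeds it are
significant, and runs of adjacent significant SNPs are merged into
hotspot intervals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout, ROHSegment


@dataclass
class CoverageTrack:
    """Per-SNP ROH carrier counts for one group."""

    group_id: str
    n: int
    counts: dict[str, np.ndarray]  # chrom -> per-SNP carrier count
    layout: GenomeLayout

    @property
    def freqs(self) -> dict[str, np.ndarray]:
        return {c: v / self.n for c, v in self.counts.items()}

    @property
    def max_freq(self) -> float:
        mx = 0.0
        for v in self.counts.values():
            if v.size:
                mx = max(mx, float(v.max()) / self.n)
        return mx


@dataclass
class NullMaxDistribution:
    """Per-permutation genome-wide maxima of SNP-wise ROH frequency."""

    group_id: str
    n_perm: int
    max_freqs: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.max_freqs = np.asarray(self.max_freqs, dtype=float)
        if self.max_freqs.size != self.n_perm:
            raise ValueError("max_freqs length must equal n_perm")
        if self.max_freqs.size and (
            self.max_freqs.min() < 0 or self.max_freqs.max() > 1
        ):
            raise ValueError("max frequencies must lie in [0, 1]")


@dataclass
class HotspotResult:
    """Called hotspots plus the per-SNP significance table."""

    group_id: str
    threshold_freq: float
    alpha: float
    hotspots: pd.DataFrame   # chrom, start, end, peak_freq, min_p, n_snps
    snp_table: pd.DataFrame  # chrom, pos, count, freq, p_fwer, significant


def _group_segments(
    segments: list[ROHSegment], members: list[str]
) -> list[ROHSegment]:
    keep = set(members)
    return [s for s in segments if s.sample_id in keep]


def coverage(
    segments: list[ROHSegment],
    layout: GenomeLayout,
    group: tuple[str, list[str]],
) -> CoverageTrack:
    """Observed SNP-wise carrier counts for one group.

    ``group`` is ``(group_id, member sample_ids)``; the denominator is
    the full member list, including ROH-free individuals.  Overlapping
    segments of one individual are tolerated (the individual counts
    once per SNP), mirroring the permutation null's convention.
    """
    gid, members = group
    if len(members) == 0:
        raise ValueError(f"group {gid!r} has no individuals")
    segs = _group_segments(segments, members)
    idx = {s: i for i, s in enumerate(members)}
    counts: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        pos = layout.positions(chrom)
        csegs = [s for s in segs if s.chrom == chrom]
        if not csegs or pos.size == 0:
            counts[chrom] = np.zeros(pos.size, dtype=np.int64)
            continue
        ind = np.array([idx[s.sample_id] for s in csegs])
        s_idx = np.searchsorted(pos, [s.start for s in csegs], side="left")
        e_idx = np.searchsorted(pos, [s.end for s in csegs], side="left")
        counts[chrom] = _union_coverage(ind, s_idx, e_idx, len(members),
                                        pos.size, n_perm=1)[0]
    return CoverageTrack(group_id=gid, n=len(members), counts=counts, layout=layout)


def _union_coverage(ind, s_idx, e_idx, n_ind, m, n_perm):
    """Carrier counts at SNP indices, counting an individual once per SNP.

    ``ind``, ``s_idx``, ``e_idx`` are flat arrays over all (permutation,
    segment) pairs; interval endpoints are SNP-index based, half-open.
    ``ind`` must already encode permutation * n_ind + individual when
    n_perm > 1.  Returns an (n_perm, m) count array.

    Intervals of one individual are unioned by sorting on a composite
    key (owner, start): after offsetting by owner * (m + 1), intervals
    of different owners cannot interleave, so a single global cumulative
    maximum of end keys identifies merged runs.
    """
    width = m + 1
    key_s = ind.astype(np.int64) * width + s_idx
    key_e = ind.astype(np.int64) * width + e_idx
    order = np.argsort(key_s, kind="stable")
    ks = key_s[order]
    ke = key_e[order]
    cmax = np.maximum.accumulate(ke)
    new_run = np.ones(ks.size, dtype=bool)
    if ks.size > 1:
        new_run[1:] = ks[1:] > cmax[:-1]
    run_starts = np.flatnonzero(new_run)
    merged_s = ks[run_starts]
    merged_e = np.maximum.reduceat(ke, run_starts)
    # map back to (perm, snp index)
    perm = merged_s // (width * n_ind)
    si = merged_s % width
    ei = merged_e % width
    diff = np.zeros(n_perm * width, dtype=np.int64)
    np.add.at(diff, perm * width + si, 1)
    np.subtract.at(diff, perm * width + ei, 1)
    cov = np.cumsum(diff).reshape(n_perm, width)[:, :m]
    return cov


def permute_null(
    segments: list[ROHSegment],
    layout: GenomeLayout,
    group: tuple[str, list[str]],
    n_perm: int = 10_000,
    seed: int | None = 0,
    chunk: int = 256,
) -> NullMaxDistribution:
    """Max-statistic null distribution under within-chromosome placement.

    Each permutation independently draws, for every segment, a new start
    uniform on ``[0, chrom_len - length]`` (same individual, same
    chromosome, same length), recomputes SNP-wise carrier counts — an
    individual's displaced segments may overlap, in which case the
    individual still counts once — and records the genome-wide maximum
    frequency.  Deterministic given ``seed``.
    """
    gid, members = group
    if len(members) == 0:
        raise ValueError(f"group {gid!r} has no individuals")
    segs = _group_segments(segments, members)
    idx = {s: i for i, s in enumerate(members)}
    lengths_bp = layout.lengths
    for s in segs:
        if s.length_bp > lengths_bp[s.chrom]:
            raise ValueError(
                f"segment of {s.sample_id} longer than chromosome {s.chrom}"
            )
    rng = np.random.default_rng(seed)
    n_ind = len(members)
    maxima = np.zeros(n_perm, dtype=float)
    for chrom in layout.names:
        pos = layout.positions(chrom)
        csegs = [s for s in segs if s.chrom == chrom]
        if not csegs or pos.size == 0:
            continue
        ind = np.array([idx[s.sample_id] for s in csegs], dtype=np.int64)
        seg_len = np.array([s.length_bp for s in csegs], dtype=np.int64)
        chrom_len = lengths_bp[chrom]
        m = pos.size
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            starts = rng.integers(0, chrom_len - seg_len + 1,
                                  size=(b, seg_len.size), dtype=np.int64)
            s_idx = np.searchsorted(pos, starts.ravel(), side="left")
            e_idx = np.searchsorted(pos, (starts + seg_len).ravel(), side="left")
            perm_of = np.repeat(np.arange(b, dtype=np.int64), seg_len.size)
            owner = perm_of * n_ind + np.tile(ind, b)
            cov = _union_coverage(owner, s_idx, e_idx, n_ind, m, n_perm=b)
            cmx = cov.max(axis=1) if m else np.zeros(b, dtype=np.int64)
            np.maximum(maxima[done:done + b], cmx / n_ind,
                       out=maxima[done:done + b])
            done += b
    return NullMaxDistribution(group_id=gid, n_perm=n_perm, max_freqs=maxima,
                               seed=seed)


def fwer_threshold(null: NullMaxDistribution, alpha: float = 0.01) -> float:
    """Empirical (1 - alpha) order-statistic threshold of the null maxima.

    Uses the order statistic at rank ``ceil((1 - alpha) * n_perm)``
    (1-based), the standard conservative permutation quantile.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if null.n_perm == 0:
        raise ValueError("empty null distribution")
    k = math.ceil((1 - alpha) * null.n_perm)
    return float(np.sort(null.max_freqs)[k - 1])


def call_hotspots(
    observed: CoverageTrack,
    null: NullMaxDistribution,
    alpha: float = 0.01,
    merge_gap_bp: int | None = None,
) -> HotspotResult:
    """Call hotspots by comparing observed SNP frequencies to the null.

    A SNP is significant iff its observed frequency *strictly* exceeds
    the threshold (conservative under ties).  The FWER-adjusted
    empirical P per SNP is ``(1 + #{perm max >= freq}) / (n_perm + 1)``.
    Consecutive significant SNPs on a chromosome are merged into one
    hotspot ``[first SNP, last SNP + 1)``; when ``merge_gap_bp`` is set,
    runs separated by less than that many bp are bridged.
    """
    thr = fwer_threshold(null, alpha)
    null_sorted = np.sort(null.max_freqs)
    snp_rows = []
    hot_rows = []
    for chrom in observed.layout.names:
        pos = observed.layout.positions(chrom)
        cnt = observed.counts[chrom]
        freq = cnt / observed.n
        # P = (1 + #{null >= f}) / (n_perm + 1)
        n_ge = null.n_perm - np.searchsorted(null_sorted, freq, side="left")
        p = (1.0 + n_ge) / (null.n_perm + 1.0)
        sig = freq > thr
        snp_rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "count": cnt, "freq": freq,
            "p_fwer": p, "significant": sig,
        }))
        for l, r in _significant_runs(pos, sig, merge_gap_bp):
            sl = slice(l, r + 1)
            hot_rows.append({
                "chrom": chrom, "start": int(pos[l]), "end": int(pos[r]) + 1,
                "peak_freq": float(freq[sl].max()),
                "min_p": float(p[sl].min()),
                "n_snps": int(sig[sl].sum()),
            })
    snp_table = pd.concat(snp_rows, ignore_index=True) if snp_rows else \
        pd.DataFrame(columns=["chrom", "pos", "count", "freq", "p_fwer",
                              "significant"])
    hotspots = pd.DataFrame(
        hot_rows, columns=["chrom", "start", "end", "peak_freq", "min_p", "n_snps"]
    )
    return HotspotResult(group_id=observed.group_id, threshold_freq=thr,
                         alpha=alpha, hotspots=hotspots, snp_table=snp_table)


def _significant_runs(pos, sig, merge_gap_bp):
    """Runs of consecutive significant SNPs, optionally bridging gaps."""
    runs = []
    start = None
    last = None
    for i in np.flatnonzero(sig):
        if start is None:
            start = last = int(i)
            continue
        consecutive = i == last + 1
        bridged = (
            merge_gap_bp is not None and pos[i] - pos[last] < merge_gap_bp
        )
        if consecutive or bridged:
            last = int(i)
        else:
            runs.append((start, last))
            start = last = int(i)
    if start is not None:
        runs.append((start, last))
    return runs


def region_overlap_frequency(
    segments: list[ROHSegment],
    groups: dict[str, list[str]],
    regions: pd.DataFrame,
) -> pd.DataFrame:
    """Fraction of each group's individuals with an ROH overlapping each region.

    ``regions`` needs ``chrom``, ``start``, ``end`` columns (0-based
    half-open).  Overlap means a non-empty intersection; an ROH touching
    a region only at its half-open end does not overlap.
    """
    if len(regions) and (regions["end"] <= regions["start"]).any():
        raise ValueError("malformed region intervals (end <= start)")
    rows = []
    for gid, members in groups.items():
        segs = _group_segments(segments, members)
        for reg in regions.itertuples(index=False):
            carriers = {
                s.sample_id
                for s in segs
                if s.chrom == str(reg.chrom)
                and s.start < reg.end and reg.start < s.end
            }
            rows.append({
                "group_id": gid, "chrom": str(reg.chrom),
                "start": int(reg.start), "end": int(reg.end),
                "n_carriers": len(carriers),
                "freq": len(carriers) / len(members),
            })
    return pd.DataFrame(
        rows, columns=["group_id", "chrom", "start", "end", "n_carriers", "freq"]
    )
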