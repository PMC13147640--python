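"""Sliding-window selection-statistic summaries and hotspot overlap.

Selection statistics computed by external engines (iHS, CLR, XP-EHH,
F_ST) are consumed as per-site tables and summarised into 50 kb / 20 kb
sliding windows; nucleotide diversity (pi) is computed natively from
genotypes.  Windows are z-standardised per statistic, one-sided normal
tail probabilities are taken (lower tail for pi, upper for the rest),
and windows with p below the retention level are merged into candidate
selection intervals.  Hotspots are then cross-referenced against these
intervals: a hotspot is "supported" by a method if their intervals
intersect, and the fraction of hotspot SNPs inside >= 1 / >= 2 methods'
intervals summarises the overall concordance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import MISSING, GenomeLayout, GenotypeMatrix
from .hotspots import HotspotResult

#: tail used for retention, per statistic (low pi = swept diversity)
DEFAULT_TAILS = {
    "prop_ihs": "upper",
    "max_clr": "upper",
    "pi": "lower",
    "xpehh_mean": "upper",
    "fst_mean": "upper",
}


def make_windows(
    layout: GenomeLayout, size_bp: int = 50_000, step_bp: int = 20_000
) -> pd.DataFrame:
    """Sliding windows ``[k*step, k*step + size)`` per chromosome.

    Window starts run while ``start < chrom_length``; windows reaching
    past the chromosome end are truncated at it.
    """
    if size_bp <= 0 or step_bp <= 0:
        raise ValueError("window size and step must be positive")
    if step_bp > size_bp:
        raise ValueError("step must be <= size")
    rows = []
    for chrom, length in layout.chromosomes:
        starts = np.arange(0, length, step_bp)
        for st in starts:
            rows.append({"chrom": chrom, "start": int(st),
                         "end": int(min(st + size_bp, length))})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_summarize(
    per_site: pd.DataFrame,
    windows: pd.DataFrame,
    statistic: str,
    min_snps: int = 10,
    ihs_abs_threshold: float = 2.0,
) -> pd.DataFrame:
    """Aggregate a per-site statistic table into windows.

    ``per_site`` needs ``chrom``, ``pos`` (0-based), ``value`` columns,
    sorted by position within chromosome.  Aggregation: ``prop_ihs`` =
    fraction of sites with |value| >= threshold (windows with fewer
    than ``min_snps`` sites are dropped — this filter applies to
    prop_ihs only); ``max_clr`` = max; ``xpehh_mean``/``fst_mean`` =
    mean.  A site contributes to every window containing it.
    """
    aggs = {"prop_ihs", "max_clr", "xpehh_mean", "fst_mean", "custom"}
    if statistic not in aggs:
        raise ValueError(f"unknown statistic {statistic!r}")
    rows = []
    for chrom, wsub in windows.groupby("chrom", sort=False):
        sites = per_site[per_site["chrom"] == chrom]
        pos = sites["pos"].to_numpy()
        if pos.size and np.any(np.diff(pos) < 0):
            raise ValueError(f"per-site table not sorted on {chrom}")
        vals = sites["value"].to_numpy(dtype=float)
        for w in wsub.itertuples(index=False):
            lo = np.searchsorted(pos, w.start, side="left")
            hi = np.searchsorted(pos, w.end, side="left")
            v = vals[lo:hi]
            n = int(hi - lo)
            if statistic == "prop_ihs":
                if n < min_snps:
                    continue
                value = float((np.abs(v) >= ihs_abs_threshold).mean())
            elif statistic == "max_clr":
                value = float(v.max()) if n else float("nan")
            else:  # mean-type
                value = float(v.mean()) if n else float("nan")
            rows.append({"chrom": w.chrom, "start": w.start, "end": w.end,
                         "statistic": statistic, "value": value, "n_snps": n})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "statistic",
                                       "value", "n_snps"])


def pi_windows(
    genotypes: GenotypeMatrix,
    group: list[str],
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Nucleotide diversity per window for one group of individuals.

    Per site, ``pi = n/(n-1) * 2 p (1-p)`` with n the non-missing allele
    count (the unbiased average pairwise difference); the window value
    is the sum over its sites divided by the window's bp length
    (truncated windows use their truncated length).
    """
    if len(group) < 2:
        raise ValueError("pi needs at least 2 individuals")
    idx = [genotypes.sample_index(s) for s in group]
    rows = []
    for chrom, wsub in windows.groupby("chrom", sort=False):
        pos = genotypes.layout.positions(chrom)
        calls = genotypes.chrom_calls(chrom)[idx]
        obs = calls != MISSING
        n = 2 * obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
            site_pi = np.where(n >= 2, (n / np.maximum(n - 1, 1)) * 2 * p * (1 - p), 0.0)
        for w in wsub.itertuples(index=False):
            lo = np.searchsorted(pos, w.start, side="left")
            hi = np.searchsorted(pos, w.end, side="left")
            length = w.end - w.start
            rows.append({
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "statistic": "pi",
                "value": float(site_pi[lo:hi].sum()) / length,
                "n_snps": int(hi - lo),
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "statistic",
                                       "value", "n_snps"])


def retain_windows(
    stats_table: pd.DataFrame,
    alpha: float = 0.01,
    tail: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-standardise window values and retain the extreme tail.

    ``z = (value - mean) / sd`` across all windows of the statistic;
    one-sided normal p in the configured tail (defaults per statistic,
    see :data:`DEFAULT_TAILS`); a window is retained iff ``p < alpha``.
    Returns the annotated table and the retained windows merged into
    maximal intervals per chromosome.
    """
    if len(stats_table) < 10:
        raise ValueError("need >= 10 windows for a stable z-scale")
    df = stats_table.copy()
    statistic = df["statistic"].iloc[0]
    if (df["statistic"] != statistic).any():
        raise ValueError("retain_windows expects a single statistic")
    tail = tail or DEFAULT_TAILS.get(statistic, "upper")
    if tail not in ("upper", "lower"):
        raise ValueError(f"unknown tail {tail!r}")
    vals = df["value"].to_numpy(dtype=float)
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation across windows")
    z = (vals - float(np.mean(vals))) / sd
    p = stats.norm.sf(z) if tail == "upper" else stats.norm.cdf(z)
    df["z"] = z
    df["nominal_p"] = p
    df["retained"] = p < alpha
    return df, merge_intervals(df[df["retained"]][["chrom", "start", "end"]])


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or abutting half-open intervals per chromosome."""
    rows = []
    for chrom, sub in intervals.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for r in sub.sort_values("start").itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
                cur_s, cur_e = r.start, r.end
        if cur_s is not None:
            rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def overlap_report(
    hotspots: HotspotResult,
    retained: dict[str, pd.DataFrame],
    layout: GenomeLayout,
) -> dict:
    """Cross-validate hotspots against retained selection intervals.

    ``retained`` maps method name -> interval table (chrom/start/end,
    half-open).  A hotspot is supported by a method iff some interval
    intersects it.  Also reports the percentage of hotspot SNPs lying
    inside the interval union of >= 1 and >= 2 methods.
    """
    hot = hotspots.hotspots
    support_rows = []
    for h in hot.itertuples(index=False):
        n_methods = 0
        methods = []
        for name, ivals in retained.items():
            sub = ivals[ivals["chrom"] == h.chrom]
            if ((sub["start"] < h.end) & (h.start < sub["end"])).any():
                n_methods += 1
                methods.append(name)
        support_rows.append({
            "chrom": h.chrom, "start": h.start, "end": h.end,
            "n_methods": n_methods, "methods": ",".join(methods),
        })
    support = pd.DataFrame(
        support_rows, columns=["chrom", "start", "end", "n_methods", "methods"]
    )
    # per-SNP accounting over hotspot SNPs
    n_snps = 0
    n_ge1 = 0
    n_ge2 = 0
    for chrom in layout.names:
        pos = layout.positions(chrom)
        hsub = hot[hot["chrom"] == chrom]
        if hsub.empty:
            continue
        in_hot = np.zeros(pos.size, dtype=bool)
        for h in hsub.itertuples(index=False):
            lo = np.searchsorted(pos, h.start, side="left")
            hi = np.searchsorted(pos, h.end, side="left")
            in_hot[lo:hi] = True
        methods_cover = np.zeros(pos.size, dtype=np.int64)
        for ivals in retained.values():
            cov = np.zeros(pos.size, dtype=bool)
            for r in ivals[ivals["chrom"] == chrom].itertuples(index=False):
                lo = np.searchsorted(pos, r.start, side="left")
                hi = np.searchsorted(pos, r.end, side="left")
                cov[lo:hi] = True
            methods_cover += cov
        n_snps += int(in_hot.sum())
        n_ge1 += int((methods_cover[in_hot] >= 1).sum())
        n_ge2 += int((methods_cover[in_hot] >= 2).sum())
    return {
        "group_id": hotspots.group_id,
        "per_hotspot": support,
        "n_hotspot_snps": n_snps,
        "pct_snps_ge1": 100.0 * n_ge1 / n_snps if n_snps else float("nan"),
        "pct_snps_ge2": 100.0 * n_ge2 / n_snps if n_snps else float("nan"),
    }
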