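"""Genomic inbreeding coefficients, heterozygosity, and rank correlations.

Four estimators are computed, all deterministic given the panel:

* ``F_ROH`` — fraction of the autosomal genome covered by ROH.
* ``F_HOM`` — excess-homozygosity method-of-moments estimator
  ``(O_hom - E_hom) / (m - E_hom)`` with the small-sample correction
  ``E_hom = sum_i (1 - 2 p_i (1 - p_i) n_i / (n_i - 1))`` (the PLINK
  ``--het`` statistic).
* ``F_GRM`` — variance-standardised genomic-relationship diagonal minus
  one: ``mean_i[(x - 2p)^2 / (2p(1-p)) - 1]``.
* ``F_UNI`` — correlation of uniting gametes:
  ``mean_i[(x^2 - (1+2p)x + 2p^2) / (2p(1-p))]``.

Allele frequencies are always estimated from the analysis panel itself,
as the reference tools do; cross-population frequency bias (negative
F_HOM / inflated F_GRM in admixed groups) is therefore a property of
the estimators, not removed by this implementation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    MISSING,
    GenomeLayout,
    GenotypeMatrix,
    ROHSegment,
    check_disjoint,
    interval_union_length,
)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation between two variables."""

    pair: tuple[str, str]
    rho: float
    p_value: float
    n: int


def f_roh(
    segments: list[ROHSegment],
    layout: GenomeLayout,
    samples: list[str] | None = None,
    per_class: bool = False,
) -> pd.DataFrame:
    """Per-individual genomic inbreeding from ROH coverage.

    ``F_ROH`` = total ROH bp / total autosome bp.  ``samples`` lists the
    individuals to report (those without segments get 0); defaults to
    the individuals present in ``segments``.  With ``per_class``,
    class-restricted numerators are added (requires class labels).
    """
    check_disjoint(segments)
    total = layout.total_length
    if samples is None:
        samples = sorted({s.sample_id for s in segments})
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in samples}
    for seg in segments:
        if seg.sample_id in by_sample:
            by_sample[seg.sample_id].append(seg)
    rows = []
    for sid in samples:
        segs = by_sample[sid]
        row = {"sample_id": sid, "f_roh": sum(s.length_bp for s in segs) / total}
        if per_class:
            for cls in ("short", "medium", "long"):
                row[f"f_roh_{cls}"] = sum(
                    s.length_bp for s in segs if s.class_label == cls
                ) / total
        rows.append(row)
    return pd.DataFrame(rows)


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site non-missing allele count n_i and alt-allele frequency p_i."""
    obs = calls != MISSING
    n = 2 * obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return n.astype(np.int64), p


def f_hom(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Excess-homozygosity inbreeding (method of moments) per individual.

    Sites with fewer than 2 non-missing alleles are excluded.  An
    individual whose usable site count m equals E_hom is flagged
    (``f_hom`` NaN) rather than divided by zero.
    """
    calls = genotypes.calls
    n, p = _allele_counts(calls)
    usable = n >= 2
    # expected per-site hom probability with the n/(n-1) correction
    e_site = 1.0 - 2.0 * p * (1.0 - p) * (n / np.maximum(n - 1, 1))
    rows = []
    for i, (sid, _) in enumerate(genotypes.samples):
        row = calls[i]
        inc = usable & (row != MISSING)
        m = int(inc.sum())
        o_hom = int(((row == 0) | (row == 2))[inc].sum())
        e_hom = float(e_site[inc].sum())
        denom = m - e_hom
        val = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else float("nan")
        rows.append({"sample_id": sid, "f_hom": val, "o_hom": o_hom,
                     "e_hom": e_hom, "n_sites": m})
    return pd.DataFrame(rows)


def f_grm_uni(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """GRM-diagonal and uniting-gametes inbreeding per individual.

    Sites monomorphic in the panel (p in {0, 1}) are excluded from both
    estimators; an individual with no included non-missing sites gets
    NaN for both.
    """
    calls = genotypes.calls
    n, p = _allele_counts(calls)
    poly = (n >= 2) & (p > 0) & (p < 1)
    het_var = 2.0 * p * (1.0 - p)
    rows = []
    for i, (sid, _) in enumerate(genotypes.samples):
        row = calls[i].astype(float)
        inc = poly & (calls[i] != MISSING)
        m = int(inc.sum())
        if m == 0:
            rows.append({"sample_id": sid, "f_grm": float("nan"),
                         "f_uni": float("nan"), "n_sites": 0})
            continue
        x = row[inc]
        pi = p[inc]
        hv = het_var[inc]
        grm = ((x - 2 * pi) ** 2 / hv - 1.0).mean()
        uni = ((x ** 2 - (1 + 2 * pi) * x + 2 * pi ** 2) / hv).mean()
        rows.append({"sample_id": sid, "f_grm": float(grm),
                     "f_uni": float(uni), "n_sites": m})
    return pd.DataFrame(rows)


def heterozygosity(
    genotypes: GenotypeMatrix,
    groups: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed heterozygosity per individual; expected per group.

    Ho = het calls / non-missing calls for the individual.  He per group
    = mean over SNPs of ``2 p (1 - p)`` with p estimated from that
    group's non-missing alleles (sites with no data in the group are
    skipped).  A fully monomorphic group validly has He = 0.
    """
    groups = groups or genotypes.groups
    calls = genotypes.calls
    rows = []
    for i, (sid, gid) in enumerate(genotypes.samples):
        row = calls[i]
        nm = int((row != MISSING).sum())
        het = int((row == 1).sum())
        rows.append({"sample_id": sid, "group_id": gid,
                     "ho": het / nm if nm else float("nan"), "n_nonmissing": nm})
    ho = pd.DataFrame(rows)
    idx = {s: i for i, (s, _) in enumerate(genotypes.samples)}
    grows = []
    for gid, members in groups.items():
        sub = calls[[idx[s] for s in members]]
        n, p = _allele_counts(sub)
        ok = n >= 1
        he = float((2 * p[ok] * (1 - p[ok])).mean()) if ok.any() else float("nan")
        mean_ho = float(ho[ho["sample_id"].isin(members)]["ho"].mean())
        grows.append({"group_id": gid, "he": he, "mean_ho": mean_ho,
                      "n_individuals": len(members)})
    return ho, pd.DataFrame(grows)


def spearman(x, y, labels: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with t-approximation p-value.

    Pairs with a missing value on either side are dropped
    (pairwise-complete).  Zero rank variance yields NaN rho/p (flagged
    as undefined rather than raising).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(labels, float("nan"), float("nan"), int(x.size))
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(labels, float(rho), float(p), int(x.size))


def correlation_matrix(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """All pairwise Spearman correlations among the named columns."""
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r = spearman(table[a], table[b], labels=(a, b))
            rows.append({"var_a": a, "var_b": b, "rho": r.rho,
                         "p_value": r.p_value, "n": r.n})
    return pd.DataFrame(rows)
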