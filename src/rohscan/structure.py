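"""ROH presence/absence matrices and principal component analysis.

Population structure can be read off shared homozygous segments alone:
segments are recoded into a binary individuals x regions matrix and
decomposed by PCA.  Regions are the *atomic partition* of the union of
all in-scope segments — the genome is cut at every distinct segment
start and end — so "presence" (full coverage of a region) is
unambiguous: a segment either covers an atomic region entirely or not
at all.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ROHSegment


@dataclass
class BinaryROHMatrix:
    """Individuals x atomic regions presence/absence matrix."""

    individuals: list[str]
    regions: pd.DataFrame          # chrom, start, end (0-based half-open)
    entries: np.ndarray            # uint8 (n_individuals, n_regions)
    class_scope: str = "total"
    constant_columns: np.ndarray | None = None  # flags columns equal across rows


@dataclass
class PCAResult:
    """Top-k principal component scores of a binary ROH matrix."""

    scores: np.ndarray             # (n_individuals, k)
    explained_variance_fractions: np.ndarray
    k: int
    individuals: list[str]


def _atomic_regions(segs: list[ROHSegment]) -> pd.DataFrame:
    rows = []
    by_chrom: dict[str, list[ROHSegment]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        cuts = np.unique(
            np.concatenate([[s.start for s in by_chrom[chrom]],
                            [s.end for s in by_chrom[chrom]]])
        )
        starts, ends = cuts[:-1], cuts[1:]
        covered = np.zeros(starts.size, dtype=bool)
        for s in by_chrom[chrom]:
            lo = np.searchsorted(starts, s.start, side="left")
            hi = np.searchsorted(ends, s.end, side="right")
            covered[lo:hi] = True
        for st, en in zip(starts[covered], ends[covered]):
            rows.append({"chrom": chrom, "start": int(st), "end": int(en)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def build_binary_matrix(
    segments: list[ROHSegment],
    individuals: list[str] | None = None,
    class_scope: str = "total",
) -> BinaryROHMatrix:
    """Recode segments into the atomic-partition presence/absence matrix.

    ``class_scope`` restricts to one length class (requires labels) or
    ``"total"``.  ``individuals`` fixes row order and may include
    ROH-free individuals; defaults to the individuals present in scope.
    An entry is 1 iff that individual has an in-scope segment fully
    covering the region (equivalently, overlapping it, since regions
    are atomic).  Columns identical across all individuals are flagged
    in ``constant_columns`` but retained.
    """
    if class_scope != "total":
        segs = [s for s in segments if s.class_label == class_scope]
    else:
        segs = list(segments)
    if not segs:
        warnings.warn(f"no segments in scope {class_scope!r}; empty matrix",
                      RuntimeWarning)
        return BinaryROHMatrix(
            individuals=list(individuals or []),
            regions=pd.DataFrame(columns=["chrom", "start", "end"]),
            entries=np.zeros((len(individuals or []), 0), dtype=np.uint8),
            class_scope=class_scope,
            constant_columns=np.zeros(0, dtype=bool),
        )
    if individuals is None:
        individuals = sorted({s.sample_id for s in segs})
    regions = _atomic_regions(segs)
    idx = {s: i for i, s in enumerate(individuals)}
    entries = np.zeros((len(individuals), len(regions)), dtype=np.uint8)
    # region lookup per chromosome
    for chrom, sub in regions.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        base = sub.index.to_numpy()
        for s in segs:
            if s.chrom != chrom or s.sample_id not in idx:
                continue
            lo = np.searchsorted(starts, s.start, side="left")
            hi = np.searchsorted(ends, s.end, side="right")
            entries[idx[s.sample_id], base[lo:hi]] = 1
    const = np.all(entries == entries[0:1, :], axis=0) if len(individuals) else \
        np.zeros(len(regions), dtype=bool)
    return BinaryROHMatrix(individuals=list(individuals), regions=regions,
                           entries=entries, class_scope=class_scope,
                           constant_columns=const)


def pca_binary(matrix: BinaryROHMatrix, k: int = 10) -> PCAResult:
    """Centering-only PCA of the presence/absence matrix.

    Columns are mean-centred but not variance-scaled (entries are
    indicators, not allele counts, so eigensoft-style p(1-p) scaling
    has no meaning here).  Component signs are fixed so the
    largest-magnitude loading of each component is positive.  ``k`` is
    truncated to ``min(n_individuals - 1, n_regions)`` with a warning.
    """
    n, m = matrix.entries.shape
    if n < 2 or m < 1:
        raise ValueError("PCA needs >= 2 individuals and >= 1 region")
    kmax = min(n - 1, m)
    if k > kmax:
        warnings.warn(f"k={k} truncated to {kmax}", RuntimeWarning)
        k = kmax
    x = matrix.entries.astype(float)
    x -= x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: the first entry attaining the largest |loading|
    # (within round-off) is made positive
    for j in range(min(s.size, k)):
        a = np.abs(vt[j])
        i = int(np.flatnonzero(a >= a.max() * (1 - 1e-9))[0])
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    total = float((s ** 2).sum())
    evr = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return PCAResult(scores=scores, explained_variance_fractions=evr, k=k,
                     individuals=list(matrix.individuals))


def export_structure_inputs(matrix: BinaryROHMatrix, out_dir) -> dict[str, str]:
    """Write a transposed pseudo-genotype coding for external tools.

    Produces ``markers.tsv`` — one row per atomic region, one column per
    individual, 0/1 haploid-like codes — and ``regions.tsv`` mapping
    marker rows to genomic intervals.  Returns the file paths.
    """
    if matrix.entries.size == 0:
        raise ValueError("cannot export an empty matrix")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    markers = pd.DataFrame(matrix.entries.T, columns=matrix.individuals)
    markers.insert(0, "marker", [f"R{i}" for i in range(len(matrix.regions))])
    mpath = out / "markers.tsv"
    markers.to_csv(mpath, sep="\t", index=False)
    regions = matrix.regions.copy()
    regions.insert(0, "marker", [f"R{i}" for i in range(len(regions))])
    rpath = out / "regions.tsv"
    regions.to_csv(rpath, sep="\t", index=False)
    return {"markers": str(mpath), "regions": str(rpath)}


def read_structure_inputs(out_dir) -> BinaryROHMatrix:
    """Round-trip reader for :func:`export_structure_inputs` files."""
    out = Path(out_dir)
    markers = pd.read_csv(out / "markers.tsv", sep="\t")
    regions = pd.read_csv(out / "regions.tsv", sep="\t")
    individuals = [c for c in markers.columns if c != "marker"]
    entries = markers[individuals].to_numpy(dtype=np.uint8).T
    return BinaryROHMatrix(
        individuals=individuals,
        regions=regions[["chrom", "start", "end"]].astype(
            {"start": int, "end": int}),
        entries=entries,
    )
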