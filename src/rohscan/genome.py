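"""Core containers: genome layout, genotype matrix, ROH segments.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open ``[start, end)``.  SNP
positions are stored 0-based; conversion to the 1-based inclusive
conventions of VCF and PLINK ``.hom`` files happens only in the readers
and writers (:mod:`rohscan.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: genotype codes: 0 = hom-ref, 1 = het, 2 = hom-alt, MISSING = no call.
MISSING: int = -1

CLASS_LABELS = ("short", "medium", "long")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered autosomes with their SNP maps.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs; names must be unique.
    snp_positions
        Per-chromosome strictly increasing 0-based positions, each in
        ``[0, length_bp)``.
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        pos = {}
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            p = np.asarray(self.snp_positions.get(name, ()), dtype=np.int64)
            if p.size and (np.any(np.diff(p) <= 0)):
                raise ValueError(f"positions on {name!r} not strictly increasing")
            if p.size and (p[0] < 0 or p[-1] >= length):
                raise ValueError(f"positions on {name!r} outside [0, {length})")
            pos[name] = p
        extra = set(self.snp_positions) - set(names)
        if extra:
            raise ValueError(f"positions given for unknown chromosomes: {sorted(extra)}")
        object.__setattr__(self, "snp_positions", pos)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: l for n, l in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @property
    def n_snps(self) -> int:
        return sum(p.size for p in self.snp_positions.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self.snp_positions[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        """Column slice of this chromosome's sites in a genotype matrix."""
        off = 0
        for name, _ in self.chromosomes:
            n = self.snp_positions[name].size
            if name == chrom:
                return slice(off, off + n)
            off += n
        raise KeyError(chrom)


@dataclass
class GenotypeMatrix:
    """Individuals x ordered SNP sites, coded 0/1/2 with MISSING = -1.

    ``samples`` is an ordered list of ``(sample_id, group_id)``; columns
    follow the layout's chromosome order, then position.
    """

    layout: GenomeLayout
    samples: list[tuple[str, str]]
    calls: np.ndarray  # int8, shape (n_individuals, n_sites)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D")
        if self.calls.shape != (len(self.samples), self.layout.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {self.layout.n_snps} sites"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {0,1,2,MISSING}")
        self.samples = [(str(s), str(g)) for s, g in self.samples]

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.samples:
            out.setdefault(g, []).append(s)
        return out

    def sample_index(self, sample_id: str) -> int:
        for i, (s, _) in enumerate(self.samples):
            if s == sample_id:
                return i
        raise KeyError(sample_id)

    def chrom_calls(self, chrom: str) -> np.ndarray:
        return self.calls[:, self.layout.chrom_slice(chrom)]


@dataclass
class ROHSegment:
    """One homozygous run of one individual (0-based half-open bp span)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int = 0
    n_missing: int = 0
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end {self.end} <= start {self.start}")
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


SEGMENT_COLUMNS = [
    "sample_id", "chrom", "start", "end",
    "n_snps", "n_het", "n_missing", "length_bp", "class_label",
]


def segments_to_frame(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    """Tabulate segments (one row each; empty input gives the empty table)."""
    rows = [
        (s.sample_id, s.chrom, s.start, s.end, s.n_snps, s.n_het,
         s.n_missing, s.length_bp, s.class_label)
        for s in segments
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def frame_to_segments(df: pd.DataFrame) -> list[ROHSegment]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ROHSegment(
                sample_id=str(row.sample_id), chrom=str(row.chrom),
                start=int(row.start), end=int(row.end), n_snps=int(row.n_snps),
                n_het=int(getattr(row, "n_het", 0) or 0),
                n_missing=int(getattr(row, "n_missing", 0) or 0),
                class_label=(None if pd.isna(getattr(row, "class_label", None))
                             else str(row.class_label)),
            )
        )
    return out


def check_disjoint(segments: Sequence[ROHSegment]) -> None:
    """Raise if any individual has overlapping segments on one chromosome."""
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append((s.start, s.end))
    for (sid, chrom), ivals in by_key.items():
        ivals.sort()
        for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping segments for {sid} on {chrom}: "
                    f"[{s0},{e0}) and [{s1},...)"
                )


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by the union of half-open intervals."""
    ivals = sorted(intervals)
    total = 0
    cur_s: int | None = None
    cur_e = 0
    for s, e in ivals:
        if cur_s is None or s > cur_e:
            if cur_s is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        total += cur_e - cur_s
    return total
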