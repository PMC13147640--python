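"""Synthetic genotype panels with planted autozygosity and known truth.

The generator emulates the statistical structure a WGS ROH analysis
sees: a multi-chromosome SNP map (Poisson-process spacing), Hardy-
Weinberg background genotypes at per-site allele frequencies, planted
autozygous tracts with a three-modal (short/medium/long) log-normal
length mixture, group-shared hotspot islands, genotyping error inside
tracts, genome-wide missingness, optional per-individual inbreeding
targets, and optional covariate-linked allele frequencies.  A
:class:`SimTruth` table records every planted feature so downstream
estimates can be scored against ground truth.

The generator does not model linkage disequilibrium or recombination;
short-ROH-from-LD phenomena are emulated only through planted short
tracts (see the methods note for what this does and does not validate).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    MISSING,
    GenomeLayout,
    GenotypeMatrix,
    interval_union_length,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TractClassModel:
    """Per-individual tract count law (Poisson) and length law (log-normal)."""

    mean_per_individual: float
    median_kb: float
    log_sd: float

    def sample_lengths_bp(self, k: int, rng: np.random.Generator) -> np.ndarray:
        kb = np.exp(rng.normal(np.log(self.median_kb), self.log_sd, size=k))
        return np.maximum((kb * 1000).round().astype(np.int64), 2)


@dataclass(frozen=True)
class HotspotSpec:
    """A group-shared autozygosity island.

    ``group`` restricts carriers to one group (None draws carriers from
    the whole panel); ``carrier_fraction`` applies to the eligible pool.
    """

    chrom: str
    start: int
    end: int
    carrier_fraction: float
    flank_bp: int = 100_000
    group: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must be in [0, 1]")
        if self.end <= self.start:
            raise ValueError("hotspot end must exceed start")


@dataclass(frozen=True)
class CovariateLink:
    """Logistic link from a group covariate to one SNP's allele frequency.

    Per-group alt-allele frequency at the chosen SNP is
    ``logistic(intercept + slope * covariate)``.
    """

    chrom: str
    snp_index: int                      # index into that chromosome's SNPs
    covariate: str
    intercept: float
    slope: float
    group_values: dict[str, float] = field(default_factory=dict)


# default tract mixture: medians ordered short < medium < long, the
# three-modal structure the length-class model is meant to recover
DEFAULT_TRACTS = {
    "short": TractClassModel(mean_per_individual=4.0, median_kb=600.0, log_sd=0.10),
    "medium": TractClassModel(mean_per_individual=3.0, median_kb=1200.0, log_sd=0.125),
    "long": TractClassModel(mean_per_individual=1.5, median_kb=3000.0, log_sd=0.20),
}


@dataclass(frozen=True)
class SimConfig:
    """Complete description of a synthetic panel to generate."""

    seed: int = 0
    n_individuals: dict[str, int] = field(default_factory=lambda: {"pop1": 20})
    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    mean_spacing_bp: int = 10_000
    freq_range: tuple[float, float] = (0.05, 0.5)
    tract_models: dict[str, TractClassModel] = field(
        default_factory=lambda: dict(DEFAULT_TRACTS))
    het_error_rate: float = 0.001
    missing_rate: float = 0.001
    hotspots: tuple[HotspotSpec, ...] = ()
    inbreeding_targets: dict[str, float] | None = None
    covariate_links: tuple[CovariateLink, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.het_error_rate <= 1 and 0 <= self.missing_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.freq_range[0] > self.freq_range[1] or self.freq_range[0] < 0 \
                or self.freq_range[1] > 1:
            raise ValueError("invalid allele-frequency range")
        medians = [self.tract_models[c].median_kb
                   for c in ("short", "medium", "long") if c in self.tract_models]
        if medians != sorted(medians) or len(set(medians)) != len(medians):
            raise ValueError("class length medians must be ordered short < medium < long")


@dataclass
class SimTruth:
    """Ground truth for a simulated panel."""

    tracts: pd.DataFrame        # sample_id, chrom, start, end, class_label
    hotspot_regions: pd.DataFrame  # chrom, start, end, carrier_fraction, n_carriers
    fractions: pd.DataFrame     # sample_id, autozygous_fraction
    covariate_freqs: pd.DataFrame  # group_id, chrom, snp_index, covariate, value, freq


def _make_layout(cfg: SimConfig, rng: np.random.Generator) -> GenomeLayout:
    chroms = []
    positions = {}
    for c in range(cfg.n_chromosomes):
        name = f"chr{c + 1}"
        chroms.append((name, cfg.chrom_length_bp))
        n_target = int(cfg.chrom_length_bp / cfg.mean_spacing_bp * 1.3) + 10
        gaps = np.maximum(
            1, rng.exponential(cfg.mean_spacing_bp, size=n_target).round()
        ).astype(np.int64)
        pos = np.cumsum(gaps) - 1
        positions[name] = pos[pos < cfg.chrom_length_bp]
    return GenomeLayout(chromosomes=tuple(chroms), snp_positions=positions)


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a genotype panel plus its ground truth, deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    layout = _make_layout(config, rng)
    samples = [
        (f"{gid}_{i:03d}", gid)
        for gid, n in config.n_individuals.items()
        for i in range(n)
    ]
    n_ind = len(samples)
    m = layout.n_snps

    # per-site allele frequencies (columns follow layout order)
    freqs = rng.uniform(config.freq_range[0], config.freq_range[1], size=m)

    # covariate-linked SNPs: per-group frequency overrides
    cov_rows = []
    overrides: dict[tuple[str, int], float] = {}  # (group, column) -> freq
    for link in config.covariate_links:
        col = layout.chrom_slice(link.chrom).start + link.snp_index
        for gid, value in link.group_values.items():
            f = 1.0 / (1.0 + np.exp(-(link.intercept + link.slope * value)))
            overrides[(gid, col)] = f
            cov_rows.append({"group_id": gid, "chrom": link.chrom,
                             "snp_index": link.snp_index,
                             "covariate": link.covariate,
                             "value": value, "freq": f})

    # background genotypes at HWE: sum of two Bernoulli(p) alleles
    calls = np.empty((n_ind, m), dtype=np.int8)
    for i, (sid, gid) in enumerate(samples):
        p = freqs.copy()
        for (g, col), f in overrides.items():
            if g == gid:
                p[col] = f
        calls[i] = (rng.random(m) < p).astype(np.int8) + \
                   (rng.random(m) < p).astype(np.int8)

    # ---- plant autozygous tracts -------------------------------------
    chrom_names = layout.names
    tract_rows: list[dict] = []

    def plant(i: int, sid: str, chrom: str, start: int, length: int, cls: str):
        L = layout.lengths[chrom]
        if length > L:
            raise ValueError(f"tract of {length} bp longer than {chrom} ({L} bp)")
        start = int(min(max(start, 0), L - length))
        end = start + length
        pos = layout.positions(chrom)
        sl = layout.chrom_slice(chrom)
        lo = sl.start + np.searchsorted(pos, start, side="left")
        hi = sl.start + np.searchsorted(pos, end, side="left")
        if hi > lo:
            a = (rng.random(hi - lo) < freqs[lo:hi]).astype(np.int8)
            calls[i, lo:hi] = 2 * a
            if config.het_error_rate > 0:
                flip = rng.random(hi - lo) < config.het_error_rate
                calls[i, lo:hi][flip] = 1
        tract_rows.append({"sample_id": sid, "chrom": chrom,
                           "start": start, "end": end, "class_label": cls})

    for i, (sid, gid) in enumerate(samples):
        for cls, model in config.tract_models.items():
            k = rng.poisson(model.mean_per_individual)
            if k == 0:
                continue
            lens = np.minimum(model.sample_lengths_bp(k, rng),
                              config.chrom_length_bp)
            for ln in lens:
                chrom = chrom_names[rng.integers(0, len(chrom_names))]
                start = int(rng.integers(0, layout.lengths[chrom] - ln + 1))
                plant(i, sid, chrom, start, int(ln), cls)

    # inbreeding gradient: top up with medium tracts until the target
    # autozygous fraction is reached
    if config.inbreeding_targets:
        total_bp = layout.total_length
        model = config.tract_models.get("medium", DEFAULT_TRACTS["medium"])
        for i, (sid, gid) in enumerate(samples):
            target = config.inbreeding_targets.get(sid)
            if not target:
                continue
            def realized() -> float:
                per_chrom = {}
                for t in tract_rows:
                    if t["sample_id"] == sid:
                        per_chrom.setdefault(t["chrom"], []).append(
                            (t["start"], t["end"]))
                return sum(interval_union_length(v) for v in per_chrom.values()) / total_bp
            guard = 0
            while realized() < target and guard < 10_000:
                ln = int(min(model.sample_lengths_bp(1, rng)[0],
                             config.chrom_length_bp))
                chrom = chrom_names[rng.integers(0, len(chrom_names))]
                start = int(rng.integers(0, layout.lengths[chrom] - ln + 1))
                plant(i, sid, chrom, start, ln, "medium")
                guard += 1

    # hotspot islands: chosen carriers get a tract covering the interval
    hot_rows = []
    for spec in config.hotspots:
        if spec.chrom not in layout.lengths:
            raise ValueError(f"unknown hotspot chromosome {spec.chrom!r}")
        pool = np.array([
            i for i, (_, gid) in enumerate(samples)
            if spec.group is None or gid == spec.group
        ])
        n_carriers = round(spec.carrier_fraction * pool.size)
        if abs(n_carriers - spec.carrier_fraction * pool.size) > 1e-9:
            log.info("hotspot %s:[%d,%d): carrier_fraction x n rounded to %d",
                     spec.chrom, spec.start, spec.end, n_carriers)
        carriers = rng.choice(pool, size=n_carriers, replace=False)
        start = max(0, spec.start - spec.flank_bp)
        end = min(layout.lengths[spec.chrom], spec.end + spec.flank_bp)
        for i in carriers:
            plant(int(i), samples[int(i)][0], spec.chrom, start, end - start,
                  "medium")
        hot_rows.append({"chrom": spec.chrom, "start": spec.start,
                         "end": spec.end,
                         "carrier_fraction": spec.carrier_fraction,
                         "n_carriers": n_carriers})

    # genome-wide missingness, applied last so it also hits tracts
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    # ---- truth tables ------------------------------------------------
    tracts = pd.DataFrame(
        tract_rows, columns=["sample_id", "chrom", "start", "end", "class_label"]
    )
    frac_rows = []
    total_bp = layout.total_length
    for sid, _ in samples:
        sub = tracts[tracts["sample_id"] == sid]
        covered = sum(
            interval_union_length(
                zip(c["start"].tolist(), c["end"].tolist()))
            for _, c in sub.groupby("chrom")
        )
        frac_rows.append({"sample_id": sid,
                          "autozygous_fraction": covered / total_bp})
    truth = SimTruth(
        tracts=tracts,
        hotspot_regions=pd.DataFrame(
            hot_rows, columns=["chrom", "start", "end", "carrier_fraction",
                               "n_carriers"]),
        fractions=pd.DataFrame(frac_rows,
                               columns=["sample_id", "autozygous_fraction"]),
        covariate_freqs=pd.DataFrame(
            cov_rows, columns=["group_id", "chrom", "snp_index", "covariate",
                               "value", "freq"]),
    )
    gm = GenotypeMatrix(layout=layout, samples=samples, calls=calls)
    return gm, truth


def simulate_null_segments(
    layout: GenomeLayout,
    n_individuals: int,
    segments_per_individual: int,
    median_kb: float = 800.0,
    log_sd: float = 0.5,
    seed: int | None = 0,
    island: tuple[str, int, int, int] | None = None,
):
    """Segment-level simulation for hotspot-caller calibration studies.

    Each individual receives ``segments_per_individual`` runs with
    log-normal lengths placed uniformly at random on uniformly chosen
    chromosomes — exactly the placement model of the permutation null,
    so datasets drawn here are true null datasets for FWER estimation.
    ``island`` = ``(chrom, start, end, n_carriers)`` optionally plants a
    shared run spanning that interval in the first ``n_carriers``
    individuals (shuffled), for power studies.  Returns
    ``(segments, sample_ids)``.
    """
    from .genome import ROHSegment

    rng = np.random.default_rng(seed)
    names = layout.names
    lengths = layout.lengths
    segs = []
    sample_ids = [f"i{k:03d}" for k in range(n_individuals)]
    for sid in sample_ids:
        lens = np.exp(rng.normal(np.log(median_kb * 1000), log_sd,
                                 segments_per_individual)).astype(np.int64)
        for ln in lens:
            chrom = names[rng.integers(0, len(names))]
            ln = int(min(ln, lengths[chrom]))
            start = int(rng.integers(0, lengths[chrom] - ln + 1))
            segs.append(ROHSegment(sid, chrom, start, start + ln,
                                   n_snps=max(2, ln // 1000)))
    if island is not None:
        chrom, start, end, n_carriers = island
        carriers = rng.permutation(n_individuals)[:n_carriers]
        for k in carriers:
            segs.append(ROHSegment(sample_ids[int(k)], chrom, int(start),
                                   int(end), n_snps=max(2, (end - start) // 1000)))
    return segs, sample_ids


def truth_report(truth: SimTruth, out_dir) -> dict[str, str]:
    """Write the truth tables as TSVs keyed for joining with outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("tracts", truth.tracts),
                     ("hotspots", truth.hotspot_regions),
                     ("fractions", truth.fractions),
                     ("covariate_freqs", truth.covariate_freqs)):
        p = out / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    return paths
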