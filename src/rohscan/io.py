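"""Readers and writers: VCF, PLINK ``.hom``-style tables, BED, manifests.

External conventions are converted at the boundary only:

* VCF and ``.hom`` positions are 1-based inclusive; BED is 0-based
  half-open; everything internal is 0-based half-open.
* A ``.hom`` row ``POS1=100001 POS2=200000`` therefore becomes the
  internal interval ``[100000, 200000)`` and round-trips exactly.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    MISSING,
    GenomeLayout,
    GenotypeMatrix,
    ROHSegment,
    segments_to_frame,
)

log = logging.getLogger(__name__)

HOM_COLUMNS = ["FID", "IID", "CHR", "POS1", "POS2", "KB", "NSNP", "NHET", "NMISS", "CLASS"]


def read_vcf(
    path,
    sample_to_group: dict[str, str] | None = None,
    strict: bool = False,
    default_group: str = "all",
) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a genotype matrix.

    Non-SNP or multi-allelic records are skipped in lenient mode
    (default) or rejected in ``strict`` mode.  Duplicate positions on a
    chromosome keep the first record (logged).  Chromosome lengths come
    from ``##contig`` header lines when present, else the last SNP
    position + 1.  ``sample_to_group`` assigns group ids; every mapped
    sample must exist in the VCF.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    vcf_samples = list(vcf.samples)
    if sample_to_group:
        missing = sorted(set(sample_to_group) - set(vcf_samples))
        if missing:
            raise ValueError(f"samples in mapping absent from VCF: {missing}")
    header_lengths: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            body = line.split("<", 1)[-1].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in body.split(",") if "=" in kv)
            if "ID" in fields and "length" in fields:
                header_lengths[fields["ID"]] = int(fields["length"])

    chrom_order: list[str] = []
    positions: dict[str, list[int]] = {}
    columns: list[np.ndarray] = []
    gt_map = np.array([0, 1, MISSING, 2], dtype=np.int8)  # cyvcf2 gt_types
    n_dup = 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            if strict:
                raise ValueError(
                    f"non-biallelic-SNP record at {v.CHROM}:{v.POS} in strict mode"
                )
            continue
        chrom = v.CHROM
        pos0 = v.POS - 1
        if chrom not in positions:
            chrom_order.append(chrom)
            positions[chrom] = []
        if positions[chrom] and pos0 <= positions[chrom][-1]:
            if pos0 == positions[chrom][-1]:
                n_dup += 1
                continue  # first record wins
            raise ValueError(f"VCF not sorted at {chrom}:{v.POS}")
        positions[chrom].append(pos0)
        columns.append(gt_map[np.asarray(v.gt_types)])
    if n_dup:
        log.info("skipped %d duplicate-position records (first record wins)", n_dup)
    if not columns:
        raise ValueError(f"no biallelic SNPs found in {path}")
    chroms = tuple(
        (c, header_lengths.get(c, positions[c][-1] + 1)) for c in chrom_order
    )
    layout = GenomeLayout(
        chromosomes=chroms,
        snp_positions={c: np.array(p, dtype=np.int64) for c, p in positions.items()},
    )
    sample_to_group = sample_to_group or {}
    samples = [(s, sample_to_group.get(s, default_group)) for s in vcf_samples]
    calls = np.stack(columns, axis=1)
    return GenotypeMatrix(layout=layout, samples=samples, calls=calls)


def write_vcf(genotypes: GenotypeMatrix, path) -> str:
    """Write the matrix as an uncompressed VCF (synthetic REF/ALT A/G)."""
    path = Path(path)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in genotypes.layout.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.sample_ids) + "\n")
        col = 0
        for name, _ in genotypes.layout.chromosomes:
            for pos0 in genotypes.layout.positions(name):
                gts = "\t".join(gt_str[int(g)] for g in genotypes.calls[:, col])
                fh.write(f"{name}\t{pos0 + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
                col += 1
    return str(path)


def read_segments(
    path,
    dialect: str = "hom",
    layout: GenomeLayout | None = None,
) -> list[ROHSegment]:
    """Read ROH segments from a ``.hom``-style TSV or a BED file.

    ``hom`` rows carry 1-based inclusive POS1/POS2 and a SNP count;
    BED rows are 0-based half-open and have no SNP count, which is
    recomputed from ``layout`` when given (else 0).  Raises on
    ``end < start`` and, when a layout is supplied, on unknown
    chromosomes.
    """
    if dialect not in ("hom", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    segs: list[ROHSegment] = []
    if dialect == "hom":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        required = {"IID", "CHR", "POS1", "POS2"}
        if not required.issubset(df.columns):
            raise ValueError(f".hom file missing columns {required - set(df.columns)}")
        for r in df.itertuples(index=False):
            start, end = int(r.POS1) - 1, int(r.POS2)
            if end <= start:
                raise ValueError(f"segment end < start at {r.CHR}:{r.POS1}-{r.POS2}")
            chrom = str(r.CHR)
            _check_chrom(chrom, layout)
            nsnp = int(getattr(r, "NSNP", 0) or 0)
            if nsnp == 0 and layout is not None:
                nsnp = _count_snps(layout, chrom, start, end)
            cls = getattr(r, "CLASS", None)
            segs.append(ROHSegment(
                sample_id=str(r.IID), chrom=chrom, start=start, end=end,
                n_snps=nsnp,
                n_het=int(getattr(r, "NHET", 0) or 0),
                n_missing=int(getattr(r, "NMISS", 0) or 0),
                class_label=None if cls is None or pd.isna(cls) or cls == "."
                else str(cls),
            ))
        return segs
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"BED end <= start at {chrom}:{start}-{end}")
            _check_chrom(chrom, layout)
            sid = parts[3] if len(parts) > 3 else "unknown"
            nsnp = _count_snps(layout, chrom, start, end) if layout else 0
            segs.append(ROHSegment(sample_id=sid, chrom=chrom, start=start,
                                   end=end, n_snps=nsnp))
    return segs


def _check_chrom(chrom: str, layout: GenomeLayout | None) -> None:
    if layout is not None and chrom not in layout.lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")


def _count_snps(layout: GenomeLayout, chrom: str, start: int, end: int) -> int:
    pos = layout.positions(chrom)
    return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))


def write_segments(segments: list[ROHSegment], path, dialect: str = "hom") -> str:
    """Write segments in ``.hom`` (1-based inclusive) or BED dialect."""
    path = Path(path)
    if dialect == "hom":
        rows = []
        for s in segments:
            rows.append({
                "FID": s.sample_id, "IID": s.sample_id, "CHR": s.chrom,
                "POS1": s.start + 1, "POS2": s.end,
                "KB": round(s.length_bp / 1000.0, 3), "NSNP": s.n_snps,
                "NHET": s.n_het, "NMISS": s.n_missing,
                "CLASS": s.class_label or ".",
            })
        pd.DataFrame(rows, columns=HOM_COLUMNS).to_csv(path, sep="\t", index=False)
    elif dialect == "bed":
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\n")
            for s in segments:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.sample_id}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return str(path)


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> str:
    """Write an interval table as BED (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend" + ("\tname" if name_col else "") + "\n")
        for r in intervals.itertuples(index=False):
            line = f"{r.chrom}\t{int(r.start)}\t{int(r.end)}"
            if name_col:
                line += f"\t{getattr(r, name_col)}"
            fh.write(line + "\n")
    return str(path)


def write_outputs(results: dict, out_dir, config: dict | None = None,
                  seed: int | None = None) -> dict:
    """Write stage results plus a JSON manifest echoing config and seed.

    Recognised keys in ``results``: ``segments`` (list of ROHSegment),
    ``hotspots`` (HotspotResult), ``inbreeding`` / ``windows`` /
    ``burden`` (DataFrames).  Returns the manifest dict (also written
    to ``manifest.json``).  Reruns with identical inputs and seed yield
    byte-identical tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "config": config or {}, "files": {},
                      "stages": {}}
    t0 = time.perf_counter()
    if "segments" in results:
        manifest["files"]["segments"] = write_segments(
            results["segments"], out / "roh.hom")
    if "hotspots" in results:
        hr = results["hotspots"]
        manifest["files"]["hotspots_bed"] = write_bed(hr.hotspots, out / "hotspots.bed")
        tsv = out / "hotspots.tsv"
        tab = hr.hotspots.copy()
        tab["threshold_freq"] = hr.threshold_freq
        tab["alpha"] = hr.alpha
        tab.to_csv(tsv, sep="\t", index=False)
        manifest["files"]["hotspots_tsv"] = str(tsv)
        snp = out / "hotspot_snps.tsv"
        hr.snp_table.to_csv(snp, sep="\t", index=False)
        manifest["files"]["hotspot_snps"] = str(snp)
        manifest["stages"]["hotspots"] = {
            "threshold_freq": hr.threshold_freq, "alpha": hr.alpha,
            "n_hotspots": int(len(hr.hotspots)),
        }
    for key in ("inbreeding", "windows", "burden", "retained"):
        if key in results:
            p = out / f"{key}.tsv"
            results[key].to_csv(p, sep="\t", index=False)
            manifest["files"][key] = str(p)
    manifest["elapsed_s"] = round(time.perf_counter() - t0, 6)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["files"]["manifest"] = str(out / "manifest.json")
    log.info("wrote %d output files to %s", len(manifest["files"]), out)
    return manifest
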