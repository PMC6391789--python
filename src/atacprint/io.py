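"""File-format helpers: BED/narrowPeak intervals, FASTA genomes, track export."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .fragments import GenomicRegion


def read_bed(path: str) -> list[GenomicRegion]:
    """Read BED3+ / narrowPeak intervals (extra columns ignored)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append(GenomicRegion(chrom, int(start), int(end)))
    return regions


def read_summits(path: str) -> dict[str, list[int]]:
    """Summit positions per chromosome from a BED of 1 bp (or midpoint) intervals."""
    out: dict[str, list[int]] = {}
    for r in read_bed(path):
        out.setdefault(r.chrom, []).append((r.start + r.end) // 2)
    return out


def load_genome(path: str) -> Mapping[str, str]:
    """Load a FASTA into chromosome -> sequence (pyfaidx-backed)."""
    from pyfaidx import Fasta

    fasta = Fasta(path, as_raw=True, sequence_always_upper=True)
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_bedgraph(values: np.ndarray, region: GenomicRegion, path: str) -> None:
    """Write a per-base track as bedGraph, merging equal-value runs."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                fh.write(f"{region.chrom}\t{region.start + run_start}\t"
                         f"{region.start + i}\t{values[run_start]:.6g}\n")
                run_start = i


def write_bigwig(values: np.ndarray, region: GenomicRegion, chrom_length: int,
                 path: str) -> None:
    import pyBigWig

    bw = pyBigWig.open(path, "w")
    bw.addHeader([(region.chrom, chrom_length)])
    bw.addEntries(region.chrom, region.start, values=np.asarray(values, dtype=float),
                  span=1, step=1)
    bw.close()


def read_expression_table(path: str) -> dict[str, float]:
    """TSV of (TF, log2FC); a header line starting with 'tf' is skipped."""
    table = {}
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2 or parts[0].lower() in ("tf", "gene"):
                continue
            table[parts[0]] = float(parts[1])
    return table


def write_tsv(rows: Sequence[Mapping], path: str, columns: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
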