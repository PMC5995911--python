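"""Readers and writers for the plain-text formats the pipeline exchanges.

BED files are 0-based half-open.  All TSV tables written by the package
carry ``#``-prefixed header comment lines naming the coordinate convention
and, where relevant, the depth-normalization target, so outputs are
self-describing and diffable.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import GeneModel, IntervalSet

logger = logging.getLogger(__name__)

BED_CONVENTION = "coordinates: 0-based half-open (BED)"

_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into a frame with chrom/start/end (+name/score/strand)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype={0: str}
    )
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in df.columns]
    # a column is only writable if all earlier BED columns are present too
    keep: list[str] = []
    for c in ["chrom", "start", "end", "name", "score", "strand"]:
        if c in cols:
            keep.append(c)
        else:
            break
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df[keep].to_csv(fh, sep="\t", header=False, index=False)


def read_tss_table(path: str | Path) -> list[GeneModel]:
    """Read the TSS TSV dialect: gene_id, chrom, strand, tss."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene_id", "chrom", "strand", "tss"],
                     dtype={"chrom": str})
    if df["gene_id"].iloc[0] == "gene_id":  # tolerate an uncommented header row
        df = df.iloc[1:].reset_index(drop=True)
    df["tss"] = df["tss"].astype(np.int64)
    return [GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss))
            for r in df.itertuples(index=False)]


def write_tss_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {BED_CONVENTION}; tss is the 0-based TSS base\n")
        fh.write("# gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def read_gtf_tss(path: str | Path) -> list[GeneModel]:
    """Extract one TSS per gene from a GTF.

    GTF is 1-based inclusive: the TSS is ``start - 1`` for ``+`` features and
    ``end - 1`` for ``-`` features, converted to 0-based.  Transcript lines
    are preferred; the first record per gene wins and later ones are
    dropped (logged).
    """
    genes: dict[str, GeneModel] = {}
    n_dropped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("transcript", "gene", "mRNA"):
                continue
            m = _GTF_GENE_ID.search(f[8])
            if not m:
                continue
            gid, chrom, strand = m.group(1), f[0], f[6]
            start, end = int(f[3]), int(f[4])
            tss = start - 1 if strand == "+" else end - 1
            if gid in genes:
                n_dropped += 1
                continue
            genes[gid] = GeneModel(gid, chrom, strand, tss)
    if n_dropped:
        logger.info("read_gtf_tss: kept first TSS per gene, dropped %d extra "
                    "transcript records", n_dropped)
    return list(genes.values())


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "size"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


DE_COLUMNS = ["gene_id", "log2fc", "fdr", "baseline"]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV: gene_id, log2FC, FDR, baseline."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=DE_COLUMNS)
    if df["gene_id"].iloc[0] == "gene_id":
        df = df.iloc[1:].reset_index(drop=True)
    for c in ("log2fc", "fdr", "baseline"):
        df[c] = df[c].astype(float)
    bad = df[(df["fdr"] < 0) | (df["fdr"] > 1)]
    if len(bad):
        raise ValueError(f"FDR outside [0, 1] for genes {bad['gene_id'].tolist()[:5]}")
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# differential expression: gene_id, log2FC (KD vs control), "
                 "BH-adjusted FDR, baseline mean\n")
        fh.write("# " + "\t".join(DE_COLUMNS) + "\n")
        df[DE_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_signature(path: str | Path, name: str | None = None) -> set[str]:
    """Read a gene signature: one gene per line, or a single-row GMT line."""
    path = Path(path)
    genes: set[str] = set()
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) == 1 and "\t" in lines[0]:
        fields = lines[0].split("\t")  # GMT: name, description, genes...
        genes = set(fields[2:])
    else:
        for ln in lines:
            if "\t" in ln:  # multi-row GMT: take members of every row
                genes |= set(ln.split("\t")[2:])
            else:
                genes.add(ln)
    return genes


def write_intervals_bed(
    intervals: IntervalSet, path: str | Path, extra_header: str = ""
) -> None:
    header = BED_CONVENTION + (f"; {extra_header}" if extra_header else "")
    write_bed(intervals.df, path, header=header)
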