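"""Readers and writers for the plain-text formats the pipeline speaks.

Coordinate conventions: everything in memory is BED-style 0-based half-open.
GFF3 (1-based inclusive) is converted on read and on write. bedGraph values
are written with 4 decimal places. All writes are atomic (temp file + rename)
so an interrupted run never leaves a truncated artifact behind.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeBinning


class BedParseError(ValueError):
    """A malformed interval line, reported with its 1-based line number."""


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp_", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# chrom sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str) -> list[tuple[str, int]]:
    """Read a two-column (name, length_bp) TSV, as used by UCSC chrom.sizes."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["name", "length"], dtype={"name": str})
    out = []
    for _, row in df.iterrows():
        length = int(row["length"])
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {row['name']!r}")
        out.append((str(row["name"]), length))
    return out


def write_chrom_sizes(chromosomes: Sequence[tuple[str, int]], path: str) -> None:
    _atomic_write(path, "".join(f"{n}\t{l}\n" for n, l in chromosomes))


# ---------------------------------------------------------------------------
# BED intervals (reads)
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str) -> pd.DataFrame:
    """Read BED3/BED6 (plain or gzip) into a DataFrame.

    Returns columns ``chromosome, start, end`` plus ``score`` when a 5th BED
    column is present. Malformed lines raise :class:`BedParseError` carrying
    the offending 1-based line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chromosome", "start", "end"])
    if df.shape[1] < 3:
        raise BedParseError(f"{path}: expected at least 3 tab-separated columns")
    out = pd.DataFrame({"chromosome": df[0].astype(str)})
    for col, name in ((1, "start"), (2, "end")):
        try:
            out[name] = df[col].astype(np.int64)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise BedParseError(
                f"{path}, line {line}: non-integer {name} field {df[col][bad].iloc[0]!r}"
            ) from None
    if (out["start"] < 0).any():
        line = int(out.index[out["start"] < 0][0]) + 1
        raise BedParseError(f"{path}, line {line}: negative start coordinate")
    if (out["start"] >= out["end"]).any():
        line = int(out.index[out["start"] >= out["end"]][0]) + 1
        raise BedParseError(f"{path}, line {line}: interval start must be < end")
    if df.shape[1] >= 5:
        out["score"] = pd.to_numeric(df[4], errors="coerce")
    return out


def write_bed6(df: pd.DataFrame, path: str) -> None:
    """Write chromosome/start/end plus optional name/score/strand columns."""
    cols = pd.DataFrame({
        "chromosome": df["chromosome"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df.get("name", pd.Series(["."] * len(df))),
        "score": df.get("score", pd.Series(["."] * len(df))),
        "strand": df.get("strand", pd.Series(["."] * len(df))),
    })
    extra = [c for c in df.columns
             if c not in ("chromosome", "start", "end", "name", "score", "strand")]
    for c in extra:
        cols[c] = df[c].to_numpy()
    _atomic_write(path, cols.to_csv(sep="\t", header=False, index=False))


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def write_bedgraph(binning: GenomeBinning, values: np.ndarray, path: str,
                   *, decimals: int = 4, skip_masked: bool = False) -> None:
    """Write one value per bin as bedGraph (chrom, start, end, value)."""
    values = np.asarray(values)
    if values.shape != (binning.n_bins_total,):
        raise ValueError("values must have one entry per bin")
    rec = binning.bin_table()
    keep = ~rec.masked if skip_masked else np.ones(len(rec), dtype=bool)
    lines = []
    for i in np.flatnonzero(keep):
        v = values[i]
        if np.issubdtype(values.dtype, np.integer):
            sval = str(int(v))
        else:
            sval = "nan" if np.isnan(v) else f"{v:.{decimals}f}"
        lines.append(f"{rec.chromosome[i]}\t{rec.start[i]}\t{rec.end[i]}\t{sval}\n")
    _atomic_write(path, "".join(lines))


def read_bedgraph(path: str, binning: GenomeBinning) -> np.ndarray:
    """Read a bedGraph written on ``binning`` back into a per-bin array.

    Bins absent from the file (e.g. masked bins written with skip_masked)
    come back as NaN.
    """
    values = np.full(binning.n_bins_total, np.nan)
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chromosome", "start", "end", "value"],
                     dtype={"chromosome": str})
    for chrom, sub in df.groupby("chromosome", sort=False):
        if chrom not in binning.chromosome_names:
            raise ValueError(f"{path}: unknown chromosome {chrom!r}")
        local = sub["start"].to_numpy() // binning.bin_width_bp
        sl = binning.chrom_slice(chrom)
        n = sl.stop - sl.start
        if (local < 0).any() or (local >= n).any():
            raise ValueError(f"{path}: interval outside binned region of {chrom}")
        values[sl.start + local] = sub["value"].to_numpy(dtype=float)
    return values


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def write_gff3(genes: Iterable, path: str, *, source: str = "ori_induce") -> None:
    """Write GeneModel records as GFF3 ``gene`` features (1-based inclusive)."""
    lines = ["##gff-version 3\n"]
    for g in genes:
        attrs = f"ID={g.gene_id};biotype={g.biotype}"
        lines.append(
            f"{g.chromosome}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
        )
    _atomic_write(path, "".join(lines))


def read_gff3_genes(path: str) -> list:
    """Read ``gene`` features from GFF3 into GeneModel records.

    Coordinates are converted to 0-based half-open. The ``biotype`` attribute
    defaults to ``protein_coding`` when absent.
    """
    import pyranges as pr

    from .genes import GeneModel

    gr = pr.read_gff3(path)
    df = gr.df if hasattr(gr, "df") else gr
    df = df[df["Feature"] == "gene"]
    genes = []
    for i, row in enumerate(df.itertuples(index=False)):
        gene_id = getattr(row, "ID", None) or f"gene_{i:05d}"
        biotype = getattr(row, "biotype", None)
        if biotype is None or (isinstance(biotype, float) and np.isnan(biotype)):
            biotype = "protein_coding"
        genes.append(GeneModel(
            gene_id=str(gene_id),
            chromosome=str(row.Chromosome),
            start=int(row.Start),
            end=int(row.End),
            strand=str(row.Strand) if str(row.Strand) in ("+", "-") else ".",
            biotype=str(biotype),
        ))
    return genes


def read_bed_genes(path: str) -> list:
    """Read genes from BED6(+1) — name = gene id, optional 7th column biotype."""
    from .genes import GeneModel

    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    genes = []
    for i, row in df.iterrows():
        biotype = row[6] if df.shape[1] >= 7 else "protein_coding"
        genes.append(GeneModel(
            gene_id=str(row[3]) if df.shape[1] >= 4 else f"gene_{i:05d}",
            chromosome=str(row[0]),
            start=int(row[1]),
            end=int(row[2]),
            strand=str(row[5]) if df.shape[1] >= 6 else ".",
            biotype=str(biotype),
        ))
    return genes


def read_gene_annotation(path: str) -> list:
    """Dispatch on extension: .gff3/.gff → GFF3, otherwise BED."""
    if path.endswith((".gff3", ".gff", ".gff3.gz", ".gff.gz")):
        return read_gff3_genes(path)
    return read_bed_genes(path)


# ---------------------------------------------------------------------------
# generic TSV
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str, *, float_format: str = "%.6g") -> None:
    _atomic_write(path, df.to_csv(sep="\t", index=False, float_format=float_format))


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_text(text: str, path: str) -> None:
    _atomic_write(path, text)
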