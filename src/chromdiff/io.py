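"""Readers and writers for the plain-text genomics formats used throughout.

bedGraph is the canonical coverage format (``chrom start end value``,
0-based half-open); BED6 carries annotations, with comma-separated linked
gene IDs in the name field for enhancers. bigWig tracks are supported
read-only when pyBigWig is installed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet

log = logging.getLogger(__name__)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph file into a DataFrame (chrom, start, end, value).

    ``track``/``browser``/comment lines are skipped. Malformed records
    (non-numeric value, start >= end) raise ``ValueError``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((parts[0], start, end, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    """Write (chrom, start, end, value) rows as bedGraph.

    Values are formatted with ``repr`` so round-trips are lossless and
    byte-stable across runs."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            v = row.value
            vs = str(int(v)) if float(v).is_integer() else repr(float(v))
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{vs}\n")


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 into an IntervalSet (name column kept when present)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return IntervalSet.from_records(rows)


def write_bed(
    intervals: IntervalSet,
    path: str | Path,
    scores=None,
    strands=None,
) -> None:
    """Write an IntervalSet as BED6 (score 0 / strand "." by default)."""
    n = len(intervals)
    if scores is None:
        scores = np.zeros(n)
    if strands is None:
        strands = ["."] * n
    with open(path, "w") as fh:
        for (chrom, start, end, name), sc, st in zip(intervals, scores, strands):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{sc:.6g}\t{st}\n")


def read_gene_set(path: str | Path) -> set[str]:
    """Read a newline-delimited gene ID file."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene x sample count matrix; first column is the gene ID index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "replicate", "role"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_bigwig_values(path: str | Path, chrom: str, length: int) -> np.ndarray:
    """Per-base values for one chromosome of a bigWig track (NaN -> 0)."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("bigWig input requires pyBigWig") from exc
    bw = pyBigWig.open(str(path))
    try:
        if chrom not in bw.chroms():
            log.warning("chromosome %s absent from %s; zeros returned", chrom, path)
            return np.zeros(length)
        vals = np.asarray(bw.values(chrom, 0, length), dtype=float)
    finally:
        bw.close()
    return np.nan_to_num(vals, nan=0.0)
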