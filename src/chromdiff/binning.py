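"""Binned coverage processing: fixed-width genome bins, per-bin track
means, CPM normalization, IgG-control subtraction, denylist filtering,
per-sample z-scoring and rolling-mean smoothing.

The stages form a fixed pipeline ``raw -> cpm -> ctrl_subtracted -> zscore
-> smoothed``; each operation checks the stage of its input so the steps
cannot be applied out of order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .intervals import IntervalSet
from .synthetic import GenomeLayout

log = logging.getLogger(__name__)

STAGES = ("raw", "cpm", "ctrl_subtracted", "zscore", "smoothed")


class StageError(ValueError):
    """Raised when a pipeline operation is applied out of order."""


@dataclass
class BinMatrix:
    """Bins x samples value matrix at a given pipeline stage."""

    bins: IntervalSet
    values: np.ndarray
    samples: list[str]
    stage: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape != (len(self.bins), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.bins)} bins x {len(self.samples)} samples"
            )
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, got {self.stage!r}"
            )

    def column(self, sample: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample)]

    def select_samples(self, samples: list[str]) -> "BinMatrix":
        idx = [self.samples.index(s) for s in samples]
        return BinMatrix(self.bins, self.values[:, idx], list(samples), self.stage)

    def to_tsv(self, path: str | Path) -> None:
        df = self.bins.df[["chrom", "start", "end"]].copy()
        for j, s in enumerate(self.samples):
            df[s] = self.values[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str = "raw") -> "BinMatrix":
        df = pd.read_csv(path, sep="\t")
        bins = IntervalSet(df["chrom"], df["start"], df["end"])
        samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
        return cls(bins, df[samples].to_numpy(float), samples, stage)


def make_bins(layout: GenomeLayout, bin_size: int | None = None) -> IntervalSet:
    """Tile each chromosome with fixed-width bins; the terminal bin is
    truncated at the chromosome end."""
    bin_size = layout.bin_size if bin_size is None else bin_size
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    chroms, starts, ends = [], [], []
    for name, length in zip(layout.chrom_names, layout.chrom_lengths):
        edges = np.arange(0, length, bin_size, dtype=np.int64)
        chroms.extend([name] * len(edges))
        starts.extend(edges)
        ends.extend(np.minimum(edges + bin_size, length))
    return IntervalSet(chroms, starts, ends)


def read_coverage(path: str | Path, bins: IntervalSet,
                  layout: GenomeLayout | None = None) -> np.ndarray:
    """Per-bin mean coverage of one track (bedGraph or bigWig).

    The value of a bin is its total signal mass (value x covered bases,
    uncovered bases contributing 0) divided by the bin width. Records on
    chromosomes absent from the bins are skipped with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        return _read_coverage_bigwig(path, bins, layout)
    records = cio.read_bedgraph(path)
    return bin_means_from_records(records, bins)


def bin_means_from_records(records: pd.DataFrame, bins: IntervalSet) -> np.ndarray:
    """Distribute (chrom, start, end, value) records over bins as mass."""
    mass = np.zeros(len(bins))
    widths = bins.lengths
    known = set(bins.chrom_order())
    bin_index = {
        chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g.index.to_numpy())
        for chrom, g in bins.df.groupby("chrom", sort=False)
    }
    skipped: set[str] = set()
    for chrom, grp in records.groupby("chrom", sort=False):
        if chrom not in known:
            skipped.add(chrom)
            continue
        bstarts, bends, bidx = bin_index[chrom]
        rs = grp["start"].to_numpy(np.int64)
        re = grp["end"].to_numpy(np.int64)
        rv = grp["value"].to_numpy(float)
        # first / last bin touched by each record
        first = np.searchsorted(bends, rs, side="right")
        last = np.searchsorted(bstarts, re, side="left") - 1
        single = first == last
        # fast path: record within one bin
        ok = single & (first < len(bidx))
        if ok.any():
            ovl = (np.minimum(re[ok], bends[first[ok]])
                   - np.maximum(rs[ok], bstarts[first[ok]]))
            np.add.at(mass, bidx[first[ok]], rv[ok] * np.maximum(ovl, 0))
        # general path: record spans several bins
        for i in np.flatnonzero(~single):
            for b in range(first[i], min(last[i], len(bidx) - 1) + 1):
                ovl = min(re[i], bends[b]) - max(rs[i], bstarts[b])
                if ovl > 0:
                    mass[bidx[b]] += rv[i] * ovl
    if skipped:
        log.warning("skipped records on unknown chromosomes: %s", sorted(skipped))
    return mass / widths


def _read_coverage_bigwig(path, bins: IntervalSet, layout) -> np.ndarray:
    if layout is None:
        raise ValueError("bigWig input needs a GenomeLayout for chromosome sizes")
    out = np.zeros(len(bins))
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        vals = cio.read_bigwig_values(path, chrom, length)
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        sel = bins.df["chrom"] == chrom
        s = bins.df.loc[sel, "start"].to_numpy()
        e = bins.df.loc[sel, "end"].to_numpy()
        out[sel.to_numpy()] = (cum[e] - cum[s]) / (e - s)
    return out


def matrix_from_tracks(paths: dict[str, str | Path], bins: IntervalSet,
                       layout: GenomeLayout | None = None) -> BinMatrix:
    """Read several tracks into a raw-stage BinMatrix (one column each)."""
    samples = list(paths)
    values = np.column_stack(
        [read_coverage(paths[s], bins, layout) for s in samples]
    )
    return BinMatrix(bins, values, samples, "raw")


def cpm_normalize(m: BinMatrix) -> BinMatrix:
    """Counts-per-million scaling: each sample's bin values sum to 1e6."""
    m.require_stage("raw")
    totals = m.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if len(zero):
        bad = [m.samples[j] for j in zero]
        raise ValueError(f"samples with zero total signal: {bad}")
    return replace(m, values=m.values / totals * 1e6, stage="cpm")


def subtract_control(target: BinMatrix, control: BinMatrix,
                     pairing: dict[str, str] | None = None) -> BinMatrix:
    """Subtract the matched IgG/control column from each target sample.

    ``pairing`` maps target sample -> control sample; when omitted the
    control matrix must contain a single column which is shared by all
    targets. Negative values are preserved.
    """
    target.require_stage("cpm")
    control.require_stage("cpm")
    if not target.bins == control.bins:
        raise ValueError("target and control bins differ")
    if pairing is None:
        if len(control.samples) != 1:
            raise ValueError(
                "pairing required when the control matrix has several columns"
            )
        pairing = {s: control.samples[0] for s in target.samples}
    out = target.values.copy()
    for j, s in enumerate(target.samples):
        out[:, j] = out[:, j] - control.column(pairing[s])
    return replace(target, values=out, stage="ctrl_subtracted")


def pairing_from_sheet(sheet: pd.DataFrame) -> dict[str, str]:
    """Match each target sample to its condition's IgG track (or to a single
    shared IgG track when only one exists)."""
    igg = sheet[sheet["role"] == "igg_control"]
    targets = sheet[sheet["role"] == "target"]
    if len(igg) == 0:
        raise ValueError("sample sheet has no igg_control track")
    by_cond = {r.condition: r.sample_id for r in igg.itertuples(index=False)}
    shared = igg["sample_id"].iloc[0] if len(igg) == 1 else None
    out = {}
    for r in targets.itertuples(index=False):
        out[r.sample_id] = by_cond.get(r.condition, shared)
        if out[r.sample_id] is None:
            raise ValueError(f"no control track for condition {r.condition!r}")
    return out


def apply_denylist(m: BinMatrix, denylist: IntervalSet) -> BinMatrix:
    """Drop bins overlapping the denylist by >= 1 bp (any stage)."""
    if len(denylist) == 0:
        return m
    keep = ~m.bins.overlaps_any(denylist)
    bins = IntervalSet.from_dataframe(m.bins.df[keep].reset_index(drop=True))
    return replace(m, bins=bins, values=m.values[keep])


def zscore(m: BinMatrix) -> BinMatrix:
    """Per-sample z-transform over retained bins (sd with ddof=1).

    Accounts for differences in dynamic range between experiments before
    replicates are compared."""
    m.require_stage("ctrl_subtracted")
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd <= 0)
    if len(dead):
        bad = [m.samples[j] for j in dead]
        raise ValueError(f"zero-variance samples cannot be z-scored: {bad}")
    return replace(m, values=(m.values - mu) / sd, stage="zscore")


def smooth(m: BinMatrix, window: int = 10, centering: str = "left") -> BinMatrix:
    """Rolling centered mean of ``window`` bins within each chromosome.

    An even window cannot be symmetric: with ``centering="left"`` the window
    for bin ``i`` is bins ``[i - w//2, i + w - w//2 - 1]`` (5 left, self, 4
    right for w=10); ``"right"`` mirrors this. Windows are clipped at
    chromosome boundaries and the mean is taken over the available bins.
    """
    m.require_stage("zscore")
    if window < 1:
        raise ValueError("window must be >= 1")
    if centering not in ("left", "right"):
        raise ValueError("centering must be 'left' or 'right'")
    left = window // 2 if centering == "left" else window - window // 2 - 1
    right = window - left - 1
    out = np.empty_like(m.values)
    chrom = m.bins.chroms
    # chromosome runs (bins are ordered; denylist gaps stay within one run)
    boundaries = np.flatnonzero(
        np.concatenate([[True], chrom[1:] != chrom[:-1], [True]])
    )
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        block = m.values[a:b]
        csum = np.concatenate([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        n = b - a
        idx = np.arange(n)
        lo = np.maximum(idx - left, 0)
        hi = np.minimum(idx + right + 1, n)
        out[a:b] = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return replace(m, values=out, stage="smoothed")


def condition_mean_tracks(m: BinMatrix, sheet: pd.DataFrame,
                          outdir: str | Path) -> None:
    """Write one bedGraph of per-bin mean score per condition (targets only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    targets = sheet[sheet["role"] == "target"]
    for cond, grp in targets.groupby("condition", sort=False):
        cols = [m.samples.index(s) for s in grp["sample_id"] if s in m.samples]
        df = m.bins.df[["chrom", "start", "end"]].copy()
        df["value"] = m.values[:, cols].mean(axis=1)
        cio.write_bedgraph(df, outdir / f"{cond}_mean_{m.stage}.bedgraph")


def preprocess(
    raw_targets: BinMatrix,
    raw_controls: BinMatrix,
    denylist: IntervalSet,
    sheet: pd.DataFrame,
    window: int = 10,
) -> BinMatrix:
    """Full stage chain for target samples: denylist removal -> CPM ->
    IgG subtraction -> z-score -> smoothing.

    Denylisted bins are dropped before CPM so per-sample totals count
    mappable signal only (as when artifact regions are removed upstream)."""
    t = cpm_normalize(apply_denylist(raw_targets, denylist))
    c = cpm_normalize(apply_denylist(raw_controls, denylist))
    pairing = pairing_from_sheet(sheet)
    sub = subtract_control(t, c, {s: pairing[s] for s in t.samples})
    return smooth(zscore(sub), window=window)
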