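"""Differential-signal domain calling.

Per-bin two-sample t-tests across replicate smoothed scores, Benjamini-
Hochberg correction, merging of book-ended significant bins into domains,
and summary statistics (count, mean length, fraction of the mappable
workspace covered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import io as cio
from .binning import BinMatrix
from .intervals import IntervalSet

log = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12  # pooled-variance floor in smoothed-z units


def per_bin_test(
    m: BinMatrix,
    sheet: pd.DataFrame,
    contrast: tuple[str, str] = ("treated", "control"),
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per bin across replicates.

    ``contrast = (treated, control)`` names two conditions from the sample
    sheet; the mean difference is treated minus control. Student's
    (equal-variance) t is the default; ``equal_var=False`` gives Welch.
    Bins where both groups have (numerically) zero variance and equal means
    get t = 0, p = 1; otherwise the pooled variance is floored at 1e-12.

    Returns a DataFrame with columns mean_diff, t, p, p_adj, direction.
    """
    m.require_stage("smoothed", "zscore")
    cond_a, cond_b = contrast
    targets = sheet[sheet["role"] == "target"] if "role" in sheet.columns else sheet
    ga = [s for s in targets[targets["condition"] == cond_a]["sample_id"]
          if s in m.samples]
    gb = [s for s in targets[targets["condition"] == cond_b]["sample_id"]
          if s in m.samples]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition, got {len(ga)} {cond_a!r} "
            f"and {len(gb)} {cond_b!r}"
        )
    A = m.select_samples(ga).values
    B = m.select_samples(gb).values
    n1, n2 = A.shape[1], B.shape[1]
    mean_diff = A.mean(axis=1) - B.mean(axis=1)
    v1 = A.var(axis=1, ddof=1)
    v2 = B.var(axis=1, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(np.maximum(sp2, _VAR_FLOOR) * (1 / n1 + 1 / n2))
        df = np.full(len(mean_diff), n1 + n2 - 2, dtype=float)
    else:
        se = np.sqrt(np.maximum(v1 / n1 + v2 / n2, _VAR_FLOOR))
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    t = mean_diff / se
    degenerate = (np.maximum(v1, v2) <= _VAR_FLOOR) & (np.abs(mean_diff) <= 1e-12)
    t[degenerate] = 0.0
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
            "direction": np.where(mean_diff >= 0, "up", "down"),
        }
    )
    return out


def bh_adjust(pvals, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    ``method="bonferroni"`` is available for the conservative alternative.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


@dataclass
class DomainCallResult:
    """Per-bin statistics plus merged significant domains and a summary."""

    bin_stats: pd.DataFrame
    bins: IntervalSet
    domains: IntervalSet
    domain_min_padj: np.ndarray  # per-domain min adjusted p
    alpha: float
    direction: str
    summary: dict

    def write(self, outdir: str | Path, prefix: str = "domains") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        named = IntervalSet(
            self.domains.chroms,
            self.domains.starts,
            self.domains.ends,
            [f"domain_{i:05d}" for i in range(len(self.domains))],
        )
        with np.errstate(divide="ignore"):
            scores = -np.log10(np.maximum(self.domain_min_padj, 1e-300))
        cio.write_bed(named, outdir / f"{prefix}.bed", scores=scores)
        stats = self.bins.df[["chrom", "start", "end"]].copy()
        stats = pd.concat([stats, self.bin_stats.reset_index(drop=True)], axis=1)
        stats.to_csv(outdir / f"{prefix}_bin_stats.tsv", sep="\t", index=False)


def call_domains(
    stats: pd.DataFrame,
    bins: IntervalSet,
    alpha: float = 0.005,
    direction: str = "up",
) -> DomainCallResult:
    """Merge adjacent significant same-direction bins into domains.

    A bin is significant when its BH-adjusted p is below ``alpha`` and its
    mean difference has the requested sign. Book-ended significant bins
    (gap 0 bp) merge into one domain; a gap of any size separates domains.
    Domains are not re-tested after merging.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(stats) != len(bins):
        raise ValueError("stats not aligned to bins")
    sig = (stats["p_adj"].to_numpy() < alpha) & (
        stats["direction"].to_numpy() == direction
    )
    sig_idx = np.flatnonzero(sig)
    sig_bins = IntervalSet.from_dataframe(
        bins.df.iloc[sig_idx].reset_index(drop=True)
    )
    domains = sig_bins.merge(gap=0)
    # min adjusted p per merged domain
    padj = stats["p_adj"].to_numpy()
    min_padj = np.ones(len(domains))
    if len(domains):
        for k, (chrom, s, e, _) in enumerate(domains):
            inside = sig_idx[
                (sig_bins.chroms == chrom)
                & (sig_bins.starts >= s)
                & (sig_bins.ends <= e)
            ]
            min_padj[k] = padj[inside].min()
    return DomainCallResult(
        bin_stats=stats,
        bins=bins,
        domains=domains,
        domain_min_padj=min_padj,
        alpha=alpha,
        direction=direction,
        summary={},
    )


def summarize_domains(
    result: DomainCallResult, workspace: IntervalSet
) -> dict:
    """Count, mean length (bp) and workspace fraction of called domains.

    The mean length is None when no domain was called; the fraction is total
    domain bp over total workspace bp.
    """
    n = len(result.domains)
    total = result.domains.total_bp
    ws = workspace.total_bp
    summary = {
        "n_domains": int(n),
        "mean_length_bp": (total / n) if n else None,
        "total_bp": int(total),
        "genome_fraction": (total / ws) if ws else 0.0,
    }
    result.summary = summary
    return summary


def recovery_scores(
    called: IntervalSet, truth: IntervalSet
) -> dict[str, float | None]:
    """Sensitivity/precision of domain recovery at >= 1 bp overlap.

    Sensitivity = fraction of planted domains hit by a called domain;
    precision = fraction of called domains hitting a planted domain.
    Undefined rates (empty sets) are returned as None.
    """
    sens = (
        float(truth.overlaps_any(called).mean()) if len(truth) else None
    )
    prec = (
        float(called.overlaps_any(truth).mean()) if len(called) else None
    )
    return {"sensitivity": sens, "precision": prec}
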