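"""Genomic interval sets and arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` as in BED/bedGraph.
An :class:`IntervalSet` is an ordered collection of intervals with optional
names; it is the backbone for bins, called domains, annotation categories and
the permutation workspace.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_COLUMNS = ["chrom", "start", "end", "name"]


class IntervalSet:
    """An ordered set of genomic intervals.

    Parameters
    ----------
    chroms, starts, ends
        Parallel sequences of chromosome names and 0-based half-open
        coordinates.
    names
        Optional per-interval labels (e.g. comma-separated linked gene IDs
        for enhancers). Missing names are stored as ``"."``.

    Intervals are validated (``0 <= start < end``) but not automatically
    sorted or merged; call :meth:`sort` / :meth:`merge` where an operation
    requires it.
    """

    __slots__ = ("df",)

    def __init__(
        self,
        chroms: Sequence[str] = (),
        starts: Sequence[int] = (),
        ends: Sequence[int] = (),
        names: Sequence[str] | None = None,
    ) -> None:
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chroms, starts, ends must have equal length")
        if names is None:
            names = np.full(len(chroms), ".", dtype=object)
        else:
            names = np.asarray(names, dtype=object)
            if len(names) != len(chroms):
                raise ValueError("names length mismatch")
        if len(starts) and (starts < 0).any():
            raise ValueError("negative start coordinate")
        if len(starts) and (starts >= ends).any():
            bad = int(np.argmax(starts >= ends))
            raise ValueError(
                f"empty or inverted interval at row {bad}: "
                f"{chroms[bad]}:{starts[bad]}-{ends[bad]}"
            )
        self.df = pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": ends, "name": names}
        )

    # ------------------------------------------------------------------ #
    # construction helpers
    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IntervalSet":
        names = df["name"] if "name" in df.columns else None
        return cls(
            df["chrom"].to_numpy(),
            df["start"].to_numpy(),
            df["end"].to_numpy(),
            None if names is None else names.to_numpy(),
        )

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        """Build from ``(chrom, start, end[, name])`` tuples."""
        rows = list(records)
        if not rows:
            return cls()
        chroms = [r[0] for r in rows]
        starts = [r[1] for r in rows]
        ends = [r[2] for r in rows]
        names = [r[3] if len(r) > 3 else "." for r in rows]
        return cls(chroms, starts, ends, names)

    def copy(self) -> "IntervalSet":
        return IntervalSet.from_dataframe(self.df)

    # ------------------------------------------------------------------ #
    # basic properties
    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield (row.chrom, int(row.start), int(row.end), row.name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True)
        )

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, bp={self.total_bp})"

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def names(self) -> np.ndarray:
        return self.df["name"].to_numpy()

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum())

    def chrom_order(self) -> list[str]:
        """Chromosomes in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.df["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    # ------------------------------------------------------------------ #
    # core operations
    # ------------------------------------------------------------------ #
    def sort(self) -> "IntervalSet":
        """Return a copy sorted by (chrom, start, end); chrom lexicographic."""
        df = self.df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return IntervalSet.from_dataframe(df)

    def is_sorted(self) -> bool:
        df = self.df
        if len(df) < 2:
            return True
        c = df["chrom"].to_numpy()
        s = df["start"].to_numpy()
        e = df["end"].to_numpy()
        for i in range(1, len(df)):
            if c[i] < c[i - 1]:
                return False
            if c[i] == c[i - 1] and (
                s[i] < s[i - 1] or (s[i] == s[i - 1] and e[i] < e[i - 1])
            ):
                return False
        return True

    def merge(self, gap: int = 0) -> "IntervalSet":
        """Merge overlapping intervals; intervals whose gap is <= ``gap``
        are joined. ``gap=0`` merges book-ended intervals (end == next
        start), matching ``bedtools merge -d 0``. Names are dropped."""
        if len(self) == 0:
            return IntervalSet()
        s = self.sort()
        out_c: list[str] = []
        out_s: list[int] = []
        out_e: list[int] = []
        cur_c, cur_s, cur_e = None, 0, 0
        for c, st, en in zip(s.chroms, s.starts, s.ends):
            if cur_c is None:
                cur_c, cur_s, cur_e = c, st, en
            elif c == cur_c and st <= cur_e + gap:
                cur_e = max(cur_e, en)
            else:
                out_c.append(cur_c)
                out_s.append(cur_s)
                out_e.append(cur_e)
                cur_c, cur_s, cur_e = c, st, en
        out_c.append(cur_c)
        out_s.append(cur_s)
        out_e.append(cur_e)
        return IntervalSet(out_c, out_s, out_e)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Interval intersection (both sides merged first); names dropped."""
        a = self.merge()
        b = other.merge()
        out: list[tuple] = []
        b_by_chrom = {c: g for c, g in b.df.groupby("chrom", sort=False)}
        for chrom, ga in a.df.groupby("chrom", sort=False):
            gb = b_by_chrom.get(chrom)
            if gb is None:
                continue
            sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
            sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
            i = j = 0
            while i < len(sa) and j < len(sb):
                lo = max(sa[i], sb[j])
                hi = min(ea[i], eb[j])
                if lo < hi:
                    out.append((chrom, int(lo), int(hi)))
                if ea[i] < eb[j]:
                    i += 1
                else:
                    j += 1
        return IntervalSet.from_records(out)

    def intersect_bp(self, other: "IntervalSet") -> int:
        """Total base pairs shared with ``other``."""
        return self.intersect(other).total_bp

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Remove all bases of ``other`` from this set; names dropped."""
        a = self.merge()
        b = other.merge()
        out: list[tuple] = []
        b_by_chrom = {c: g for c, g in b.df.groupby("chrom", sort=False)}
        for chrom, ga in a.df.groupby("chrom", sort=False):
            gb = b_by_chrom.get(chrom)
            if gb is None:
                for _, r in ga.iterrows():
                    out.append((chrom, int(r["start"]), int(r["end"])))
                continue
            sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
            for _, r in ga.iterrows():
                lo, hi = int(r["start"]), int(r["end"])
                cursor = lo
                # b intervals overlapping [lo, hi)
                k0 = int(np.searchsorted(eb, lo, side="right"))
                for k in range(k0, len(sb)):
                    if sb[k] >= hi:
                        break
                    if sb[k] > cursor:
                        out.append((chrom, cursor, int(sb[k])))
                    cursor = max(cursor, int(eb[k]))
                if cursor < hi:
                    out.append((chrom, cursor, hi))
        return IntervalSet.from_records(out)

    def clip_to(self, workspace: "IntervalSet") -> "IntervalSet":
        """Clip to the workspace (= intersect; names dropped)."""
        return self.intersect(workspace)

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean mask: does each interval of *self* overlap ``other`` by
        >= 1 bp? Preserves self's order; ``other`` may be unsorted."""
        mask = np.zeros(len(self), dtype=bool)
        if len(self) == 0 or len(other) == 0:
            return mask
        b = other.merge()
        b_by_chrom = {c: g for c, g in b.df.groupby("chrom", sort=False)}
        for chrom, ga in self.df.groupby("chrom", sort=False):
            gb = b_by_chrom.get(chrom)
            if gb is None:
                continue
            sb = gb["start"].to_numpy()
            eb = gb["end"].to_numpy()
            sa = ga["start"].to_numpy()
            ea = ga["end"].to_numpy()
            # overlap iff some b with sb < ea and eb > sa
            idx = np.searchsorted(eb, sa, side="right")
            hit = (idx < len(sb)) & (sb[np.minimum(idx, len(sb) - 1)] < ea)
            mask[ga.index.to_numpy()] = hit
        return mask

    def restrict_chroms(self, chrom_names: Sequence[str]) -> "IntervalSet":
        keep = self.df["chrom"].isin(set(chrom_names))
        return IntervalSet.from_dataframe(self.df[keep].reset_index(drop=True))


def coverage_index(merged: IntervalSet, chrom_offsets: dict[str, int]):
    """Precompute a cumulative-coverage lookup for a merged interval set.

    Maps intervals into a single linear axis via per-chromosome offsets and
    returns ``(starts, ends, cum)`` where ``cum[i]`` is the total covered bp
    strictly before interval ``i``. Used by the enrichment sampler to score
    thousands of permuted placements without re-intersecting interval sets.
    """
    if len(merged) == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z
    off = np.array([chrom_offsets[c] for c in merged.chroms], dtype=np.int64)
    gs = merged.starts + off
    ge = merged.ends + off
    order = np.argsort(gs, kind="mergesort")
    gs, ge = gs[order], ge[order]
    lens = ge - gs
    cum = np.concatenate([[0], np.cumsum(lens)[:-1]])
    return gs, ge, cum


def covered_before(x: np.ndarray, gs, ge, cum) -> np.ndarray:
    """Total covered bp in the linear axis strictly below positions ``x``."""
    x = np.asarray(x, dtype=np.int64)
    if len(gs) == 0:
        return np.zeros_like(x)
    idx = np.searchsorted(gs, x, side="right") - 1
    idx_c = np.clip(idx, 0, len(gs) - 1)
    inside = np.clip(x - gs[idx_c], 0, ge[idx_c] - gs[idx_c])
    out = cum[idx_c] + inside
    out[idx < 0] = 0
    return out
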