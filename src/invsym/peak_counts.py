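"""Intersect element occurrences with ChIP peak intervals.

The central quantity is the absolute number of times each variant element
occurs inside the peaks of an experiment: every containment is counted, with
no per-peak deduplication and no preference for the least-variant element, so
a peak holding several elements contributes to each of them.  A separate
operation reproduces the older unique-assignment convention (each peak
labelled by its least-variant element).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .element_space import (
    ElementSchema,
    HalfSiteGroup,
    element_from_id,
    revcomp,
)


@dataclass(frozen=True)
class PeakSet:
    """Peak intervals (0-based half-open) with the experiment-level metadata
    used by the noise model: N (peak count) and L (nominal peak length)."""

    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        df = self.intervals
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"peak frame lacks columns: {sorted(missing)}")
        if (df["end"] <= df["start"]).any():
            raise ValueError("degenerate peak interval (end <= start)")
        object.__setattr__(self, "intervals", df.reset_index(drop=True))

    @property
    def n_peaks(self) -> int:
        return int(len(self.intervals))

    @property
    def peak_length(self) -> int:
        """Mean interval length, rounded half-up to the nearest nt."""
        mean = float((self.intervals["end"] - self.intervals["start"]).mean())
        return int(np.floor(mean + 0.5))

    @property
    def total_length(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def subsample(self, q: float, seed: int | None = None) -> "PeakSet":
        """Keep each peak independently with probability q."""
        rng = np.random.default_rng(seed)
        keep = rng.random(self.n_peaks) < q
        return PeakSet(self.intervals.loc[keep].reset_index(drop=True))


@dataclass
class CountTable:
    """Per-element occurrence counts within peaks, plus experiment metadata."""

    schema: ElementSchema
    counts: pd.Series  # element_id -> count
    n_peaks: int
    peak_length: int
    total_peak_length: int
    k_max: int

    def count_of(self, element_id: str) -> int:
        return int(self.counts.get(element_id, 0))

    def _k_of_ids(self) -> pd.Series:
        ks = [element_from_id(self.schema, e).k for e in self.counts.index]
        return pd.Series(ks, index=self.counts.index)

    def by_level(self) -> pd.Series:
        """Total count per variant level k (plain sum over the level's elements)."""
        out = self.counts.groupby(self._k_of_ids()).sum()
        return out.reindex(range(self.k_max + 1), fill_value=0).astype(np.int64)

    def by_position_combo(self) -> pd.Series:
        """Counts aggregated by (substituted-position combination, k)."""
        combos = [
            tuple(sorted(element_from_id(self.schema, e).positions))
            for e in self.counts.index
        ]
        frame = pd.DataFrame(
            {"combo": combos, "k": self._k_of_ids().values, "count": self.counts.values}
        )
        return frame.groupby(["combo", "k"])["count"].sum()

    def by_group_level(self, groups: Sequence[HalfSiteGroup]) -> pd.DataFrame:
        """Counts per half-site group and level.

        A level-k element contributes to every group whose varied positions
        cover its substituted positions, so low-k counts are shared between
        groups while each 5-nt (half-site) variant belongs to exactly one.
        Aggregates by position combination first: the group sum only depends
        on which positions are substituted.
        """
        combo_counts = self.by_position_combo()
        by_combo: dict[tuple[int, ...], tuple[int, int]] = {}
        for (combo, k), c in combo_counts.items():
            by_combo[tuple(combo)] = (int(k), int(c) + by_combo.get(tuple(combo), (0, 0))[1])
        out = np.zeros((len(groups), self.k_max + 1), dtype=np.int64)
        for gi, g in enumerate(groups):
            varied = g.varied
            for combo, (k, c) in by_combo.items():
                if k <= self.schema.n // 2 and set(combo) <= varied:
                    out[gi, k] += c
        return pd.DataFrame(
            out, index=[g.gid for g in groups], columns=range(self.k_max + 1)
        )


def _containment_counts(
    occ: pd.DataFrame, peaks: pd.DataFrame, mode: str
) -> np.ndarray:
    """Number of peaks containing (or overlapping) each occurrence."""
    result = np.zeros(len(occ), dtype=np.int64)
    peak_chroms = set(peaks["chrom"])
    for chrom, sub in occ.groupby("chrom", sort=False):
        if chrom not in peak_chroms:
            warnings.warn(
                f"occurrences on {chrom!r} have no matching peak sequence id; "
                "counted as zero"
            )
            continue
        p = peaks[peaks["chrom"] == chrom]
        starts = np.sort(p["start"].to_numpy())
        order = np.argsort(p["start"].to_numpy(), kind="stable")
        ends = p["end"].to_numpy()[order]
        lengths = ends - starts
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if mode == "overlap":
            # peaks with start < occ.end and end > occ.start
            n_start_lt = np.searchsorted(starts, e, side="left")
            ends_sorted = np.sort(ends)
            n_end_le = np.searchsorted(ends_sorted, s, side="right")
            result[occ.index.get_indexer(sub.index)] = n_start_lt - n_end_le
            continue
        if (lengths == lengths[0]).all():
            # uniform peak length: containment <=> start in [e - L, s]
            L = int(lengths[0])
            hi = np.searchsorted(starts, s, side="right")
            lo = np.searchsorted(starts, e - L, side="left")
            result[occ.index.get_indexer(sub.index)] = np.maximum(hi - lo, 0)
        else:
            Lmax = int(lengths.max())
            hi = np.searchsorted(starts, s, side="right")
            lo = np.searchsorted(starts, e - Lmax, side="left")
            idx = occ.index.get_indexer(sub.index)
            for j, (l, h, ee) in enumerate(zip(lo, hi, e)):
                result[idx[j]] = int((ends[l:h] >= ee).sum())
    return result


def _iter_containments(occ: pd.DataFrame, peaks: pd.DataFrame, mode: str):
    """Yield (peak index, element_id) for every containment/overlap."""
    for chrom, sub in occ.groupby("chrom", sort=False):
        mask = peaks["chrom"] == chrom
        if not mask.any():
            continue
        p = peaks[mask]
        starts = p["start"].to_numpy()
        ends = p["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts_sorted, ends_sorted = starts[order], ends[order]
        pidx = p.index.to_numpy()[order]
        Lmax = int((ends - starts).max())
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        lo = np.searchsorted(starts_sorted, e - Lmax - (e - s), side="left")
        hi = np.searchsorted(starts_sorted, e if mode == "overlap" else s, side="right" if mode == "contained" else "left")
        for row, l, h in zip(sub.itertuples(), lo, hi):
            for j in range(l, h):
                if mode == "contained":
                    ok = starts_sorted[j] <= row.start and ends_sorted[j] >= row.end
                else:
                    ok = starts_sorted[j] < row.end and ends_sorted[j] > row.start
                if ok:
                    yield int(pidx[j]), row.element_id


def count_in_peaks(
    occurrences: pd.DataFrame,
    peaks: PeakSet,
    schema: ElementSchema,
    k_max: int | None = None,
    mode: str = "contained",
    per_peak_presence: bool = False,
) -> CountTable:
    """Count element occurrences inside peaks.

    ``mode='contained'`` (default) counts an occurrence once per peak whose
    interval fully contains its footprint; ``mode='overlap'`` counts any
    overlap.  With ``per_peak_presence`` a peak contributes at most 1 to an
    element no matter how often the element recurs inside it.
    """
    if mode not in ("contained", "overlap"):
        raise ValueError("mode must be 'contained' or 'overlap'")
    occ = occurrences.reset_index(drop=True)
    if k_max is None:
        k_max = int(occ["k"].max()) if len(occ) else 0
    if per_peak_presence:
        pairs = set()
        for pi, eid in _iter_containments(occ, peaks.intervals, mode):
            pairs.add((pi, eid))
        counts = (
            pd.Series([e for _, e in pairs], dtype=object).value_counts().astype(np.int64)
            if pairs
            else pd.Series(dtype=np.int64)
        )
    else:
        n_containing = _containment_counts(occ, peaks.intervals, mode)
        counts = (
            pd.Series(n_containing, index=occ["element_id"])
            .groupby(level=0)
            .sum()
            .astype(np.int64)
        )
    counts = counts[counts > 0]
    counts.index.name = "element_id"
    return CountTable(
        schema=schema,
        counts=counts,
        n_peaks=peaks.n_peaks,
        peak_length=peaks.peak_length,
        total_peak_length=peaks.total_length,
        k_max=k_max,
    )


@dataclass
class UniqueAssignment:
    labels: pd.Series  # peak index -> element_id (or None)
    n_ties: int

    def level_histogram(self, schema: ElementSchema) -> pd.Series:
        ks = [
            element_from_id(schema, e).k for e in self.labels.dropna()
        ]
        return pd.Series(ks).value_counts().sort_index()


def assign_unique(
    peaks: PeakSet, occurrences: pd.DataFrame, mode: str = "contained"
) -> UniqueAssignment:
    """Label each peak by the least-variant element it contains.

    Ties between distinct minimum-k elements break deterministically:
    leftmost occurrence first, then lexicographic element id.  Peaks holding
    no occurrence get None.  The count of genuine ties (two distinct
    minimum-k elements in one peak) is reported for auditing.
    """
    occ = occurrences.sort_values(["k", "start", "element_id"]).reset_index(drop=True)
    pk = peaks.intervals
    best: dict[int, tuple] = {}
    ties = 0
    for chrom, sub in occ.groupby("chrom", sort=False):
        mask = pk["chrom"] == chrom
        if not mask.any():
            continue
        p = pk[mask]
        starts = p["start"].to_numpy()
        ends = p["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts_sorted = starts[order]
        ends_sorted = ends[order]
        pidx = p.index.to_numpy()[order]
        Lmax = int((ends - starts).max())
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        lo = np.searchsorted(starts_sorted, e - Lmax, side="left")
        hi = np.searchsorted(starts_sorted, s, side="right")
        for row, l, h in zip(sub.itertuples(), lo, hi):
            if mode == "contained":
                sel = np.nonzero(ends_sorted[l:h] >= row.end)[0] + l
            else:
                sel = np.arange(l, h)
            key = (row.k, row.start, row.element_id)
            for j in sel:
                pi = int(pidx[j])
                cur = best.get(pi)
                if cur is None or key < cur:
                    if cur is not None and key[0] == cur[0] and key[2] != cur[2]:
                        ties += 1
                    best[pi] = key
                elif key[0] == cur[0] and key[2] != cur[2]:
                    ties += 1
    labels = pd.Series(
        [best[i][2] if i in best else None for i in pk.index], index=pk.index
    )
    return UniqueAssignment(labels=labels, n_ties=ties)


# ---------------------------------------------------------------------------
# Degenerate-consensus (IUPAC) matching
# ---------------------------------------------------------------------------

def iupac_to_regex(pattern: str) -> str:
    parts = []
    for ch in pattern.upper():
        try:
            vals = ambiguous_dna_values[ch]
        except KeyError as err:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern") from err
        parts.append(ch if len(vals) == 1 else f"[{vals}]")
    return "".join(parts)


def iupac_match(peak_seqs: Iterable[str], pattern: str) -> float:
    """Fraction of peak sequences containing a window matching the degenerate
    pattern on either strand (forward sequence or its reverse complement)."""
    rx = re.compile(iupac_to_regex(pattern))
    seqs = list(peak_seqs)
    if not seqs:
        return 0.0
    hits = 0
    for s in seqs:
        s = s.upper()
        if rx.search(s) or rx.search(revcomp(s)):
            hits += 1
    return hits / len(seqs)
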