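"""Forward-strand scanning for variant elements and single-strand k-mer parity.

Everything here works on the sense strand only: the reverse complement of an
element is a different entry in the variant space, and the reverse complement
of a k-mer is a different k-mer.  Any inversion symmetry in the results is a
property of the sequence, never an artifact of double-strand counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .element_space import ElementSchema, VariantElement, iter_variants

# base codes: A=0 C=1 G=2 T=3; anything else (N, gaps) = 4
_CODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_SCAN_CHUNK = 2_000_000


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit base codes (int8), with 4 marking non-ACGT characters."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _primary_code(element: VariantElement) -> int:
    """Integer encoding of the n primary bases (2 bits each, spacer skipped)."""
    code = 0
    seq = element.realize()
    for off in element.schema.primary_offsets:
        code = code * 4 + int(_CODE_LUT[ord(seq[off])])
    return code


def build_element_index(schema: ElementSchema, k_max: int) -> dict[int, tuple[str, int]]:
    """Exact-lookup index: primary-base code -> (element_id, k) for all
    variants with k <= k_max."""
    index: dict[int, tuple[str, int]] = {}
    for k in range(k_max + 1):
        for e in iter_variants(schema, k):
            index[_primary_code(e)] = (e.element_id, k)
    return index


def scan_elements(
    seq: str,
    schema: ElementSchema,
    k_max: int,
    seq_id: str = "seq",
    element_index: dict[int, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """All forward-strand occurrences of 0..k_max-nt variant elements.

    A window is reported when its primary positions are within Hamming
    distance ``k_max`` of the consensus.  Windows with non-ACGT characters at
    either primary or spacer positions are skipped (the element location must
    be unambiguous).  Returns a BED-like frame with columns
    ``chrom, start, end, element_id, k`` (0-based half-open coordinates).
    """
    if not 0 <= k_max <= schema.n:
        raise ValueError(f"k_max must be in [0, {schema.n}]")
    codes = encode_sequence(seq)
    w = schema.footprint
    nwin = len(codes) - w + 1
    cols = {"chrom": [], "start": [], "element_id": [], "k": []}
    if nwin > 0:
        if element_index is None:
            element_index = build_element_index(schema, k_max)
        prim = np.array(schema.primary_offsets)
        spac = np.array(schema.spacer_offsets, dtype=np.intp)
        cons = np.array(
            [_CODE_LUT[ord(b)] for b in schema.half_site + revcomp_str(schema.half_site)],
            dtype=np.int8,
        )
        pow4 = (4 ** np.arange(schema.n - 1, -1, -1)).astype(np.int64)
        starts_all, ids_all, ks_all = [], [], []
        for lo in range(0, nwin, _SCAN_CHUNK):
            hi = min(lo + _SCAN_CHUNK, nwin)
            offs = np.arange(lo, hi)[:, None]
            mat = codes[offs + prim]  # (chunk, n)
            valid = (mat != 4).all(axis=1)
            if spac.size:
                valid &= (codes[offs + spac] != 4).all(axis=1)
            dist = (mat != cons).sum(axis=1)
            hit = valid & (dist <= k_max)
            if not hit.any():
                continue
            hit_codes = (mat[hit].astype(np.int64) * pow4).sum(axis=1)
            hit_starts = np.arange(lo, hi)[hit]
            for s, c in zip(hit_starts.tolist(), hit_codes.tolist()):
                eid, k = element_index[c]
                starts_all.append(s)
                ids_all.append(eid)
                ks_all.append(k)
        cols = {
            "chrom": [seq_id] * len(starts_all),
            "start": starts_all,
            "element_id": ids_all,
            "k": ks_all,
        }
    df = pd.DataFrame(cols, columns=["chrom", "start", "element_id", "k"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["start"] + w
    df["k"] = df["k"].astype(np.int64)
    return df[["chrom", "start", "end", "element_id", "k"]]


def scan_fasta_records(
    records: Mapping[str, str], schema: ElementSchema, k_max: int
) -> pd.DataFrame:
    """Scan each record independently; windows never cross record boundaries."""
    index = build_element_index(schema, k_max)
    frames = [
        scan_elements(seq, schema, k_max, seq_id=name, element_index=index)
        for name, seq in records.items()
    ]
    if not frames:
        return scan_elements("", schema, k_max)
    return pd.concat(frames, ignore_index=True)


def revcomp_str(seq: str) -> str:
    from .element_space import revcomp

    return revcomp(seq)


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerCountTable:
    """Forward-strand k-mer counts, stored sparsely.

    ``codes`` are the 2-bit-encoded k-mers actually observed (sorted,
    uint64), ``counts`` the matching occurrence counts; memory scales with
    distinct observed k-mers, never with 4^k.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    total_windows: int

    @property
    def n_present(self) -> int:
        return int(len(self.codes))

    @property
    def space_size(self) -> int:
        return 4**self.k

    def count_of(self, kmer: str) -> int:
        code = kmer_to_code(kmer)
        i = np.searchsorted(self.codes, code)
        if i < len(self.codes) and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.counts, index=[code_to_kmer(int(c), self.k) for c in self.codes]
        )


def kmer_to_code(kmer: str) -> int:
    code = 0
    for b in kmer.upper():
        v = int(_CODE_LUT[ord(b)])
        if v == 4:
            raise ValueError(f"non-ACGT base in k-mer: {kmer!r}")
        code = code * 4 + v
    return code


def code_to_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _record_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of every valid (ACGT-only) window of one record."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = (codes == 4).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    safe = np.where(codes == 4, 0, codes).astype(np.uint64)
    acc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        acc = (acc << np.uint64(2)) | safe[j : j + n]
    return acc[valid]


def count_kmers(seqs: str | Mapping[str, str] | Iterable[str], k: int) -> KmerCountTable:
    """Count every forward-strand k-mer window containing only A/C/G/T.

    Multiple sequences are counted independently; no window spans a record
    boundary (an N sentinel inside one string breaks windows the same way).
    """
    if not 1 <= k <= 32:
        raise ValueError("k must be in [1, 32] (2-bit encoder limit)")
    if isinstance(seqs, str):
        seqs = [seqs]
    elif isinstance(seqs, Mapping):
        seqs = list(seqs.values())
    parts = [_record_kmer_codes(encode_sequence(s), k) for s in seqs]
    allcodes = (
        np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    )
    codes, counts = np.unique(allcodes, return_counts=True)
    return KmerCountTable(k, codes, counts.astype(np.int64), int(len(allcodes)))


def merge_tables(tables: Iterable[KmerCountTable]) -> KmerCountTable:
    """Combine per-sequence tables into a whole-genome table."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to merge")
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("tables have mixed k")
    codes = np.concatenate([t.codes for t in tables])
    counts = np.concatenate([t.counts for t in tables])
    order = np.argsort(codes, kind="stable")
    codes, counts = codes[order], counts[order]
    uniq, start = np.unique(codes, return_index=True)
    summed = np.add.reduceat(counts, start)
    return KmerCountTable(k, uniq, summed, sum(t.total_windows for t in tables))


# ---------------------------------------------------------------------------
# Parity (reverse / complement / reverse-complement) comparisons
# ---------------------------------------------------------------------------

PARITY_OPS = ("reverse_complement", "reverse", "complement")


def _op_codes(codes: np.ndarray, k: int, operation: str) -> np.ndarray:
    mask = np.uint64(4**k - 1)
    if operation == "complement":
        return (~codes) & mask
    if operation in ("reverse", "reverse_complement"):
        src = codes if operation == "reverse" else (~codes) & mask
        out = np.zeros_like(src)
        tmp = src.copy()
        for _ in range(k):
            out = (out << np.uint64(2)) | (tmp & np.uint64(3))
            tmp >>= np.uint64(2)
        return out
    raise ValueError(f"unknown parity operation: {operation!r}")


@dataclass(frozen=True)
class ParityReport:
    """Least-squares comparison of the k-mer count vector c(s) with c(op(s))."""

    k: int
    operation: str
    correlation: float
    slope: float
    intercept: float
    n_present: int
    n_missing: int


def missing_count(table: KmerCountTable) -> tuple[int, int]:
    """(present, missing) k-mers out of the 4^k possibilities."""
    present = table.n_present
    return present, table.space_size - present


def parity_compare(
    table: KmerCountTable, operation: str = "reverse_complement", include_absent: bool = True
) -> ParityReport:
    """Pearson correlation, slope and intercept of c(op(s)) against c(s).

    With ``include_absent`` (default) the statistics run over all 4^k k-mers,
    absent ones counting 0 -- the convention under which the missing-element
    tallies are meaningful.  Otherwise only jointly-present pairs enter.
    Because op is a permutation of the k-mer space, the marginal moments of
    the two vectors are identical, which the computation exploits; sums are
    exact integers so a perfectly mirrored input yields correlation exactly
    1.0, slope 1.0, intercept 0.0.
    """
    if table.k < 1:
        raise ValueError("degenerate k-mer space")
    if operation not in PARITY_OPS:
        raise ValueError(f"operation must be one of {PARITY_OPS}")
    counts = table.counts
    op_codes = _op_codes(table.codes, table.k, operation)
    # join: y[i] = count of op(codes[i]), via binary search in the sorted codes
    pos = np.searchsorted(table.codes, op_codes)
    pos_clip = np.minimum(pos, len(table.codes) - 1) if len(table.codes) else pos
    found = (
        (table.codes[pos_clip] == op_codes) if len(table.codes) else np.zeros(0, bool)
    )
    y = np.where(found, counts[pos_clip], 0)

    present, absent = missing_count(table)
    if include_absent:
        n = table.space_size
        x_for_xy = counts
        sx = int(counts.sum())
        sxx = int(np.dot(counts, counts))
        sxy = int(np.dot(counts, y))
        sy, syy = sx, sxx  # op is a permutation of the full space
    else:
        sel = found
        n = int(sel.sum())
        if n < 2:
            raise ValueError("fewer than two jointly-present pairs")
        xs, ys = counts[sel], y[sel]
        sx, sy = int(xs.sum()), int(ys.sum())
        sxx, syy = int(np.dot(xs, xs)), int(np.dot(ys, ys))
        sxy = int(np.dot(xs, ys))

    num = n * sxy - sx * sy
    den_x = n * sxx - sx * sx
    den_y = n * syy - sy * sy
    if den_x == 0 or den_y == 0:
        raise ValueError("count vector has zero variance")
    if num == den_x and den_x == den_y:  # exact mirror: avoid float round-off
        corr, slope = 1.0, 1.0
    else:
        corr = num / math.sqrt(den_x) / math.sqrt(den_y)
        slope = num / den_x
    intercept = (sy - slope * sx) / n
    return ParityReport(
        table.k, operation, float(corr), float(slope), float(intercept), present, absent
    )


def parity_table(table: KmerCountTable, include_absent: bool = True) -> pd.DataFrame:
    """All three parity comparisons as one tidy frame."""
    rows = [
        parity_compare(table, op, include_absent=include_absent).__dict__
        for op in PARITY_OPS
    ]
    return pd.DataFrame(rows)
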