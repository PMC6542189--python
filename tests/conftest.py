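import numpy as np
import pytest

from invsym import SCHEMAS


@pytest.fixture(scope="session")
def ere13():
    return SCHEMAS["ERE13"]


@pytest.fixture(scope="session")
def hre13():
    return SCHEMAS["HRE13"]


@pytest.fixture(scope="session")
def ere15():
    return SCHEMAS["ERE15"]


@pytest.fixture(scope="session")
def p53re():
    return SCHEMAS["P53RE"]


def naive_scan(seq, schema, k_max):
    """Brute-force per-window Hamming scan: the oracle for scan_elements.

    Returns a set of (start, element_id, k) tuples.
    """
    seq = seq.upper()
    w = schema.footprint
    cons = schema.consensus
    prim = schema.primary_offsets
    spac = schema.spacer_offsets
    out = set()
    for s in range(len(seq) - w + 1):
        win = seq[s : s + w]
        if any(win[o] not in "ACGT" for o in prim):
            continue
        if any(win[o] not in "ACGT" for o in spac):
            continue
        subs = [(i + 1, win[schema.offset(i + 1)]) for i in range(schema.n)
                if win[schema.offset(i + 1)] != cons[schema.offset(i + 1)]]
        if len(subs) <= k_max:
            eid = "+".join(f"{p}{b}" for p, b in subs) if subs else "0"
            out.add((s, eid, len(subs)))
    return out


def naive_peak_counts(occ_df, peaks_df, mode="contained"):
    """Per-peak window check: the oracle for count_in_peaks."""
    counts = {}
    for peak in peaks_df.itertuples():
        for row in occ_df.itertuples():
            if row.chrom != peak.chrom:
                continue
            if mode == "contained":
                hit = peak.start <= row.start and row.end <= peak.end
            else:
                hit = row.start < peak.end and peak.start < row.end
            if hit:
                counts[row.element_id] = counts.get(row.element_id, 0) + 1
    return counts
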