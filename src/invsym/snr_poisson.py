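"""Signal-to-noise ratios against the random-genome expectation, with
one-tailed Poisson significance bounds.

The noise model: a random genome presents each specific n-primary-position
element once every 4^n nt, so an experiment with N peaks of nominal length L
is expected to contain lambda = N*L*m/4^n occurrences of a unit aggregating
m elements.  S/N is observed/lambda; the p < 0.001 band on the S/N scale is
[Q(p)/lambda, Q(1-p)/lambda] with Q the Poisson quantile function (smallest
integer whose CDF reaches the given level).  The bounds depend only on
lambda and p, never on the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .element_space import (
    ElementSchema,
    HalfSiteGroup,
    VacancyHierarchy,
    axis_order,
    element_from_id,
)
from .peak_counts import CountTable

import math


def expected_count(
    n_peaks: int, peak_length: float, schema: ElementSchema, m: int = 1
) -> float:
    """lambda = N * L * m / 4^n.

    ``m`` is the number of elements aggregated in the unit: 1 for a single
    element, C(n/2,k)*3^k for a half-site group at level k, C(n,k)*3^k for a
    whole level.  For variable-length peak sets pass the summed interval
    length as ``n_peaks * peak_length`` (e.g. n_peaks=1, peak_length=total).
    """
    if n_peaks <= 0 or peak_length <= 0 or m <= 0:
        raise ValueError("n_peaks, peak_length and m must be positive")
    return n_peaks * peak_length * m / 4**schema.n


def poisson_thresholds(lam: float, p: float = 0.001) -> tuple[float, float]:
    """One-tailed significance bounds (lower, upper) on the S/N scale.

    lower = Q(p)/lambda and upper = Q(1-p)/lambda with Q(q) the smallest
    integer whose Poisson CDF at ``lam`` reaches q; when CDF(0) >= p the
    lower bound is exactly 0.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0 < p < 0.5:
        raise ValueError("p must be in (0, 0.5)")
    lower = float(poisson.ppf(p, lam)) / lam
    upper = float(poisson.ppf(1 - p, lam)) / lam
    return lower, upper


def round_half_up(x: float, places: int = 2) -> float:
    """Decimal rounding as printed in figure captions (0.005 -> 0.01)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _m_group_level(schema: ElementSchema, k: int) -> int:
    return math.comb(schema.n // 2, k) * 3**k


def _m_level(schema: ElementSchema, k: int) -> int:
    return math.comb(schema.n, k) * 3**k


@dataclass
class SNRTable:
    """Long-format S/N profile: one row per display unit."""

    data: pd.DataFrame  # unit, k, observed, lam, snr, lower, upper (+ axis_pos)
    n_peaks: int
    peak_length: int
    p: float


def snr_by_level(table: CountTable, p: float = 0.001) -> pd.DataFrame:
    """Level-aggregate S/N: one row per variant count k."""
    obs = table.by_level()
    rows = []
    for k, o in obs.items():
        lam = expected_count(
            table.n_peaks, table.peak_length, table.schema, _m_level(table.schema, k)
        )
        lo, hi = poisson_thresholds(lam, p)
        rows.append(
            {"k": int(k), "observed": int(o), "lam": lam, "snr": o / lam,
             "lower": lo, "upper": hi}
        )
    return pd.DataFrame(rows)


def snr_profile(
    table: CountTable,
    groups: Sequence[HalfSiteGroup],
    hierarchy: VacancyHierarchy,
    p: float = 0.001,
) -> SNRTable:
    """Half-site-group S/N profile on the display axis.

    One row per (group, level); groups are ordered by :func:`axis_order`
    (``axis_pos`` is 1-based), so reverse-complement partners sit at mirror
    positions and the profile of an inversion-symmetric signal is mirror
    symmetric.
    """
    order = axis_order(groups, hierarchy)
    counts = table.by_group_level(groups)
    schema = table.schema
    k_levels = [k for k in counts.columns if k <= schema.n // 2]
    lam_k = {
        k: expected_count(table.n_peaks, table.peak_length, schema, _m_group_level(schema, k))
        for k in k_levels
    }
    bounds = {k: poisson_thresholds(lam, p) for k, lam in lam_k.items()}
    rows = []
    for pos, gi in enumerate(order, start=1):
        g = groups[gi]
        for k in k_levels:
            o = int(counts.loc[g.gid, k])
            lam = lam_k[k]
            rows.append(
                {
                    "axis_pos": pos,
                    "group": g.gid,
                    "vacancy_label": g.vacancy_label,
                    "double_label": g.double_label or ".",
                    "k": int(k),
                    "observed": o,
                    "lam": lam,
                    "snr": o / lam,
                    "lower": bounds[k][0],
                    "upper": bounds[k][1],
                }
            )
    return SNRTable(
        data=pd.DataFrame(rows),
        n_peaks=table.n_peaks,
        peak_length=table.peak_length,
        p=p,
    )


def snr_by_element(table: CountTable, p: float = 0.001) -> pd.DataFrame:
    """Per-element S/N (m = 1), including elements observed zero times is the
    caller's concern: only observed elements appear here."""
    schema = table.schema
    lam1 = expected_count(table.n_peaks, table.peak_length, schema, 1)
    lo, hi = poisson_thresholds(lam1, p)
    df = table.counts.rename("observed").reset_index()
    df["k"] = [element_from_id(schema, e).k for e in df["element_id"]]
    df["lam"] = lam1
    df["snr"] = df["observed"] / lam1
    df["lower"], df["upper"] = lo, hi
    return df


@dataclass
class ScaleInvarianceReport:
    ratios_full: pd.Series
    ratios_sub: pd.Series
    max_sd_units: float
    sufficient: bool


def scale_invariance(
    table_full: CountTable, table_sub: CountTable, baseline_k: int = 0
) -> ScaleInvarianceReport:
    """Compare level-aggregate S/N ratios between a full peak set and a
    subsample of it.

    The relative S/N values are scale invariant: subsampling peaks at rate q
    scales every expected count by q, leaving ratios between levels fixed up
    to binomial noise.  Deviations are reported in binomial-SD units of the
    subsampled counts.
    """
    full = snr_by_level(table_full).set_index("k")
    sub = snr_by_level(table_sub).set_index("k")
    if table_sub.n_peaks == 0 or (sub["observed"] == 0).all():
        return ScaleInvarianceReport(
            pd.Series(dtype=float), pd.Series(dtype=float), float("nan"), False
        )
    base_f = full.loc[baseline_k, "snr"]
    base_s = sub.loc[baseline_k, "snr"]
    if base_f == 0 or base_s == 0:
        return ScaleInvarianceReport(
            pd.Series(dtype=float), pd.Series(dtype=float), float("nan"), False
        )
    rf = full["snr"] / base_f
    rs = sub["snr"] / base_s
    # deviation of each subsampled level count from its binomial expectation
    # q * n_full, in SD units; q estimated from the peak totals
    q = table_sub.n_peaks / table_full.n_peaks
    devs = []
    for k in rf.index:
        n_f = int(full.loc[k, "observed"])
        n_s = int(sub.loc[k, "observed"])
        exp = q * n_f
        sd = float(np.sqrt(max(n_f * q * (1 - q), 1.0)))
        devs.append(abs(n_s - exp) / sd)
    return ScaleInvarianceReport(rf, rs, float(max(devs)), True)
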