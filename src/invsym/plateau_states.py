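"""Quantify the discrete plateaus of level-1 half-site-group S/N profiles.

Plateau membership is *structural*: a group belongs to the plateau named by
its algebraic state under the chosen pair grouping (vacancy weights minus
double-occupant weights), never to a cluster fitted from the data.  The
empirical S/N values are then summarized per plateau, and the step sizes
(the grouping's algebraic variables) are estimated by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .element_space import (
    HalfSiteGroup,
    StateGrouping,
    state_of_group,
    state_vector,
)


def _state_label(vec: tuple[int, ...], labels: tuple[str, ...], reference: str) -> str:
    """Symbolic label like ``+2X`` / ``-X+Y`` from a class vector."""
    sym = {}
    names = "XYZWV"
    j = 0
    for lab in labels:
        if lab == reference:
            sym[lab] = None
        else:
            sym[lab] = names[j % len(names)]
            j += 1
    parts = []
    for lab, c in zip(labels, vec):
        s = sym[lab]
        if s is None or c == 0:
            continue
        sign = "+" if c > 0 else "-"
        mag = "" if abs(c) == 1 else str(abs(c))
        parts.append(f"{sign}{mag}{s}")
    return "".join(parts) if parts else "0"


def _reference_class(grouping: StateGrouping) -> str:
    """The weight-0 class if declared, else the largest class."""
    zero = [lab for lab, w in grouping.weights.items() if w == 0]
    if zero:
        return zero[0]
    from collections import Counter

    sizes = Counter(grouping.classes.values())
    return max(sorted(sizes), key=lambda lab: sizes[lab])


def assign_plateaus(
    groups: Sequence[HalfSiteGroup], grouping: StateGrouping
) -> dict[tuple[int, ...], list[str]]:
    """Structural plateau membership: state vector -> member group ids."""
    if groups and groups[0].schema.pairs != grouping.schema.pairs:
        raise ValueError("grouping and groups use different schemas")
    out: dict[tuple[int, ...], list[str]] = {}
    for g in groups:
        out.setdefault(state_vector(g, grouping), []).append(g.gid)
    return out


@dataclass
class PlateauSummary:
    """Per-plateau statistics and fitted step sizes.

    ``table`` has one row per plateau: symbolic state, numeric state (under
    the grouping's declared weights, if any), member count, mean S/N, sample
    and population SD, and the difference from the zero-state plateau mean.
    ``weights`` holds the least-squares estimate of each non-reference class
    weight (the algebraic variables) with its standard error.
    """

    grouping: StateGrouping
    table: pd.DataFrame
    weights: pd.DataFrame  # index class label, columns estimate, se
    zero_mean: float
    residual_sd: float

    @property
    def step(self) -> float:
        """X-hat for single-variable groupings (first fitted weight)."""
        return float(self.weights["estimate"].iloc[0])

    @property
    def step_se(self) -> float:
        return float(self.weights["se"].iloc[0])


def quantify(
    groups: Sequence[HalfSiteGroup],
    snr: Mapping[str, float] | pd.Series,
    grouping: StateGrouping,
) -> PlateauSummary:
    """Summarize one S/N value per group into plateau statistics.

    The difference-from-mean column is relative to the 0-state plateau mean.
    Class weights are estimated by regressing the per-group S/N on the
    integer class vectors (reference class dropped; its weight is 0 by the
    translation invariance of the state).
    """
    snr = pd.Series(snr, dtype=float)
    missing = [g.gid for g in groups if g.gid not in snr.index]
    if missing:
        raise ValueError(f"no S/N value for groups: {missing[:3]}...")
    labels = grouping.class_labels
    ref = _reference_class(grouping)
    free = [lab for lab in labels if lab != ref]

    vecs = np.array([state_vector(g, grouping) for g in groups])
    y = snr.loc[[g.gid for g in groups]].to_numpy()
    keep = [labels.index(lab) for lab in free]
    X = np.column_stack([np.ones(len(groups)), vecs[:, keep]])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(groups) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    weights = pd.DataFrame(
        {"estimate": beta[1:], "se": np.sqrt(np.diag(cov)[1:])}, index=free
    )

    plateaus = assign_plateaus(list(groups), grouping)
    zero_vec = tuple(0 for _ in labels)
    rows = []
    for vec in sorted(plateaus, key=lambda v: tuple(-c for c in v)):
        members = plateaus[vec]
        vals = snr.loc[members].to_numpy()
        numeric = sum(
            c * float(grouping.weights.get(lab, 0.0)) for c, lab in zip(vec, labels)
        )
        rows.append(
            {
                "state": _state_label(vec, labels, ref),
                "vector": vec,
                "numeric_state": numeric,
                "n_groups": len(members),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "sd_pop": float(vals.std(ddof=0)),
                "empty": len(vals) == 0,
            }
        )
    table = pd.DataFrame(rows)
    if zero_vec in plateaus:
        zero_mean = float(snr.loc[plateaus[zero_vec]].to_numpy().mean())
    else:
        zero_mean = float("nan")
    table["diff_from_mean"] = table["mean"] - zero_mean
    # order: numeric state descending when weights are declared, else by label
    if grouping.weights:
        table = table.sort_values("numeric_state", ascending=False).reset_index(drop=True)
    return PlateauSummary(
        grouping=grouping,
        table=table,
        weights=weights,
        zero_mean=zero_mean,
        residual_sd=float(np.sqrt(sigma2)),
    )


def plateau_census(summary: PlateauSummary) -> dict[str, int]:
    return dict(zip(summary.table["state"], summary.table["n_groups"]))


def algebraic_checks(summary: PlateauSummary) -> pd.DataFrame:
    """Verify the grouping's equation system on the fitted summary.

    Each plateau mean should equal (zero-plateau mean) + vector . weights;
    the report lists the residual of that identity per plateau (for the
    two-class case these are exactly the ladder equations, e.g.
    mean(+2X) - mean(0) = 2*X-hat).  Noiseless synthetic input gives zero
    residuals up to floating point.
    """
    labels = summary.grouping.class_labels
    ref = _reference_class(summary.grouping)
    w = {lab: 0.0 for lab in labels}
    for lab, row in summary.weights.iterrows():
        w[lab] = float(row["estimate"])
    rows = []
    for _, r in summary.table.iterrows():
        pred = summary.zero_mean + sum(
            c * w[lab] for c, lab in zip(r["vector"], labels)
        )
        rows.append(
            {
                "state": r["state"],
                "mean": r["mean"],
                "predicted": pred,
                "residual": r["mean"] - pred,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["max_residual"] = float(df["residual"].abs().max())
    return df
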