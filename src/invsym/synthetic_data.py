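"""Synthetic genomes and ChIP-like peak sets with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* genomes with (optionally block-heterogeneous) base composition carrying
  planted variant elements at controlled multiplicities;
* peak sets whose per-element occupancy decays with the variant count and
  follows a pair-weight hierarchy with a spacer-crossing penalty, so the
  group-level S/N profile is mirror symmetric with discrete plateaus;
* exactly inversion-symmetric (mirrored) genomes for parity tests.

The occupancy link function is a modelling convenience: only its contract
matters -- monotone decay in k, additive pair weights, a crossover penalty,
and exact reverse-complement symmetry (the probability depends on the
substituted pairs and the side pattern only up to mirror image).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .element_space import ElementSchema, VariantElement, revcomp


@dataclass(frozen=True)
class OccupancyModel:
    """P(peak | element occurrence) for a planted element.

    logit P = alpha - beta*k + sum over substituted positions of the weight
    of their palindromic pair, minus gamma when substitutions sit on both
    sides of the spacer (a crossover).  ``pair_weights`` is keyed by the low
    member of each pair.
    """

    schema: ElementSchema
    pair_weights: Mapping[int, float]
    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 0.0

    def __post_init__(self) -> None:
        lows = {p.low for p in self.schema.pairs}
        if set(self.pair_weights) != lows:
            raise ValueError("pair_weights must cover every palindromic pair")
        object.__setattr__(self, "pair_weights", dict(self.pair_weights))

    def logit(self, element: VariantElement) -> float:
        half = self.schema.n // 2
        positions = element.positions
        score = self.alpha - self.beta * element.k
        for p in positions:
            score += self.pair_weights[self.schema.pair_of(p).low]
        left = any(p <= half for p in positions)
        right = any(p > half for p in positions)
        if left and right:
            score -= self.gamma
        return score

    def prob(self, element: VariantElement) -> float:
        return 1.0 / (1.0 + math.exp(-self.logit(element)))

    def dim_variant(self, weight_scale: float = 0.3, alpha_shift: float = -1.5) -> "OccupancyModel":
        """A binding-attenuated model: same hierarchy, reduced amplitude.

        Mimics a DNA-binding-domain mutant that obeys the same rules with a
        shorter residence time: all pair weights are scaled toward zero and
        the baseline occupancy drops, so the S/N profile keeps its structure
        (rank order of plateaus) at a reduced amplitude, converging to the
        same noise floor at high k.
        """
        return OccupancyModel(
            self.schema,
            {p: w * weight_scale for p, w in self.pair_weights.items()},
            alpha=self.alpha + alpha_shift,
            beta=self.beta * weight_scale,
            gamma=self.gamma * weight_scale,
        )


#: Pair weights shaped like the empirical vacancy hierarchies (arbitrary
#: units on the logit scale, descending along the hierarchy).
DEFAULT_ERE_WEIGHTS: dict[int, float] = {3: 1.0, 1: 0.6, 5: 0.1, 4: -0.35, 2: -0.8}
DEFAULT_HRE_WEIGHTS: dict[int, float] = {2: 1.0, 5: 0.6, 1: 0.1, 4: -0.35, 3: -0.8}


def _draw_background(
    rng: np.random.Generator,
    length: int,
    composition: Sequence[float] | Sequence[Sequence[float]],
    block_len: int | None,
) -> np.ndarray:
    comp = np.asarray(composition, dtype=float)
    if comp.ndim == 1:
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("composition must be 4 probabilities summing to 1")
        return rng.choice(4, size=length, p=comp).astype(np.int8)
    # block-heterogeneous composition: cycle the rows in blocks
    if block_len is None:
        block_len = max(length // (4 * len(comp)), 1)
    out = np.empty(length, dtype=np.int8)
    pos = 0
    row = 0
    while pos < length:
        n = min(block_len, length - pos)
        p = comp[row % len(comp)]
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("each composition row must sum to 1")
        out[pos : pos + n] = rng.choice(4, size=n, p=p)
        pos += n
        row += 1
    return out


def make_genome(
    length: int,
    plantings: Sequence[tuple[VariantElement, int]] = (),
    composition: Sequence[float] | Sequence[Sequence[float]] = (0.25, 0.25, 0.25, 0.25),
    seed: int | None = None,
    block_len: int | None = None,
    margin: int = 500,
    seq_id: str = "synth",
) -> tuple[str, pd.DataFrame]:
    """A random genome with planted element variants at recorded positions.

    Planted elements are inserted at non-overlapping uniform positions (kept
    ``margin`` nt away from the ends so later peak placement cannot clip
    them); spacer positions are filled with random bases.  Returns the
    sequence and a ground-truth table (chrom, start, end, element_id, k).
    Fully reproducible from ``seed``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    elements = [e for e, copies in plantings for _ in range(int(copies))]
    if elements:
        w = elements[0].schema.footprint
        footprint_total = len(elements) * w
        usable = length - 2 * margin
        if footprint_total > usable / 2:
            raise ValueError(
                f"infeasible planting density: {footprint_total} nt of elements "
                f"into {usable} usable nt"
            )
    seq = _draw_background(rng, length, composition, block_len)
    rows = []
    if elements:
        w = elements[0].schema.footprint
        # sample non-overlapping starts: draw gaps from the leftover space
        m = len(elements)
        slack = (length - 2 * margin) - m * w
        cuts = np.sort(rng.choice(slack + 1, size=m, replace=True))
        starts = margin + cuts + w * np.arange(m)
        order = rng.permutation(m)
        for i, s in zip(order, starts):
            e = elements[i]
            realized = e.realize()
            enc = np.array(
                [("ACGT".index(b) if b != "N" else -1) for b in realized], dtype=np.int8
            )
            spacer_fill = rng.integers(0, 4, size=(enc == -1).sum())
            enc[enc == -1] = spacer_fill
            seq[s : s + w] = enc
            rows.append(
                {
                    "chrom": seq_id,
                    "start": int(s),
                    "end": int(s + w),
                    "element_id": e.element_id,
                    "k": e.k,
                }
            )
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "element_id", "k"])
    truth = truth.sort_values("start").reset_index(drop=True) if len(truth) else truth
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = bases[seq].tobytes().decode("ascii")
    return genome, truth


def make_mirrored_genome(
    length: int,
    seed: int | None = None,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> str:
    """S + N-sentinel + reverse_complement(S), with |S| = length / 2.

    Every k-mer window avoiding the sentinel then has an exactly matching
    reverse-complement window on the same strand, so reverse-complement
    parity of k-mer counts is exact by construction (not merely asymptotic).
    """
    if length <= 0 or length % 2:
        raise ValueError("length must be a positive even integer")
    half, _ = make_genome(length // 2, composition=composition, seed=seed, margin=0)
    return half + "N" + revcomp(half)


def make_peaks(
    truth: pd.DataFrame,
    model: OccupancyModel,
    genome_length: int,
    peak_length: int,
    n_background: int = 0,
    seed: int | None = None,
    seq_id: str = "synth",
) -> tuple[pd.DataFrame, pd.Series]:
    """Emit a peak set from a ground-truth occurrence table.

    Each occurrence spawns a peak of length L centered on it with the
    model's occupancy probability; ``n_background`` peaks land uniformly.
    Returns (peaks frame, expected per-element signal-peak counts) -- the
    expectation covers the planted channel only, background containments
    are extra.
    """
    w = model.schema.footprint
    if peak_length < w:
        raise ValueError("peak length must cover the element footprint")
    rng = np.random.default_rng(seed)
    from .element_space import element_from_id

    probs = {}
    rows = []
    expected: dict[str, float] = {}
    for r in truth.itertuples():
        eid = r.element_id
        if eid not in probs:
            probs[eid] = model.prob(element_from_id(model.schema, eid))
        expected[eid] = expected.get(eid, 0.0) + probs[eid]
        if rng.random() < probs[eid]:
            center = (r.start + r.end) // 2
            start = int(np.clip(center - peak_length // 2, 0, genome_length - peak_length))
            rows.append((r.chrom, start, start + peak_length, "signal"))
    if n_background:
        starts = rng.integers(0, genome_length - peak_length + 1, size=n_background)
        for s in starts:
            rows.append((seq_id, int(s), int(s) + peak_length, "background"))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "origin"])
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    return peaks, pd.Series(expected, name="expected", dtype=float)
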