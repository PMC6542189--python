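"""Combinatorics of the variant space around a palindromic response element.

A palindromic response element (e.g. the estrogen response element,
5'-GGTCAnnnTGACC-3') consists of ``n`` informative *primary positions* --
a half-site, an unconstrained spacer, and the reverse complement of the
half-site.  Primary positions are numbered 1..n, skipping the spacer, and
position ``p`` is the reverse complement of position ``n + 1 - p``; the two
form a *palindromic position pair*.

This module enumerates the Hamming neighbourhood of the consensus (the
k-nt variant elements), the reverse-complement structure of that space,
the *half-site groups* obtained by fixing n/2 primary positions, and the
discrete-state algebra induced by weighting palindromic pairs.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


class PalindromicPair(NamedTuple):
    """A pair of mutually reverse-complementary primary positions."""

    low: int
    high: int

    @property
    def label(self) -> str:
        return f"{self.low}-{self.high}"


@dataclass(frozen=True)
class ElementSchema:
    """A palindromic element: half-site, spacer length, derived geometry.

    The consensus is ``half_site + spacer + revcomp(half_site)`` where the
    spacer is wildcard (N).  ``n`` primary positions are numbered 1..n with
    the spacer sitting implicitly between n/2 and n/2 + 1.
    """

    name: str
    half_site: str
    spacer_len: int

    def __post_init__(self) -> None:
        hs = self.half_site.upper()
        if not hs or any(b not in BASES for b in hs):
            raise ValueError(f"half_site must be non-empty A/C/G/T: {self.half_site!r}")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        object.__setattr__(self, "half_site", hs)

    @property
    def n(self) -> int:
        """Number of primary (informative) positions; always even."""
        return 2 * len(self.half_site)

    @property
    def footprint(self) -> int:
        """Total element length in the genome, spacer included."""
        return self.n + self.spacer_len

    @property
    def consensus(self) -> str:
        return self.half_site + "N" * self.spacer_len + revcomp(self.half_site)

    @property
    def pairs(self) -> tuple[PalindromicPair, ...]:
        return tuple(PalindromicPair(p, self.n + 1 - p) for p in range(1, self.n // 2 + 1))

    def pair_of(self, p: int) -> PalindromicPair:
        """The palindromic pair containing primary position ``p``."""
        low = min(p, self.n + 1 - p)
        return PalindromicPair(low, self.n + 1 - low)

    def offset(self, p: int) -> int:
        """0-based sequence offset of primary position ``p`` within the element."""
        if not 1 <= p <= self.n:
            raise ValueError(f"primary position out of range: {p}")
        return p - 1 if p <= self.n // 2 else p - 1 + self.spacer_len

    @property
    def primary_offsets(self) -> tuple[int, ...]:
        return tuple(self.offset(p) for p in range(1, self.n + 1))

    @property
    def spacer_offsets(self) -> tuple[int, ...]:
        h = self.n // 2
        return tuple(range(h, h + self.spacer_len))

    def consensus_base(self, p: int) -> str:
        return self.consensus[self.offset(p)]


#: The element schemas studied here: the 13-nt estrogen (ERE) and ketosteroid
#: hormone (HRE) response elements, their 15-nt flank-extended forms, and the
#: spacer-less p53 response element.
SCHEMAS: dict[str, ElementSchema] = {
    "ERE13": ElementSchema("ERE13", "GGTCA", 3),
    "HRE13": ElementSchema("HRE13", "GAACA", 3),
    "ERE15": ElementSchema("ERE15", "AGGTCA", 3),
    "HRE15": ElementSchema("HRE15", "AGAACA", 3),
    "P53RE": ElementSchema("P53RE", "TGCCC", 0),
}


@dataclass(frozen=True)
class VariantElement:
    """An element at Hamming distance k from the consensus.

    ``subs`` maps 1-based primary positions to replacement bases, each
    different from the consensus base at that position.  The spacer is never
    substituted.
    """

    schema: ElementSchema
    subs: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        subs = tuple(sorted(self.subs))
        for p, b in subs:
            if not 1 <= p <= self.schema.n:
                raise ValueError(f"substitution position out of range: {p}")
            if b == self.schema.consensus_base(p):
                raise ValueError(f"substitution at {p} equals the consensus base {b}")
            if b not in BASES:
                raise ValueError(f"invalid base {b!r}")
        if len({p for p, _ in subs}) != len(subs):
            raise ValueError("duplicate substitution positions")
        object.__setattr__(self, "subs", subs)

    @property
    def k(self) -> int:
        return len(self.subs)

    @property
    def element_id(self) -> str:
        """Compact identifier, e.g. ``1T`` or ``3C+8T``; consensus is ``0``."""
        if not self.subs:
            return "0"
        return "+".join(f"{p}{b}" for p, b in self.subs)

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(p for p, _ in self.subs)

    def realize(self) -> str:
        """The concrete sequence, with N at spacer positions."""
        seq = list(self.schema.consensus)
        for p, b in self.subs:
            seq[self.schema.offset(p)] = b
        return "".join(seq)

    def reverse_complement(self) -> "VariantElement":
        """Map each substitution (p, b) to (n+1-p, complement(b))."""
        n = self.schema.n
        return VariantElement(
            self.schema, tuple((n + 1 - p, COMPLEMENT[b]) for p, b in self.subs)
        )


def element_from_id(schema: ElementSchema, element_id: str) -> VariantElement:
    """Parse an ``element_id`` string back into a :class:`VariantElement`."""
    if element_id in ("0", "", "consensus"):
        return VariantElement(schema)
    subs = []
    for token in element_id.split("+"):
        subs.append((int(token[:-1]), token[-1]))
    return VariantElement(schema, tuple(subs))


def iter_variants(schema: ElementSchema, k: int) -> Iterator[VariantElement]:
    """Yield all C(n,k)*3^k elements at Hamming distance exactly ``k``.

    Deterministic order: lexicographic by substituted positions, then by base.
    """
    if not 0 <= k <= schema.n:
        raise ValueError(f"k must be in [0, {schema.n}], got {k}")
    positions = range(1, schema.n + 1)
    for combo in itertools.combinations(positions, k):
        alt = [tuple(b for b in BASES if b != schema.consensus_base(p)) for p in combo]
        for bases in itertools.product(*alt):
            yield VariantElement(schema, tuple(zip(combo, bases)))


def enumerate_variants(schema: ElementSchema, k: int) -> list[VariantElement]:
    """All distinct elements at Hamming distance exactly ``k`` (materialized)."""
    return list(iter_variants(schema, k))


def variant_count(schema: ElementSchema, k: int) -> int:
    """Closed-form size of the exact-k level: C(n,k) * 3^k."""
    if not 0 <= k <= schema.n:
        raise ValueError(f"k must be in [0, {schema.n}], got {k}")
    return math.comb(schema.n, k) * 3**k


def reverse_complement(element: VariantElement) -> VariantElement:
    return element.reverse_complement()


# ---------------------------------------------------------------------------
# Half-site groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HalfSiteGroup:
    """A choice of n/2 fixed primary positions.

    Every palindromic pair falls into one of three classes relative to the
    fixed set F:

    * vacancy (V): neither member fixed -- the consensus identity of the pair
      is absent from the element;
    * double occupant (D): both members fixed -- the identity is specified
      twice;
    * single (S): exactly one member fixed.

    |V| = |D| always, because |F| = n/2 forces the excess of doubles to
    balance the deficit of vacancies.
    """

    schema: ElementSchema
    fixed: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.fixed) != self.schema.n // 2:
            raise ValueError("a half-site group fixes exactly n/2 primary positions")
        if not self.fixed <= set(range(1, self.schema.n + 1)):
            raise ValueError("fixed positions out of range")

    @property
    def gid(self) -> str:
        """Identifier listing the fixed positions, e.g. ``1-2-3-4-5``."""
        return "-".join(str(p) for p in sorted(self.fixed))

    @property
    def varied(self) -> frozenset[int]:
        return frozenset(range(1, self.schema.n + 1)) - self.fixed

    def _split(self) -> tuple[tuple, tuple, tuple]:
        V, D, S = [], [], []
        for pair in self.schema.pairs:
            m = (pair.low in self.fixed) + (pair.high in self.fixed)
            (V if m == 0 else D if m == 2 else S).append(pair)
        return tuple(V), tuple(D), tuple(S)

    @property
    def vacancies(self) -> tuple[PalindromicPair, ...]:
        return self._split()[0]

    @property
    def double_occupants(self) -> tuple[PalindromicPair, ...]:
        return self._split()[1]

    @property
    def singles(self) -> tuple[PalindromicPair, ...]:
        return self._split()[2]

    @property
    def vacancy_label(self) -> str:
        V = self.vacancies
        tag = f"{len(V)}V"
        if V:
            tag += "-".join(str(p.low) for p in V)
        return tag

    @property
    def double_label(self) -> str:
        D = self.double_occupants
        return "-".join(str(p.low) for p in D)

    def rc_fixed(self) -> frozenset[int]:
        n = self.schema.n
        return frozenset(n + 1 - p for p in self.fixed)

    @property
    def rc_group(self) -> "HalfSiteGroup":
        return HalfSiteGroup(self.schema, self.rc_fixed())

    @property
    def complement_group(self) -> "HalfSiteGroup":
        """The group fixing the complementary position set.

        Complementation swaps vacancies with double occupants and therefore
        negates the algebraic state; the reverse-complement group, by
        contrast, preserves V and D (each palindromic pair keeps its number
        of fixed members under the pair map), which is why a group and its
        reverse complement sit on the same plateau and the display profile
        is mirror symmetric.
        """
        return HalfSiteGroup(self.schema, self.varied)

    @property
    def innate(self) -> bool:
        """True when the group is its own reverse complement (no singles)."""
        return self.fixed == self.rc_fixed()

    def contains(self, element: VariantElement) -> bool:
        """Whether the element's substituted positions avoid the fixed set."""
        return element.positions <= self.varied


def enumerate_half_site_groups(schema: ElementSchema) -> list[HalfSiteGroup]:
    """One group per choice of n/2 fixed positions: C(n, n/2) groups total."""
    if schema.n % 2:
        raise ValueError("n must be even")
    h = schema.n // 2
    return [
        HalfSiteGroup(schema, frozenset(c))
        for c in itertools.combinations(range(1, schema.n + 1), h)
    ]


def group_members(group: HalfSiteGroup, k: int) -> list[VariantElement]:
    """Level-k elements whose substitutions sit inside the group's varied
    positions: C(n/2, k) * 3^k elements."""
    h = group.schema.n // 2
    if not 0 <= k <= h:
        raise ValueError(f"k must be in [0, {h}], got {k}")
    out = []
    varied = sorted(group.varied)
    for combo in itertools.combinations(varied, k):
        alt = [
            tuple(b for b in BASES if b != group.schema.consensus_base(p)) for p in combo
        ]
        for bases in itertools.product(*alt):
            out.append(VariantElement(group.schema, tuple(zip(combo, bases))))
    return out


# ---------------------------------------------------------------------------
# Display ordering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VacancyHierarchy:
    """Preference order over palindromic pairs, most-preferred first.

    Stored as the low member of each pair, e.g. ``(3, 1, 5, 4, 2)`` for the
    ERE order 3-8 > 1-10 > 5-6 > 4-7 > 2-9.
    """

    order: tuple[int, ...]

    def rank(self, pair: PalindromicPair) -> int:
        return self.order.index(pair.low)

    def validate(self, schema: ElementSchema) -> None:
        expected = tuple(sorted(p.low for p in schema.pairs))
        if tuple(sorted(self.order)) != expected:
            raise ValueError(
                f"hierarchy {self.order} is not a permutation of the pairs of {schema.name}"
            )


#: Empirical pair-preference hierarchies (most-preferred vacancy first).
HIERARCHIES: dict[str, VacancyHierarchy] = {
    "ERE13": VacancyHierarchy((3, 1, 5, 4, 2)),
    "HRE13": VacancyHierarchy((2, 5, 1, 4, 3)),
    "P53RE": VacancyHierarchy((5, 1, 3, 4, 2)),
    "ERE15": VacancyHierarchy((4, 1, 2, 6, 5, 3)),
    "HRE15": VacancyHierarchy((3, 1, 6, 2, 5, 4)),
}


def axis_order(groups: Sequence[HalfSiteGroup], hierarchy: VacancyHierarchy) -> list[int]:
    """Display order of half-site groups as indices into ``groups``.

    Left block: one representative per reverse-complement pair, sorted by
    vacancy count ascending, then by the hierarchy ranks of the vacancy
    pairs, then of the double-occupant pairs, then lexicographically by the
    fixed set.  Right block: the reverse complements of the left block in
    reversed order, so the ends of the axis are mutual reverse complements.
    Self-reverse-complement (innate palindrome) groups form the center block.
    """
    if not groups:
        return []
    schema = groups[0].schema
    hierarchy.validate(schema)
    index = {g.fixed: i for i, g in enumerate(groups)}

    def sort_key(g: HalfSiteGroup):
        return (
            len(g.vacancies),
            tuple(sorted(hierarchy.rank(p) for p in g.vacancies)),
            tuple(sorted(hierarchy.rank(p) for p in g.double_occupants)),
            tuple(sorted(g.fixed)),
        )

    reps, innate = [], []
    for g in groups:
        if g.innate:
            innate.append(g)
        elif tuple(sorted(g.fixed)) <= tuple(sorted(g.rc_fixed())):
            reps.append(g)
    reps.sort(key=sort_key)
    innate.sort(key=sort_key)
    order = [index[g.fixed] for g in reps]
    order += [index[g.fixed] for g in innate]
    order += [index[g.rc_fixed()] for g in reversed(reps)]
    return order


# ---------------------------------------------------------------------------
# Discrete-state algebra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateGrouping:
    """A partition of the palindromic pairs into weighted classes.

    ``classes`` maps the low member of each pair to a class label;
    ``weights`` gives one numeric weight per label.  The reference class
    conventionally has weight 0 -- because |V| = |D|, the group state
    sum(V) - sum(D) is invariant to adding a constant to every weight, so
    this loses no generality.
    """

    schema: ElementSchema
    classes: Mapping[int, str]
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lows = {p.low for p in self.schema.pairs}
        if set(self.classes) != lows:
            raise ValueError("classes must cover every palindromic pair exactly once")
        object.__setattr__(self, "classes", dict(self.classes))
        object.__setattr__(self, "weights", dict(self.weights))

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.classes.values())))

    @property
    def signature(self) -> tuple[int, ...]:
        """Class sizes, descending, zero-padded to n/2 entries."""
        sizes = sorted(Counter(self.classes.values()).values(), reverse=True)
        return tuple(sizes) + (0,) * (self.schema.n // 2 - len(sizes))

    def weight_of_pair(self, pair: PalindromicPair) -> float:
        return float(self.weights.get(self.classes[pair.low], 0.0))


def grouping_from_signature(
    schema: ElementSchema,
    sizes: Sequence[int],
    hierarchy: VacancyHierarchy | None = None,
) -> StateGrouping:
    """Build a grouping with the given class-size signature.

    Pairs are assigned to classes (labelled A, B, C, ... by decreasing
    weight priority, smallest class first) following the hierarchy order if
    given, else the natural pair order.  Weights are left empty (generic).
    """
    sizes = [s for s in sizes if s > 0]
    if sum(sizes) != schema.n // 2:
        raise ValueError("class sizes must sum to n/2")
    order = (
        list(hierarchy.order)
        if hierarchy is not None
        else [p.low for p in schema.pairs]
    )
    classes: dict[int, str] = {}
    labels = [chr(ord("A") + i) for i in range(len(sizes))]
    # smallest classes first: the distinguished (non-reference) pairs come
    # from the top of the hierarchy
    it = iter(order)
    for label, size in zip(labels, sorted(sizes)):
        for _ in range(size):
            classes[next(it)] = label
    return StateGrouping(schema, classes)


def ere_grouping(schema: ElementSchema | None = None) -> StateGrouping:
    """The two-class split behind the five estrogen-receptor plateaus:
    pairs 3-8 and 1-10 carry weight +1, the rest 0 (signature (3,2))."""
    schema = schema or SCHEMAS["ERE13"]
    classes = {p.low: ("A" if p.low in (3, 1) else "B") for p in schema.pairs}
    return StateGrouping(schema, classes, {"A": 1.0, "B": 0.0})


def hre_grouping(schema: ElementSchema | None = None) -> StateGrouping:
    """The split behind the three ketosteroid-receptor plateaus: pair 2-9
    carries weight +1, the rest 0 (signature (4,1))."""
    schema = schema or SCHEMAS["HRE13"]
    classes = {p.low: ("A" if p.low == 2 else "B") for p in schema.pairs}
    return StateGrouping(schema, classes, {"A": 1.0, "B": 0.0})


def singleton_grouping(schema: ElementSchema) -> StateGrouping:
    """Every pair in its own class (fully generic weights)."""
    classes = {p.low: chr(ord("A") + i) for i, p in enumerate(schema.pairs)}
    return StateGrouping(schema, classes)


def state_vector(group: HalfSiteGroup, grouping: StateGrouping) -> tuple[int, ...]:
    """Net vacancy-minus-double count per class, in label order.

    With algebraically independent class weights, two groups share a state
    value iff they share this integer vector, so the vector is the exact
    (float-free) state identity.
    """
    labels = grouping.class_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    v = [0] * len(labels)
    for pair in group.vacancies:
        v[idx[grouping.classes[pair.low]]] += 1
    for pair in group.double_occupants:
        v[idx[grouping.classes[pair.low]]] -= 1
    return tuple(v)


def state_of_group(group: HalfSiteGroup, grouping: StateGrouping) -> float:
    """Numeric state: sum of vacancy-pair weights minus double-occupant weights."""
    s = 0.0
    for pair in group.vacancies:
        s += grouping.weight_of_pair(pair)
    for pair in group.double_occupants:
        s -= grouping.weight_of_pair(pair)
    return s


class DistinctStates(NamedTuple):
    n_states: int
    census: dict[tuple[int, ...], int]


def count_distinct_states(
    schema: ElementSchema, grouping: StateGrouping | Sequence[int]
) -> DistinctStates:
    """Number of distinct state values over all C(n, n/2) groups, with
    generic (algebraically independent) class weights.

    Distinctness is decided on exact integer class vectors, never on floats.
    Returns the count and the per-state group census keyed by vector.
    """
    if not isinstance(grouping, StateGrouping):
        grouping = grouping_from_signature(schema, grouping)
    census: Counter = Counter()
    for g in enumerate_half_site_groups(schema):
        census[state_vector(g, grouping)] += 1
    return DistinctStates(len(census), dict(census))
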