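"""Chain topology of disulfide-bonded peptides.

One disulfide bond partitions a chain into a cyclized loop and up to two
linear tails.  With cysteines at positions n1 < n2 in a chain of length L,
two dimensionless parameters summarize the geometry:

    s = (L - n2 + n1 + 1) / L      fraction of the chain outside the loop,
                                   plus the two bridging cysteines
    p = (L - n2) / (n1 - 1)        ratio of C-tail to N-tail length
                                   (undefined when n1 = 1)

A chain is hairpin-like (HL) when s < 0.5 (the loop spans most of it).
Otherwise it is lasso-like (LL) when one tail dominates — n1 = 1, p <= 0.3
or p >= 3 — subtyped C-LL (C-terminal loop, L - n2 < n1) or N-LL
(N-terminal loop, L - n2 > n1).  The published condition is printed as
"0.3 >= p >= 3", which no p satisfies; it is implemented here as the
disjunction p <= 0.3 OR p >= 3, the geometric reading of "one tail much
longer than the other".  Chains with s >= 0.5 but balanced tails fall into
an explicit AMBIGUOUS class rather than being silently coerced.

With k >= 2 disulfide bonds, the 2k bonded cysteines are enumerated along
the chain and the bond set becomes a perfect matching of ordinals 1..2k —
a chord diagram.  The fully nested matching {i, 2k+1-i} is ladder-like
(LD), the sequential matching {2i-1, 2i} a string of rings (SR), any
matching with a chord crossing (a1 < a2 < b1 < b2) crossed rings (CR).
Non-crossing matchings that are neither pure scheme exist for k >= 3
(Catalan(k) - 2 of them) and are labelled MIXED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .records import BondKind, DomainError, PeptideRecord

MAX_ENUMERATION_K = 6

# classification thresholds; defaults are the published values
S_CUTOFF = 0.5
P_LOW = 0.3
P_HIGH = 3.0


class NotDisulfideCyclic(ValueError):
    """Record carries no disulfide bond; chain topology is undefined here."""


class BondConflictError(ValueError):
    """Two disulfide bonds share a cysteine position."""


@dataclass(frozen=True)
class LassoParams:
    L: int
    n1: int
    n2: int
    s: float
    p: Optional[float]  # None when n1 = 1 (no N-terminal tail ratio)


class StructureClass(str, Enum):
    C_LL = "C-LL"
    N_LL = "N-LL"
    HL = "HL"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class SingleBondCall:
    value: StructureClass
    params: LassoParams


def lasso_params(L: int, n1: int, n2: int) -> LassoParams:
    """Compute s and p for cysteines at n1 < n2 in a chain of length L."""
    if not (1 <= n1 < n2 <= L):
        raise DomainError(
            f"need 1 <= n1 < n2 <= L, got n1={n1}, n2={n2}, L={L}"
        )
    s = (L - n2 + n1 + 1) / L
    p = (L - n2) / (n1 - 1) if n1 > 1 else None
    return LassoParams(L=L, n1=n1, n2=n2, s=s, p=p)


def classify_single_dsb(
    L: int,
    n1: int,
    n2: int,
    *,
    s_cutoff: float = S_CUTOFF,
    p_low: float = P_LOW,
    p_high: float = P_HIGH,
) -> SingleBondCall:
    """Lasso-like vs hairpin-like call for a single disulfide bond.

    Tie-break: L - n2 = n1 is assigned C-LL (C-terminal loops dominate
    single-disulfide peptides overwhelmingly).
    """
    params = lasso_params(L, n1, n2)
    if params.s < s_cutoff:
        return SingleBondCall(StructureClass.HL, params)
    lasso = params.n1 == 1 or (
        params.p is not None and (params.p <= p_low or params.p >= p_high)
    )
    if not lasso:
        return SingleBondCall(StructureClass.AMBIGUOUS, params)
    c_tail = L - n2
    subtype = StructureClass.N_LL if c_tail > n1 else StructureClass.C_LL
    return SingleBondCall(subtype, params)


def loop_size(n1: int, n2: int) -> int:
    """Residues in the cyclized loop, both bridging positions included."""
    if n1 >= n2:
        raise DomainError(f"need n1 < n2, got ({n1}, {n2})")
    return n2 - n1 + 1


Matching = tuple[tuple[int, int], ...]


def count_matchings(k: int) -> int:
    """Number of perfect matchings of 2k points: (2k)! / (2^k k!)."""
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    return math.factorial(2 * k) // (2**k * math.factorial(k))


def enumerate_matchings(k: int) -> list[Matching]:
    """All perfect matchings of ordinals 1..2k, lexicographic on sorted pairs.

    Guarded to k <= 6 (10395 matchings at the guard) — beyond that the
    closed-form count suffices.
    """
    if not (1 <= k <= MAX_ENUMERATION_K):
        raise DomainError(
            f"enumeration supports 1 <= k <= {MAX_ENUMERATION_K}, got {k}"
        )

    def rec(remaining: tuple[int, ...]) -> Iterable[Matching]:
        if not remaining:
            yield ()
            return
        first, rest = remaining[0], remaining[1:]
        for idx, partner in enumerate(rest):
            pair = (first, partner)
            for tail in rec(rest[:idx] + rest[idx + 1:]):
                yield (pair,) + tail

    return sorted(rec(tuple(range(1, 2 * k + 1))))


def _normalize(matching: Iterable[Iterable[int]]) -> Matching:
    pairs = tuple(sorted(tuple(sorted(p)) for p in matching))
    flat = sorted(x for p in pairs for x in p)
    k = len(pairs)
    if flat != list(range(1, 2 * k + 1)):
        raise DomainError(
            f"pairs must partition ordinals 1..{2 * k}, got {pairs}"
        )
    return pairs


def crossing_count(matching: Iterable[Iterable[int]]) -> int:
    """Number of crossing chord pairs (a1 < a2 < b1 < b2)."""
    pairs = _normalize(matching)
    n = 0
    for i, (a1, b1) in enumerate(pairs):
        for a2, b2 in pairs[i + 1:]:
            lo, hi = ((a1, b1), (a2, b2)) if a1 < a2 else ((a2, b2), (a1, b1))
            if lo[0] < hi[0] < lo[1] < hi[1]:
                n += 1
    return n


class PairingScheme(str, Enum):
    LD = "LD"       # ladder-like: fully nested {i, 2k+1-i}
    SR = "SR"       # string of rings: sequential {2i-1, 2i}
    CR = "CR"       # crossed rings: >= 1 chord crossing
    MIXED = "MIXED"  # non-crossing but neither pure scheme


@dataclass(frozen=True)
class PairingClass:
    value: PairingScheme
    crossing_count: int


def ladder_matching(k: int) -> Matching:
    return tuple((i, 2 * k + 1 - i) for i in range(1, k + 1))


def string_matching(k: int) -> Matching:
    return tuple((2 * i - 1, 2 * i) for i in range(1, k + 1))


def classify_matching(matching: Iterable[Iterable[int]]) -> PairingClass:
    """LD / SR / CR / MIXED call for a cysteine pairing."""
    pairs = _normalize(matching)
    k = len(pairs)
    xings = crossing_count(pairs)
    if xings > 0:
        return PairingClass(PairingScheme.CR, xings)
    if pairs == ladder_matching(k):
        return PairingClass(PairingScheme.LD, 0)
    if pairs == string_matching(k):
        return PairingClass(PairingScheme.SR, 0)
    return PairingClass(PairingScheme.MIXED, 0)


@dataclass(frozen=True)
class TopologyCall:
    """Structure class of a disulfide-bonded peptide."""

    k: int
    label: str                 # C-LL / N-LL / HL / AMBIGUOUS or LD / SR / CR / MIXED
    crossing_count: int
    s: Optional[float] = None  # k = 1 only
    p: Optional[float] = None  # k = 1 only, None also when n1 = 1
    loop_sizes: tuple[int, ...] = ()


def classify_peptide_topology(
    record: PeptideRecord,
    *,
    strict_three_class: bool = False,
    s_cutoff: float = S_CUTOFF,
    p_low: float = P_LOW,
    p_high: float = P_HIGH,
) -> TopologyCall:
    """Topology call for a record from its annotated disulfide bonds.

    Cysteine ordinals are derived from the disulfide bond endpoints sorted by
    chain position — free or nonstandard cysteines in the sequence do not
    perturb the matching.  With ``strict_three_class`` the MIXED label is
    folded into SR (three-class output: nested ladders, rings in a row or
    nested without crossing, crossed rings).
    """
    dsbs = [b for b in record.bonds if b.kind is BondKind.DSB]
    if not dsbs:
        raise NotDisulfideCyclic(
            f"record {record.chain.id!r} has no disulfide bond"
        )
    endpoints = sorted(p for b in dsbs for p in (b.pos1, b.pos2))
    if len(set(endpoints)) != len(endpoints):
        raise BondConflictError(
            f"record {record.chain.id!r}: a position is shared by two "
            f"disulfide bonds"
        )
    loops = tuple(loop_size(b.pos1, b.pos2) for b in dsbs)
    if len(dsbs) == 1:
        bond = dsbs[0]
        call = classify_single_dsb(
            record.chain.length, bond.pos1, bond.pos2,
            s_cutoff=s_cutoff, p_low=p_low, p_high=p_high,
        )
        return TopologyCall(
            k=1,
            label=call.value.value,
            crossing_count=0,
            s=call.params.s,
            p=call.params.p,
            loop_sizes=loops,
        )
    ordinal = {pos: i + 1 for i, pos in enumerate(endpoints)}
    matching = [(ordinal[b.pos1], ordinal[b.pos2]) for b in dsbs]
    pairing = classify_matching(matching)
    label = pairing.value
    if strict_three_class and label is PairingScheme.MIXED:
        label = PairingScheme.SR
    return TopologyCall(
        k=len(dsbs),
        label=label.value,
        crossing_count=pairing.crossing_count,
        loop_sizes=loops,
    )
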