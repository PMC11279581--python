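"""Domain types for small cyclic peptide records.

A peptide is an ordered chain of residue tokens — one-letter codes for the
twenty proteinogenic amino acids plus bracketed multi-character tokens (e.g.
``[Orn]``) for nonstandard residues — cyclized by zero or more ring-closing
intrachain bonds.  Positions are 1-based and inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: The twenty standard one-letter residue codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Symbol under which bracketed (nonstandard) tokens are pooled in
#: composition statistics.
UNUSUAL_SYMBOL = "X"

_TOKEN_RE = re.compile(r"\[([^\[\]]+)\]|([A-Za-z])")


class DomainError(ValueError):
    """Input violates a documented precondition."""


def tokenize(sequence: str) -> list[str]:
    """Split a sequence string into residue tokens.

    Single letters must belong to the standard alphabet; anything inside
    square brackets is carried verbatim as one opaque token.
    """
    tokens: list[str] = []
    pos = 0
    for m in _TOKEN_RE.finditer(sequence):
        if m.start() != pos:
            raise DomainError(
                f"unparseable sequence at offset {pos}: {sequence[pos:pos + 5]!r}"
            )
        if m.group(1) is not None:
            tokens.append(f"[{m.group(1)}]")
        else:
            letter = m.group(2).upper()
            if letter not in STANDARD_RESIDUES:
                raise DomainError(f"unknown residue letter {letter!r}")
            tokens.append(letter)
        pos = m.end()
    if pos != len(sequence):
        raise DomainError(f"trailing junk in sequence: {sequence[pos:]!r}")
    if not tokens:
        raise DomainError("empty sequence")
    return tokens


def token_symbol(token: str) -> str:
    """Composition symbol for a token: itself, or the pooled unusual class."""
    return UNUSUAL_SYMBOL if token.startswith("[") else token


@dataclass(frozen=True)
class ResidueChain:
    """An identified residue chain; ``length`` counts tokens."""

    id: str
    tokens: tuple[str, ...]

    @classmethod
    def from_sequence(cls, id: str, sequence: str) -> "ResidueChain":
        return cls(id=id, tokens=tuple(tokenize(sequence)))

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def sequence(self) -> str:
        return "".join(self.tokens)


class SizeClass(str, Enum):
    USP = "USP"   # ultra-short, length <= 5
    SP = "SP"     # short, length 6..25
    LARGE = "LARGE"


def size_class(length: int) -> SizeClass:
    """Size class of a chain: USP (<=5), SP (6-25) or LARGE (>25)."""
    if not isinstance(length, int) or isinstance(length, bool) or length < 1:
        raise DomainError(f"length must be a positive integer, got {length!r}")
    if length <= 5:
        return SizeClass.USP
    if length <= 25:
        return SizeClass.SP
    return SizeClass.LARGE


def is_small(length: int) -> bool:
    """Small = ultra-short or short (<= 25 residues)."""
    return size_class(length) is not SizeClass.LARGE


class BondKind(str, Enum):
    AMD = "AMD"  # amide
    EST = "EST"  # ester
    ETH = "ETH"  # ether
    TIE = "TIE"  # thioether (sulfide)
    DSB = "DSB"  # disulfide
    AMN = "AMN"  # amine
    IMN = "IMN"  # imine
    CAR = "CAR"  # carbon


class Linkage(str, Enum):
    MMB = "MMB"  # mainchain-mainchain
    SMB = "SMB"  # sidechain-mainchain
    SSB = "SSB"  # sidechain-sidechain


class Saturation(str, Enum):
    SATURATED = "saturated"
    ONE_DOUBLE_BOND = "one_double_bond"
    TWO_DOUBLE_BONDS = "two_double_bonds"


@dataclass(frozen=True)
class BondQualifier:
    """Optional chemical detail used to refine coarse ring labels."""

    ring_members: Optional[int] = None        # small-ring atom count
    saturation: Optional[Saturation] = None
    methylated: Optional[bool] = None
    alpha_carbon: Optional[bool] = None       # disulfide between two C-alpha
    residue1: Optional[str] = None            # residue token at pos1
    residue2: Optional[str] = None            # residue token at pos2


@dataclass(frozen=True)
class IntrachainBond:
    """One ring-closing covalent bond between two chain positions.

    Invariants (1 <= pos1 <= pos2 <= L; distinct positions for a disulfide)
    are checked by :func:`validate_record`, which reports rather than aborts,
    so deliberately broken bonds remain constructible for validation tests.
    """

    kind: BondKind
    linkage: Linkage
    pos1: int
    pos2: int
    head_to_tail: bool = False
    qualifier: Optional[BondQualifier] = None


class Synthesis(str, Enum):
    RIBOSOMAL = "ribosomal"
    NONRIBOSOMAL = "nonribosomal"


class GramClass(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


KINGDOMS = frozenset(
    {"Animalia", "Plantae", "Protista", "Fungi", "Bacteria", "Archaea"}
)


@dataclass(frozen=True)
class MICMeasurement:
    strain: str
    gram: Optional[GramClass]
    value: float          # concentration, > 0
    unit: str             # "ug/mL" or "uM"


@dataclass
class PeptideRecord:
    """One peptide entry: chain, synthesis route, ring-closing bonds, MICs.

    ``truth`` is a sidecar label written only by the synthetic generator and
    never read by any analysis stage.
    """

    chain: ResidueChain
    synthesis: Synthesis
    bonds: tuple[IntrachainBond, ...] = ()
    source_kingdom: Optional[str] = None
    target_object: Optional[str] = None
    mic: tuple[MICMeasurement, ...] = ()
    truth: Optional[str] = field(default=None, compare=False)

    @property
    def is_cyclic(self) -> bool:
        return len(self.bonds) > 0


def validate_record(record: PeptideRecord) -> list[str]:
    """Collect invariant violations; empty list means the record is valid.

    Validation never raises: each violation yields one message, in a stable
    order (chain first, then bonds in sequence order, then metadata).
    """
    messages: list[str] = []
    L = record.chain.length
    if L < 1:
        messages.append("chain must contain at least one residue")
    for i, tok in enumerate(record.chain.tokens, start=1):
        if not tok.startswith("[") and tok not in STANDARD_RESIDUES:
            messages.append(f"residue {i}: unknown token {tok!r}")
    for j, bond in enumerate(record.bonds, start=1):
        if bond.pos1 < 1 or bond.pos2 > L:
            messages.append(f"bond {j}: bond position out of range")
        if bond.pos1 > bond.pos2:
            messages.append(f"bond {j}: pos1 exceeds pos2")
        if bond.kind is BondKind.DSB and bond.pos1 == bond.pos2:
            messages.append(f"bond {j}: disulfide requires two distinct positions")
        if bond.head_to_tail and not (bond.pos1 == 1 and bond.pos2 == L):
            messages.append(
                f"bond {j}: head-to-tail bond must span positions 1..{L}"
            )
    if record.source_kingdom is not None and record.source_kingdom not in KINGDOMS:
        messages.append(f"unknown source kingdom {record.source_kingdom!r}")
    for k, m in enumerate(record.mic, start=1):
        if not m.value > 0:
            messages.append(f"mic {k}: non-positive concentration")
    return messages
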