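"""Ring ontology for cyclized peptides.

Every ring-closing intrachain bond is characterized by three parameters —
bond kind (amide, ester, ether, thioether, disulfide, amine, imine, carbon),
linkage (mainchain-mainchain, sidechain-mainchain, sidechain-sidechain), and
the ring it closes.  The mapping from (kind, linkage) plus chemical
qualifiers (small-ring atom count, saturation, methylation, residue
identities) to a ring label is a closed vocabulary; missing qualifiers yield
a coarse GENERIC label rather than a guessed chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import (
    BondKind,
    BondQualifier,
    IntrachainBond,
    Linkage,
    PeptideRecord,
    Saturation,
)

AROMATIC = frozenset("FWY")


class RingLabel(str):
    pass


#: Closed ring vocabulary.
RING_LABELS = frozenset(
    {
        "THZN", "THZD", "THZ", "TZ", "AVC", "MeAVC", "LAN", "MeLAN",
        "OXZN", "MeOXZN", "OXZ", "MeOXZ", "LCN", "CST", "DSL", "NCB",
        "LAC", "DKP", "BLAC", "DLAC", "PRL", "BAR", "PYR",
        "GENERIC", "UNRESOLVED",
    }
)

#: (kind, linkage) pairs admitted by the ontology.
VALID_COMBINATIONS = frozenset(
    {
        (BondKind.TIE, Linkage.SMB),
        (BondKind.TIE, Linkage.SSB),
        (BondKind.ETH, Linkage.SMB),
        (BondKind.ETH, Linkage.SSB),
        (BondKind.EST, Linkage.SMB),
        (BondKind.EST, Linkage.MMB),
        (BondKind.DSB, Linkage.SSB),
        (BondKind.AMD, Linkage.MMB),
        (BondKind.AMD, Linkage.SMB),
        (BondKind.IMN, Linkage.MMB),
        (BondKind.AMN, Linkage.SMB),
        (BondKind.AMN, Linkage.SSB),
        (BondKind.CAR, Linkage.SMB),
        (BondKind.CAR, Linkage.SSB),
        (BondKind.CAR, Linkage.MMB),
    }
)


class OntologyError(ValueError):
    """A (kind, linkage) pair outside the ring ontology."""

    def __init__(self, kind: BondKind, linkage: Linkage):
        self.pair = (kind, linkage)
        super().__init__(
            f"no ring is formed by bond kind {kind.value} with linkage "
            f"{linkage.value}"
        )


@dataclass(frozen=True)
class RingCall:
    """A ring label plus a coarseness flag (qualifiers were insufficient)."""

    label: str
    coarse: bool = False

    def __post_init__(self):
        assert self.label in RING_LABELS
        if self.label in ("GENERIC", "UNRESOLVED"):
            assert self.coarse


_GENERIC = RingCall("GENERIC", coarse=True)


def _methyl(base: str, methylated) -> str:
    return ("Me" + base) if methylated else base


def _thioether(linkage: Linkage, q: BondQualifier) -> RingCall:
    if linkage is Linkage.SMB:
        # five-membered Cys-to-mainchain rings: thiazolidine/-line/-ole
        if q.ring_members == 5 and q.saturation is not None:
            return RingCall(
                {
                    Saturation.SATURATED: "THZD",
                    Saturation.ONE_DOUBLE_BOND: "THZN",
                    Saturation.TWO_DOUBLE_BONDS: "THZ",
                }[q.saturation]
            )
        return _GENERIC
    # sidechain-sidechain: small rings or macrolactam-scale lanthionines
    if q.ring_members == 5 and q.saturation is Saturation.SATURATED:
        return RingCall("THZD")
    if q.ring_members == 6 and q.saturation is Saturation.TWO_DOUBLE_BONDS:
        return RingCall("TZ")
    if (q.ring_members is None or q.ring_members > 6) and q.saturation is not None:
        if q.saturation is Saturation.SATURATED:
            return RingCall(_methyl("LAN", q.methylated))
        if q.saturation is Saturation.ONE_DOUBLE_BOND:
            return RingCall(_methyl("AVC", q.methylated))
    return _GENERIC


def _ether(linkage: Linkage, q: BondQualifier) -> RingCall:
    if linkage is Linkage.SSB:
        return RingCall("LAC")
    if q.ring_members == 5:
        if q.saturation is Saturation.ONE_DOUBLE_BOND:
            return RingCall(_methyl("OXZN", q.methylated))
        if q.saturation is Saturation.TWO_DOUBLE_BONDS:
            return RingCall(_methyl("OXZ", q.methylated))
    return _GENERIC


def _disulfide(q: BondQualifier) -> RingCall:
    if q.alpha_carbon:
        return RingCall("DSL")
    if q.residue1 == "C" and q.residue2 == "C":
        return RingCall("CST")
    return _GENERIC


def _amine(linkage: Linkage, q: BondQualifier) -> RingCall:
    if linkage is Linkage.SSB:
        return RingCall("LAC")
    if q.ring_members == 4:
        return RingCall("BLAC")
    if q.ring_members == 5:
        return RingCall("PRL")
    if q.ring_members == 6:
        return RingCall("DLAC")
    if q.ring_members is not None and q.ring_members > 6:
        return RingCall("LAC")
    return _GENERIC


def _carbon(linkage: Linkage, q: BondQualifier) -> RingCall:
    if linkage is Linkage.SMB:
        return RingCall("LAC")
    if linkage is Linkage.MMB:
        return RingCall("PYR")
    if q.ring_members == 6:
        return RingCall("PYR")
    if q.residue1 in AROMATIC and q.residue2 in AROMATIC:
        return RingCall("BAR")  # biaryl staple between two aryl sidechains
    if q.ring_members is not None and q.ring_members > 6:
        return RingCall("LAC")
    return _GENERIC


def classify_ring(bond: IntrachainBond, chain_length: int) -> RingCall:
    """Ring label closed by ``bond`` in a chain of ``chain_length`` residues.

    Pure function of its arguments.  Raises :class:`OntologyError` for a
    (kind, linkage) pair outside the ontology; returns a coarse GENERIC call
    when the qualifiers cannot discriminate between sibling ring types.
    """
    if (bond.kind, bond.linkage) not in VALID_COMBINATIONS:
        raise OntologyError(bond.kind, bond.linkage)
    q = bond.qualifier or BondQualifier()

    if bond.kind is BondKind.EST:
        return RingCall("LCN")
    if bond.kind is BondKind.AMD:
        if bond.linkage is Linkage.SMB:
            return RingCall("LAC")
        if bond.head_to_tail:
            return RingCall("DKP" if chain_length == 2 else "NCB")
        return _GENERIC
    if bond.kind is BondKind.IMN:
        return RingCall("LAC")
    if bond.kind is BondKind.DSB:
        return _disulfide(q)
    if bond.kind is BondKind.TIE:
        return _thioether(bond.linkage, q)
    if bond.kind is BondKind.ETH:
        return _ether(bond.linkage, q)
    if bond.kind is BondKind.AMN:
        return _amine(bond.linkage, q)
    return _carbon(bond.linkage, q)  # CAR


def classify_record_rings(record: PeptideRecord) -> list[RingCall]:
    """Ring calls for every bond of a record.

    Residue identities missing from a bond qualifier are filled in from the
    chain before classification (a disulfide between two sequence cysteines
    is a cystine ring even when the record omits the qualifier).
    """
    calls = []
    for bond in record.bonds:
        q = bond.qualifier or BondQualifier()
        if q.residue1 is None or q.residue2 is None:
            q = BondQualifier(
                ring_members=q.ring_members,
                saturation=q.saturation,
                methylated=q.methylated,
                alpha_carbon=q.alpha_carbon,
                residue1=q.residue1 or record.chain.tokens[bond.pos1 - 1],
                residue2=q.residue2 or record.chain.tokens[bond.pos2 - 1],
            )
            bond = IntrachainBond(
                kind=bond.kind,
                linkage=bond.linkage,
                pos1=bond.pos1,
                pos2=bond.pos2,
                head_to_tail=bond.head_to_tail,
                qualifier=q,
            )
        calls.append(classify_ring(bond, record.chain.length))
    return calls
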