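"""Synthetic DBAASP-like peptide records with planted ground truth.

The generator emulates the record structure of a curated antimicrobial
peptide database — short chains (by default up to 25 residues), disulfide
bonds placed to realize a requested chain topology with a margin away from
every classification threshold, controllable residue composition, an
optional planted cysteine-pair spacing enrichment, and paired linear/cyclic
MIC values on a two-fold dilution grid with a planted cyclization effect
and single-dilution noise.

Planted truth labels travel in the record's sidecar ``truth`` field, which
no analysis stage reads: every closed-loop test recovers the label from the
record content alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .records import (
    BondKind,
    BondQualifier,
    GramClass,
    IntrachainBond,
    Linkage,
    PeptideRecord,
    ResidueChain,
    Synthesis,
)
from .potency import MICPair
from .topology import ladder_matching, string_matching

STANDARD20 = "ACDEFGHIKLMNPQRSTVWY"

#: Uniform default background over the twenty standard residues.
UNIFORM_BACKGROUND: dict[str, float] = {aa: 1 / 20 for aa in STANDARD20}

#: Qualitative preset mirroring the elevated Cys/Gly content of ribosomal
#: short cyclic peptides (illustrative proportions, not measured ones).
CYS_GLY_ENRICHED_BACKGROUND: dict[str, float] = {
    **{aa: 0.8 / 18 for aa in STANDARD20 if aa not in "CG"},
    "C": 0.10,
    "G": 0.10,
}

#: Single-bond topology classes and multi-bond pairing schemes.
SINGLE_CLASSES = ("C-LL", "N-LL", "HL")
MULTI_CLASSES = ("LD", "SR", "CR", "MIXED")
ALL_CLASSES = SINGLE_CLASSES + MULTI_CLASSES + ("LINEAR",)


class ConfigurationError(ValueError):
    """The generator configuration is internally infeasible."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic corpus.

    ``class_mix`` fractions must sum to 1; the default mix mirrors the
    qualitative prevalences of the structural classes in curated data
    (C-terminal lassos dominate single-disulfide peptides, ladders dominate
    two-disulfide ones, crossings take over at three or more).
    """

    n_peptides: int = 100
    seed: int = 0
    length_range: tuple[int, int] = (6, 25)
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "C-LL": 0.40,
            "N-LL": 0.05,
            "HL": 0.20,
            "LD": 0.15,
            "SR": 0.05,
            "CR": 0.10,
            "MIXED": 0.05,
        }
    )
    k_distribution: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.60, 3: 0.25, 4: 0.15}
    )
    residue_background: Mapping[str, float] = field(
        default_factory=lambda: dict(UNIFORM_BACKGROUND)
    )
    planted_spacing: Optional[tuple[int, float]] = None  # (spacing, fold)
    min_cys_spacing: int = 2  # steric floor: no bonded pair closer than this
    # MIC generator: two-fold grid 2**min_exp .. 2**max_exp (ug/mL)
    mic_grid_exponents: tuple[int, int] = (-1, 8)
    cyclization_effect: int = -2      # planted shift, dilutions
    noise_probability: float = 0.25   # per side, one dilution
    mic_unit: str = "ug/mL"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_mix sums to {total}, not 1")
        unknown = set(self.class_mix) - set(ALL_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown classes in mix: {sorted(unknown)}")
        lo, hi = self.length_range
        if not (2 <= lo <= hi <= 25):
            raise ConfigurationError(
                f"length range must lie within 2..25, got {self.length_range}"
            )
        if self.min_cys_spacing < 0:
            raise ConfigurationError("min_cys_spacing must be >= 0")
        if not (0 <= self.noise_probability <= 0.5):
            raise ConfigurationError("noise_probability must be in [0, 0.5]")


def _min_length(cls: str, k: int, gap: int) -> int:
    """Smallest chain length at which the class is placeable with margin."""
    if cls in ("C-LL", "N-LL"):
        return 15   # keeps s >= 0.6 with a 7-8 residue loop
    if cls == "HL":
        return 12   # keeps s <= 1/3 with near-terminal cysteines
    if cls == "LINEAR":
        return 2
    # multi-bond: 2k positions with consecutive gaps >= gap + 1
    return (gap + 1) * (2 * k - 1) + 1


def _draw_background(rng: np.random.Generator, n: int,
                     background: Mapping[str, float]) -> list[str]:
    symbols = sorted(background)
    probs = np.array([background[s] for s in symbols], dtype=float)
    probs = probs / probs.sum()
    return list(rng.choice(symbols, size=n, p=probs))


def _place_positions(rng: np.random.Generator, L: int, n_pos: int,
                     min_diff: int) -> list[int]:
    """n_pos increasing positions in 1..L, consecutive differences >= min_diff."""
    slack = min_diff - 1
    reduced = L - slack * (n_pos - 1)
    q = np.sort(rng.choice(np.arange(1, reduced + 1), size=n_pos, replace=False))
    return [int(q[j] + slack * j) for j in range(n_pos)]


def _crossed_matching(k: int) -> tuple[tuple[int, int], ...]:
    # every chord crosses every other: {i, i + k}
    return tuple((i, i + k) for i in range(1, k + 1))


def _mixed_matching(k: int) -> tuple[tuple[int, int], ...]:
    # one enclosing chord over a string of rings: non-crossing, neither pure
    inner = tuple((2 * i, 2 * i + 1) for i in range(1, k))
    return ((1, 2 * k),) + inner


def _sample_k(rng: np.random.Generator, config: SynthConfig, cls: str) -> int:
    hi = config.length_range[1]
    feasible = {
        k: w
        for k, w in config.k_distribution.items()
        if _min_length(cls, k, config.min_cys_spacing) <= hi
        and (cls != "MIXED" or k >= 3)
        and k >= 2
    }
    if not feasible:
        raise ConfigurationError(
            f"class {cls}: no bond count in k_distribution fits within "
            f"length {hi} (min spacing {config.min_cys_spacing})"
        )
    ks = sorted(feasible)
    probs = np.array([feasible[k] for k in ks], dtype=float)
    return int(rng.choice(ks, p=probs / probs.sum()))


def _make_record(rng: np.random.Generator, config: SynthConfig,
                 cls: str, index: int) -> PeptideRecord:
    lo, hi = config.length_range
    gap = config.min_cys_spacing

    if cls in SINGLE_CLASSES or cls == "LINEAR":
        k = 0 if cls == "LINEAR" else 1
        min_L = _min_length(cls, k, gap)
        if min_L > hi:
            raise ConfigurationError(
                f"class {cls} needs length >= {min_L}, range caps at {hi}"
            )
        L = int(rng.integers(max(min_L, lo), hi + 1))
        pairs_pos: list[tuple[int, int]] = []
        if cls == "C-LL":
            loop = int(rng.integers(7, 9))          # 7-8 residues incl. Cys
            n2 = L - int(rng.integers(0, 2))        # C-tail of 0-1 residues
            pairs_pos = [(n2 - loop + 1, n2)]
        elif cls == "N-LL":
            loop = int(rng.integers(7, 9))
            pairs_pos = [(1, loop)]
        elif cls == "HL":
            n1 = int(rng.integers(1, 3))            # within 2 of N-terminus
            n2 = L - int(rng.integers(0, 2))        # within 1 of C-terminus
            pairs_pos = [(n1, n2)]
    else:
        k = _sample_k(rng, config, cls)
        min_L = _min_length(cls, k, gap)
        L = int(rng.integers(max(min_L, lo), hi + 1))
        positions = _place_positions(rng, L, 2 * k, gap + 1)
        scheme = {
            "LD": ladder_matching,
            "SR": string_matching,
            "CR": _crossed_matching,
            "MIXED": _mixed_matching,
        }[cls](k)
        pairs_pos = [(positions[a - 1], positions[b - 1]) for a, b in scheme]

    tokens = _draw_background(rng, L, config.residue_background)
    bonds = []
    for p1, p2 in pairs_pos:
        tokens[p1 - 1] = "C"
        tokens[p2 - 1] = "C"
        bonds.append(
            IntrachainBond(
                kind=BondKind.DSB,
                linkage=Linkage.SSB,
                pos1=p1,
                pos2=p2,
                qualifier=BondQualifier(residue1="C", residue2="C"),
            )
        )
    return PeptideRecord(
        chain=ResidueChain(id=f"SYN{index:05d}", tokens=tuple(tokens)),
        synthesis=Synthesis.RIBOSOMAL,
        bonds=tuple(bonds),
        truth=cls,
    )


def _plant_spacing(rng: np.random.Generator, records: list[PeptideRecord],
                   spacing: int, fold: float) -> None:
    """Overwrite residue pairs so the spacing count reaches ~fold x baseline.

    The number of planted pairs is (fold - 1) times the closed-form expected
    count of the corpus as generated, so the observed count lands near fold
    times the positional-exchangeability expectation.
    """
    from .seqstats import _analytic_expected, _encode_corpus

    arrays, a, b = _encode_corpus([r.chain for r in records], ("C", "C"))
    baseline = _analytic_expected(arrays, a, b, spacing)[spacing]
    n_plant = int(round(max(fold - 1.0, 0.0) * baseline))
    eligible = [i for i, r in enumerate(records)
                if r.chain.length >= spacing + 2]
    if n_plant > len(eligible):
        raise ConfigurationError(
            f"cannot plant {n_plant} spacing-{spacing} pairs into "
            f"{len(eligible)} eligible records"
        )
    chosen = rng.choice(eligible, size=n_plant, replace=False)
    for i in chosen:
        rec = records[int(i)]
        L = rec.chain.length
        start = int(rng.integers(1, L - spacing))  # 1-based first position
        tokens = list(rec.chain.tokens)
        tokens[start - 1] = "C"
        tokens[start + spacing] = "C"
        records[int(i)] = PeptideRecord(
            chain=ResidueChain(id=rec.chain.id, tokens=tuple(tokens)),
            synthesis=rec.synthesis,
            bonds=rec.bonds,
            source_kingdom=rec.source_kingdom,
            target_object=rec.target_object,
            mic=rec.mic,
            truth=rec.truth,
        )


def generate_peptides(config: SynthConfig) -> list[PeptideRecord]:
    """Generate a corpus of records with planted, margined topology classes.

    Deterministic under ``config.seed``; truth labels sit in the sidecar
    ``truth`` field only.
    """
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(classes, size=config.n_peptides, p=probs)
    records = [
        _make_record(rng, config, cls, i) for i, cls in enumerate(draws)
    ]
    if config.planted_spacing is not None:
        spacing, fold = config.planted_spacing
        _plant_spacing(rng, records, int(spacing), float(fold))
    return records


def generate_mic_pairs(config: SynthConfig) -> list[MICPair]:
    """Paired linear/cyclic MICs on a two-fold grid with a planted effect.

    The linear MIC is drawn from the interior of the grid, the cyclic MIC is
    the linear one shifted by ``cyclization_effect`` dilutions, then moved
    one further dilution up or down with ``noise_probability`` each.  Values
    pushed off the grid are clamped and flagged.  The first half of the
    pairs forms the disulfide (DSB) set with longer chains, the second half
    the head-to-tail (HT) set with 6-9-mers, and gram classes alternate.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo_e, hi_e = config.mic_grid_exponents
    effect = config.cyclization_effect
    if lo_e + abs(effect) + 1 > hi_e - abs(effect) - 1:
        raise ConfigurationError("MIC grid too narrow for the planted effect")
    pairs: list[MICPair] = []
    n = config.n_peptides
    for i in range(n):
        bond_set = "DSB" if i < n / 2 else "HT"
        length = int(rng.integers(13, 25)) if bond_set == "DSB" else int(
            rng.integers(6, 10)
        )
        seq = "".join(_draw_background(rng, length, config.residue_background))
        lin_exp = int(
            rng.integers(lo_e + abs(effect) + 1, hi_e - abs(effect))
        )
        cyc_exp = lin_exp + effect
        u = rng.random()
        if u < config.noise_probability:
            cyc_exp -= 1
        elif u < 2 * config.noise_probability:
            cyc_exp += 1
        clamped = False
        if cyc_exp < lo_e:
            cyc_exp, clamped = lo_e, True
        elif cyc_exp > hi_e:
            cyc_exp, clamped = hi_e, True
        gram = GramClass.NEGATIVE if i % 2 == 0 else GramClass.POSITIVE
        strain = "E. coli ATCC 25922" if gram is GramClass.NEGATIVE \
            else "S. aureus ATCC 25923"
        pairs.append(
            MICPair(
                id=f"PAIR{i:04d}",
                sequence=seq,
                mic_linear=float(2.0**lin_exp),
                mic_cyclic=float(2.0**cyc_exp),
                unit=config.mic_unit,
                bond_set=bond_set,
                strain=strain,
                gram=gram,
                clamped=clamped,
            )
        )
    return pairs
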