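"""Cyclization impact on potency: the ΔMIC statistic.

For a pair of peptides with identical sequence, one linear and one cyclic,
the signed log2 ratio r = log2(MIC_cyclic / MIC_linear) expresses the
potency difference in two-fold dilution units (negative r: the cyclic form
is more potent, i.e. has the lower MIC).  Because the broth microdilution
assay resolves potencies only to one dilution step, a difference is called
reliable only when it reaches two or more dilutions; pairs within one
dilution are indistinguishable.  ΔMIC is r rounded to the nearest integer
dilution (half away from zero); the raw r is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import DomainError, GramClass

RELIABILITY_CUTOFF = 2  # dilutions


class Direction(str, Enum):
    CYCLIC_MORE_POTENT = "cyclic_more_potent"
    LINEAR_MORE_POTENT = "linear_more_potent"
    INDISTINGUISHABLE = "indistinguishable"


@dataclass(frozen=True)
class MICPair:
    """Paired MICs of a linear peptide and its cyclized counterpart."""

    id: str
    sequence: str
    mic_linear: float
    mic_cyclic: float
    unit: str = "ug/mL"
    bond_set: str = "DSB"       # DSB or HT
    strain: str = ""
    gram: Optional[GramClass] = None
    clamped: bool = False       # generator flag: effect pushed MIC off-grid


@dataclass(frozen=True)
class DeltaMICResult:
    r: float                    # signed log2 ratio, dilution units
    delta_mic: int              # r rounded half away from zero
    reliable: bool
    direction: Direction


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def delta_mic(
    mic_c: float,
    mic_l: float,
    *,
    unit_c: Optional[str] = None,
    unit_l: Optional[str] = None,
    reliability_cutoff: int = RELIABILITY_CUTOFF,
) -> DeltaMICResult:
    """ΔMIC for one cyclic/linear pair (lower MIC = more potent)."""
    if unit_c is not None and unit_l is not None and unit_c != unit_l:
        raise DomainError(f"unit mismatch: {unit_c!r} vs {unit_l!r}")
    if not (mic_c > 0 and mic_l > 0):
        raise DomainError("MIC values must be positive")
    # as a difference of logs so antisymmetry in the two arguments is exact
    r = math.log2(mic_c) - math.log2(mic_l)
    d = _round_half_away(r)
    reliable = abs(d) >= reliability_cutoff
    if not reliable:
        direction = Direction.INDISTINGUISHABLE
    elif d < 0:
        direction = Direction.CYCLIC_MORE_POTENT
    else:
        direction = Direction.LINEAR_MORE_POTENT
    return DeltaMICResult(r=r, delta_mic=d, reliable=reliable, direction=direction)


def delta_mic_pair(pair: MICPair, **kwargs) -> DeltaMICResult:
    return delta_mic(pair.mic_cyclic, pair.mic_linear, **kwargs)


_GROUPABLE = ("bond_set", "gram", "strain")


def summarize_pairs(
    pairs: Sequence[MICPair],
    group_keys: Iterable[str] = ("bond_set",),
    *,
    reliability_cutoff: int = RELIABILITY_CUTOFF,
) -> pd.DataFrame:
    """Per-group ΔMIC summary table.

    Columns: the group keys, n, counts per direction, median ΔMIC and the
    fraction of pairs within one dilution; rows sorted by group key.
    """
    if not pairs:
        raise DomainError("no MIC pairs supplied")
    keys = list(group_keys)
    for key in keys:
        if key not in _GROUPABLE:
            raise DomainError(f"cannot group by {key!r}; allowed: {_GROUPABLE}")
    rows = []
    for p in pairs:
        res = delta_mic_pair(p, reliability_cutoff=reliability_cutoff)
        rows.append(
            {
                "bond_set": p.bond_set,
                "gram": p.gram.value if p.gram else "",
                "strain": p.strain,
                "r": res.r,
                "delta_mic": res.delta_mic,
                "direction": res.direction.value,
            }
        )
    df = pd.DataFrame(rows)
    if not keys:
        df["_all"] = "all"
        keys = ["_all"]
    grouped = df.groupby(keys, sort=True)
    out = grouped.agg(
        n=("delta_mic", "size"),
        n_cyclic_more_potent=(
            "direction", lambda s: int((s == Direction.CYCLIC_MORE_POTENT.value).sum())
        ),
        n_linear_more_potent=(
            "direction", lambda s: int((s == Direction.LINEAR_MORE_POTENT.value).sum())
        ),
        n_indistinguishable=(
            "direction", lambda s: int((s == Direction.INDISTINGUISHABLE.value).sum())
        ),
        median_delta_mic=("delta_mic", "median"),
        frac_within_one_dilution=(
            "delta_mic", lambda s: float((s.abs() <= 1).mean())
        ),
    ).reset_index()
    if keys == ["_all"]:
        out = out.drop(columns="_all")
    return out
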