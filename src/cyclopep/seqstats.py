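"""Residue-pair spacing statistics (DiSAAP) and composition enrichment.

The distribution of i-spaced amino-acid pairs counts, over a sequence set,
ordered pairs of residues with exactly ``i`` residues strictly between them
(i = 0 means adjacent).  The null model is a within-sequence,
composition-preserving shuffle: each null sequence is an exact anagram of
its original, so the null isolates positional structure from composition.
A closed-form positional-exchangeability expectation is available as a
cheaper secondary check: for one sequence of length L the expected count at
spacing i is

    (L - i - 1) * m_a * m_b / (L (L - 1))        distinct symbols a, b
    (L - i - 1) * m * (m - 1) / (L (L - 1))      identical symbols

where m_* are symbol multiplicities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from statsmodels.stats.multitest import multipletests

from .records import DomainError, ResidueChain, token_symbol, tokenize

SequenceLike = Union[str, Sequence[str], ResidueChain]


def _as_tokens(seq: SequenceLike) -> list[str]:
    if isinstance(seq, ResidueChain):
        return list(seq.tokens)
    if isinstance(seq, str):
        return tokenize(seq)
    return list(seq)


@dataclass(frozen=True)
class SpacingProfile:
    """Observed i-spaced pair counts pooled over a sequence set."""

    residue_pair: tuple[str, str]
    counts: tuple[int, ...]       # index i = spacing, 0..max_spacing
    n_sequences: int
    total_pairs: int              # all qualifying pairs at any spacing

    @property
    def frequencies(self) -> tuple[float, ...]:
        tot = sum(self.counts)
        return tuple(c / tot if tot else 0.0 for c in self.counts)


def _pair_counts(arr: np.ndarray, a: int, b: int, max_spacing: int) -> np.ndarray:
    """Counts per spacing for one encoded sequence (ordered pair a then b)."""
    L = arr.shape[0]
    out = np.zeros(max_spacing + 1, dtype=np.int64)
    for i in range(min(max_spacing + 1, L - 1)):
        out[i] = int(np.count_nonzero((arr[: L - i - 1] == a) & (arr[i + 1 :] == b)))
    return out


def _encode_corpus(
    sequences: Sequence[SequenceLike], pair: tuple[str, str]
) -> tuple[list[np.ndarray], int, int]:
    """Encode sequences as int arrays; the pair symbols get codes 0 and 1."""
    a_tok, b_tok = pair
    vocab: dict[str, int] = {a_tok: 0}
    vocab.setdefault(b_tok, 1)
    arrays = []
    for seq in sequences:
        toks = _as_tokens(seq)
        arrays.append(
            np.array([vocab.setdefault(t, len(vocab)) for t in toks], dtype=np.int16)
        )
    return arrays, vocab[a_tok], vocab[b_tok]


def disaap(
    sequences: Sequence[SequenceLike],
    pair: tuple[str, str] = ("C", "C"),
    max_spacing: int = 10,
) -> SpacingProfile:
    """Observed i-spaced pair counts for ``pair`` over ``sequences``.

    Ordered counting: position j holds the first symbol and j + i + 1 the
    second.  For identical symbols this counts each unordered occurrence
    exactly once (the earlier position is always "first").
    """
    if max_spacing < 0:
        raise DomainError("max_spacing must be >= 0")
    if not sequences:
        raise DomainError("empty sequence set")
    arrays, a, b = _encode_corpus(sequences, pair)
    counts = np.zeros(max_spacing + 1, dtype=np.int64)
    total = 0
    for arr in arrays:
        counts += _pair_counts(arr, a, b, max_spacing)
        # total over all spacings up to L - 2 (conservation denominator)
        total += int(
            _pair_counts(arr, a, b, max(arr.shape[0] - 2, 0)).sum()
        )
    return SpacingProfile(
        residue_pair=tuple(pair),
        counts=tuple(int(c) for c in counts),
        n_sequences=len(arrays),
        total_pairs=total,
    )


@dataclass(frozen=True)
class NullSummary:
    """Null distribution of spacing counts and per-spacing significance."""

    method: str                       # "shuffle" or "analytic"
    observed: tuple[int, ...]
    expected: tuple[float, ...]       # null mean per spacing
    sd: Optional[tuple[float, ...]]   # shuffle only
    z: Optional[tuple[float, ...]]    # shuffle only; nan flags degenerate sd
    p_two_sided: Optional[tuple[float, ...]]  # empirical, add-one smoothed
    bh_significant: Optional[tuple[bool, ...]]
    ratio: tuple[float, ...]          # observed / expected (inf on zero mean)
    n_shuffles: Optional[int]
    seed: Optional[int]


def _analytic_expected(
    arrays: Sequence[np.ndarray], a: int, b: int, max_spacing: int
) -> np.ndarray:
    expected = np.zeros(max_spacing + 1)
    spac = np.arange(max_spacing + 1)
    for arr in arrays:
        L = arr.shape[0]
        if L < 2:
            continue
        m_a = int(np.count_nonzero(arr == a))
        m_b = int(np.count_nonzero(arr == b))
        pairs = m_a * (m_a - 1) if a == b else m_a * m_b
        slots = np.clip(L - spac - 1, 0, None)
        expected += slots * pairs / (L * (L - 1))
    return expected


def disaap_null(
    sequences: Sequence[SequenceLike],
    pair: tuple[str, str] = ("C", "C"),
    max_spacing: int = 10,
    method: str = "shuffle",
    n_shuffles: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> NullSummary:
    """Null model for the spacing profile.

    ``shuffle`` permutes each sequence independently (exact anagrams) and
    reports per-spacing mean, sd, z and an empirical two-sided p with
    add-one smoothing, plus Benjamini-Hochberg significance across spacings.
    ``analytic`` reports the closed-form expectation and observed/expected
    ratios (no dispersion available).
    """
    obs = disaap(sequences, pair, max_spacing)
    arrays, a, b = _encode_corpus(sequences, pair)
    observed = np.array(obs.counts, dtype=float)

    if method == "analytic":
        expected = _analytic_expected(arrays, a, b, max_spacing)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(expected > 0, observed / expected, np.inf)
            ratio = np.where((expected == 0) & (observed == 0), 1.0, ratio)
        return NullSummary(
            method="analytic",
            observed=obs.counts,
            expected=tuple(expected),
            sd=None, z=None, p_two_sided=None, bh_significant=None,
            ratio=tuple(ratio),
            n_shuffles=None, seed=seed,
        )
    if method != "shuffle":
        raise DomainError(f"unknown null method {method!r}")
    if n_shuffles < 100:
        raise DomainError("shuffle null requires n_shuffles >= 100")
    if seed is None:
        raise DomainError("shuffle null requires a seed (reproducibility)")

    rng = np.random.default_rng(seed)
    # group by length so each group shuffles as one 2-D permuted block
    by_len: dict[int, list[np.ndarray]] = {}
    for arr in arrays:
        by_len.setdefault(arr.shape[0], []).append(arr)
    blocks = {L: np.stack(group) for L, group in by_len.items() if L >= 2}

    null = np.zeros((n_shuffles, max_spacing + 1), dtype=np.int64)
    for t in range(n_shuffles):
        for L, block in blocks.items():
            perm = rng.permuted(block, axis=1)
            for i in range(min(max_spacing + 1, L - 1)):
                null[t, i] += int(
                    np.count_nonzero(
                        (perm[:, : L - i - 1] == a) & (perm[:, i + 1 :] == b)
                    )
                )
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.full(max_spacing + 1, np.nan)
    ok = sd > 0
    z[ok] = (observed[ok] - mean[ok]) / sd[ok]
    z[(~ok) & (observed == mean)] = 0.0  # degenerate but consistent
    dev_null = np.abs(null - mean)
    dev_obs = np.abs(observed - mean)
    p = (1 + (dev_null >= dev_obs).sum(axis=0)) / (n_shuffles + 1)
    bh = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean > 0, observed / mean, np.inf)
        ratio = np.where((mean == 0) & (observed == 0), 1.0, ratio)
    return NullSummary(
        method="shuffle",
        observed=obs.counts,
        expected=tuple(mean),
        sd=tuple(sd),
        z=tuple(z),
        p_two_sided=tuple(p),
        bh_significant=tuple(bool(x) for x in bh),
        ratio=tuple(ratio),
        n_shuffles=n_shuffles,
        seed=seed,
    )


@dataclass(frozen=True)
class CompositionProfile:
    """Pooled residue composition of a sequence set."""

    counts: Mapping[str, int]
    n_sequences: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        tot = self.total
        return {sym: c / tot for sym, c in self.counts.items()}


def composition(sequences: Sequence[SequenceLike]) -> CompositionProfile:
    """Pooled residue fractions; bracketed tokens pool under the X class."""
    if not sequences:
        raise DomainError("empty sequence set")
    counts: dict[str, int] = {}
    for seq in sequences:
        for tok in _as_tokens(seq):
            sym = token_symbol(tok)
            counts[sym] = counts.get(sym, 0) + 1
    return CompositionProfile(counts=dict(sorted(counts.items())),
                              n_sequences=len(sequences))


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-symbol log2(f_set / f_background) with zero-cell flooring."""

    log2_ratio: Mapping[str, float]
    floored: frozenset[str]        # symbols whose fraction was floored
    background_id: str
    floor: float


def enrichment(
    profile: Union[CompositionProfile, Mapping[str, float]],
    background: Union[CompositionProfile, Mapping[str, float]],
    *,
    background_id: str = "background",
    floor: Optional[float] = 1e-4,
) -> EnrichmentTable:
    """Composition enrichment of a set against a background.

    Symbols with zero fraction on either side are floored at ``floor``
    (pseudo-fraction) and flagged; with ``floor=None`` a zero cell is a
    domain error.  Flooring is applied symmetrically, so
    enrichment(A, B) = -enrichment(B, A) exactly.
    """
    f_set = profile.frequencies if isinstance(profile, CompositionProfile) else dict(profile)
    f_bg = background.frequencies if isinstance(background, CompositionProfile) else dict(background)
    symbols = sorted(set(f_set) | set(f_bg))
    ratios: dict[str, float] = {}
    floored: set[str] = set()
    for sym in symbols:
        a = f_set.get(sym, 0.0)
        b = f_bg.get(sym, 0.0)
        if (a <= 0 or b <= 0) and floor is None:
            raise DomainError(
                f"symbol {sym!r} has a zero fraction and flooring is disabled"
            )
        if a <= 0:
            a = floor
            floored.add(sym)
        if b <= 0:
            b = floor
            floored.add(sym)
        ratios[sym] = float(np.log2(a / b))
    return EnrichmentTable(
        log2_ratio=ratios,
        floored=frozenset(floored),
        background_id=background_id,
        floor=floor if floor is not None else float("nan"),
    )
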