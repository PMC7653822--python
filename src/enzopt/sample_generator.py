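"""Pseudo-sequence generation and synthetic test families.

Two jobs live here:

1. The *approximation method* used to stretch a small labeled family:
   fit per-class, per-site symbol frequencies on the training split and
   sample site-independent pseudo-sequences from them, so the contrastive
   training loop sees more (approximate) samples than the family provides.

2. A synthetic family generator with *planted* condition-discriminative
   sites, so the whole pipeline — gain computation, embedding training,
   ranking, mutation suggestion — is exercisable end to end without any
   external dataset.  High-condition sequences prefer the alkali-resistant
   residues Lys/Arg at planted sites, low-condition sequences the acidic
   Asp/Glu; everything else is drawn from one shared background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa_io import (
    ALPHABET,
    GAP_INDEX,
    SYMBOL_INDEX,
    AlignedFamily,
    AlignedSequence,
    Partition,
)
from .site_statistics import N_SYMBOLS, kl_distance, site_distribution

ALKALI_SYMBOLS = ("K", "R")  # Lys, Arg
ACID_SYMBOLS = ("D", "E")  # Asp, Glu
#: Default background residues for non-planted sites: a realistic effective
#: alphabet of common small/polar/aliphatic residues.
DEFAULT_BACKGROUND = "AGSTNQVL"
BACKGROUND_GAP_MASS = 0.05


@dataclass(frozen=True)
class SiteProfile:
    """Per-class column-wise symbol distributions fitted on a family subset."""

    class_label: str  # "high" or "low"
    distributions: np.ndarray  # (l, 21), each row sums to 1

    def __post_init__(self) -> None:
        d = np.asarray(self.distributions, dtype=float)
        if d.ndim != 2 or d.shape[1] != N_SYMBOLS:
            raise ValueError(f"distributions must be (l, {N_SYMBOLS})")
        if np.any(d < 0) or not np.allclose(d.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each site distribution must sum to 1")
        object.__setattr__(self, "distributions", d)

    @property
    def l(self) -> int:
        return self.distributions.shape[0]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic labeled family with planted discriminative sites.

    ``effect`` is the probability mass the favoured residue pair receives at
    a planted site (the disfavoured pair gets the remainder); 1.0 plants a
    perfectly class-separating site.
    """

    n_sequences: int = 120
    l: int = 60
    n_planted: int = 8
    effect: float = 0.9
    class_balance: float = 0.5
    seed: int = 0
    background_symbols: str = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        if self.n_sequences <= 0 or self.l <= 0 or self.n_planted < 0:
            raise ValueError("counts must be positive")
        if self.n_planted > self.l:
            raise ValueError("n_planted cannot exceed the aligned length")
        if not 0 < self.effect <= 1:
            raise ValueError("effect must lie in (0, 1]")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")


def fit_site_profiles(
    family: AlignedFamily, partition: Partition
) -> tuple[SiteProfile, SiteProfile]:
    """Fit (high, low) per-site symbol frequency profiles on a labeled family."""
    matrix = family.to_matrix()
    ids = family.ids
    out = []
    for label, members in (("high", partition.S_h), ("low", partition.S_l)):
        rows = [i for i, sid in enumerate(ids) if sid in members]
        if not rows:
            raise ValueError(f"class {label!r} has no sequences; cannot fit profile")
        sub = matrix[rows]
        counts = np.stack(
            [np.bincount(sub[:, j], minlength=N_SYMBOLS) for j in range(family.l)]
        ).astype(float)
        out.append(
            SiteProfile(class_label=label, distributions=counts / counts.sum(1, keepdims=True))
        )
    return out[0], out[1]


def _sample_matrix(
    distributions: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n site-independent rows from per-column categoricals (inverse CDF)."""
    l = distributions.shape[0]
    cum = np.cumsum(distributions, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n, l))
    out = np.empty((n, l), dtype=np.uint8)
    for j in range(l):
        out[:, j] = np.searchsorted(cum[j], u[:, j], side="right")
    return np.minimum(out, N_SYMBOLS - 1)


def generate_pseudo_sequences(
    profile: SiteProfile, n: int, seed: int, *, id_prefix: str | None = None
) -> list[AlignedSequence]:
    """Sample *n* pseudo-sequences site-independently from a class profile.

    Deterministic given *seed*.  Ids are ``pseudo_<class>_<i>`` unless a
    prefix is given.  Pseudo-sequences carry no numeric label — they inherit
    only the class membership of their source profile.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    matrix = _sample_matrix(profile.distributions, n, rng)
    prefix = id_prefix or f"pseudo_{profile.class_label}"
    return [
        AlignedSequence(
            id=f"{prefix}_{i}", residues="".join(ALPHABET[c] for c in row)
        )
        for i, row in enumerate(matrix)
    ]


def _background_distribution(symbols: str) -> np.ndarray:
    probs = np.zeros(N_SYMBOLS)
    idx = [SYMBOL_INDEX[s] for s in symbols]
    probs[idx] = (1.0 - BACKGROUND_GAP_MASS) / len(idx)
    probs[GAP_INDEX] = BACKGROUND_GAP_MASS
    return probs


def _planted_distribution(favoured: tuple[str, str], effect: float) -> np.ndarray:
    disfavoured = ACID_SYMBOLS if favoured == ALKALI_SYMBOLS else ALKALI_SYMBOLS
    probs = np.zeros(N_SYMBOLS)
    for s in favoured:
        probs[SYMBOL_INDEX[s]] = effect / 2
    for s in disfavoured:
        probs[SYMBOL_INDEX[s]] = (1 - effect) / 2
    return probs


def generate_synthetic_family(
    spec: SyntheticSpec,
) -> tuple[AlignedFamily, frozenset[int]]:
    """Build a labeled synthetic family; returns (family, planted 1-based sites).

    High-class sequences get optimal pH ~ U(7.5, 9.5) and draw Lys/Arg at
    planted sites with probability ``effect``; low-class sequences get pH ~
    U(4.5, 6.5) and the mirror-image preference.  Non-planted sites share one
    background distribution for both classes.
    """
    rng = np.random.default_rng(spec.seed)
    n_high = int(round(spec.n_sequences * spec.class_balance))
    n_high = min(max(n_high, 1), spec.n_sequences - 1)
    n_low = spec.n_sequences - n_high

    planted = rng.choice(spec.l, size=spec.n_planted, replace=False)
    background = _background_distribution(spec.background_symbols)
    high_dist = np.tile(background, (spec.l, 1))
    low_dist = np.tile(background, (spec.l, 1))
    high_dist[planted] = _planted_distribution(ALKALI_SYMBOLS, spec.effect)
    low_dist[planted] = _planted_distribution(ACID_SYMBOLS, spec.effect)

    high_matrix = _sample_matrix(high_dist, n_high, rng)
    low_matrix = _sample_matrix(low_dist, n_low, rng)
    high_ph = rng.uniform(7.5, 9.5, size=n_high)
    low_ph = rng.uniform(4.5, 6.5, size=n_low)

    seqs = [
        AlignedSequence(
            id=f"high_{i}",
            residues="".join(ALPHABET[c] for c in row),
            label=float(ph),
        )
        for i, (row, ph) in enumerate(zip(high_matrix, high_ph))
    ] + [
        AlignedSequence(
            id=f"low_{i}",
            residues="".join(ALPHABET[c] for c in row),
            label=float(ph),
        )
        for i, (row, ph) in enumerate(zip(low_matrix, low_ph))
    ]
    return AlignedFamily(seqs), frozenset(int(k) + 1 for k in planted)


def augment_family(
    family: AlignedFamily,
    partition: Partition,
    factor: int,
    seed: int,
) -> tuple[list[AlignedSequence], list[AlignedSequence]]:
    """Approximation-method augmentation: per-class pseudo-sequences.

    Returns (high pseudo-sequences, low pseudo-sequences), ``factor`` times
    each class's real size, sampled from the class profiles.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    high_profile, low_profile = fit_site_profiles(family, partition)
    n_high = factor * len(partition.S_h)
    n_low = factor * len(partition.S_l)
    # Derive two distinct streams from one seed, staying well below 2**31.
    high = generate_pseudo_sequences(high_profile, n_high, seed=(seed * 2 + 1) % (2**31))
    low = generate_pseudo_sequences(low_profile, n_low, seed=(seed * 2 + 2) % (2**31))
    return high, low


def kl_curve(
    family: AlignedFamily,
    proportions: list[float],
    seed: int,
    *,
    base: float = 2.0,
) -> pd.DataFrame:
    """Per-site KL(train || full) for random training subsets of given sizes.

    For each proportion p, a subset of round(p*n) sequences is drawn without
    replacement and each column's symbol distribution is compared with the
    full family's by KL divergence.  Columns: proportion, site, kl.
    """
    rng = np.random.default_rng(seed)
    n = len(family)
    full = [site_distribution(family, k) for k in range(1, family.l + 1)]
    records = []
    for p in proportions:
        if not 0 < p <= 1:
            raise ValueError(f"proportion {p} outside (0, 1]")
        size = int(round(p * n))
        if size == 0:
            raise ValueError(f"proportion {p} yields an empty training subset")
        idx = rng.choice(n, size=size, replace=False)
        sub = AlignedFamily([family.sequences[i] for i in sorted(idx)])
        for k in range(1, family.l + 1):
            records.append(
                {
                    "proportion": p,
                    "site": k,
                    "kl": kl_distance(
                        site_distribution(sub, k), full[k - 1], base=base
                    ),
                }
            )
    return pd.DataFrame.from_records(records)
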