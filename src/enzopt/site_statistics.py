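"""Per-site alignment statistics: symbol distributions, information gain, KL.

The information gain of a column measures how much knowing the symbol at
that site reduces uncertainty about a sequence's condition class (high vs
low optimal pH): ``Gain(k) = H(y) - H(y|k)``.  Sites with gain at or above
a threshold ``omega`` form the *selected* set used for embedding training,
scoring and mutation; the remainder are effectively conserved (or
condition-uninformative) and carry no class signal.

All entropies default to base 2 (bits); the base is configurable because
the gain threshold ``omega`` is only meaningful relative to a base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr
from scipy.stats import entropy as _entropy

from .msa_io import ALPHABET, AlignedFamily, LabelError, Partition

N_SYMBOLS = len(ALPHABET)


@dataclass(frozen=True)
class SiteDistribution:
    """Empirical symbol distribution of one alignment column (1-based site)."""

    site: int
    probs: np.ndarray  # (21,), ordered as ALPHABET

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_SYMBOLS,):
            raise ValueError(f"probs must have shape ({N_SYMBOLS},)")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be non-negative and sum to 1")
        object.__setattr__(self, "probs", p)

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(ALPHABET, self.probs) if p > 0}


@dataclass(frozen=True)
class SiteStatistics:
    """Information gain for every site plus the selected-site set at omega."""

    gains: np.ndarray  # (l,), bits (or the chosen base)
    H_y: float
    omega: float
    selected: frozenset[int]  # 1-based sites with gain >= omega
    base: float = 2.0

    @property
    def l(self) -> int:
        return len(self.gains)


def _check_site(family: AlignedFamily, k: int) -> None:
    if not 1 <= k <= family.l:
        raise IndexError(f"site {k} out of range [1..{family.l}]")


def _class_vector(family: AlignedFamily, partition: Partition) -> np.ndarray:
    """Per-sequence class code: 1 = S_h, 0 = S_l, -1 = unlabeled."""
    codes = np.full(len(family), -1, dtype=np.int8)
    for i, s in enumerate(family):
        if s.id in partition.S_h:
            codes[i] = 1
        elif s.id in partition.S_l:
            codes[i] = 0
    return codes


def site_distribution(family: AlignedFamily, k: int) -> SiteDistribution:
    """Unsmoothed empirical symbol frequencies of column *k* (gap included)."""
    _check_site(family, k)
    column = family.to_matrix()[:, k - 1]
    counts = np.bincount(column, minlength=N_SYMBOLS).astype(float)
    return SiteDistribution(site=k, probs=counts / counts.sum())


def label_entropy(
    family: AlignedFamily, partition: Partition, *, base: float = 2.0
) -> float:
    """Entropy H(y) of the high/low class membership over labeled sequences."""
    n_h, n_l = len(partition.S_h), len(partition.S_l)
    if n_h + n_l == 0:
        raise LabelError("partition contains no labeled sequences")
    return float(_entropy([n_h, n_l], base=base))


def conditional_entropy(
    family: AlignedFamily, partition: Partition, k: int, *, base: float = 2.0
) -> float:
    """H(y|k): class entropy after observing the symbol at site *k*.

    Weighted average, over symbols, of the binary class entropy among the
    labeled sequences carrying that symbol.
    """
    _check_site(family, k)
    codes = _class_vector(family, partition)
    column = family.to_matrix()[:, k - 1]
    mask = codes >= 0
    if not mask.any():
        raise LabelError("partition contains no labeled sequences")
    column, codes = column[mask], codes[mask]
    n = len(column)
    h = 0.0
    for sym in np.unique(column):
        sel = column == sym
        n_sym = int(sel.sum())
        h += (n_sym / n) * float(
            _entropy([int(codes[sel].sum()), n_sym - int(codes[sel].sum())], base=base)
        )
    return h


def information_gain(
    family: AlignedFamily, partition: Partition, k: int, *, base: float = 2.0
) -> float:
    """Gain(k) = H(y) - H(y|k), clipped at 0 against floating rounding."""
    gain = label_entropy(family, partition, base=base) - conditional_entropy(
        family, partition, k, base=base
    )
    return max(0.0, float(gain))


def compute_gains(
    family: AlignedFamily, partition: Partition, *, base: float = 2.0
) -> np.ndarray:
    """Information gain of every site, vectorized over columns."""
    codes = _class_vector(family, partition)
    mask = codes >= 0
    if not mask.any():
        raise LabelError("partition contains no labeled sequences")
    matrix = family.to_matrix()[mask]
    codes = codes[mask]
    n = len(codes)
    h_y = label_entropy(family, partition, base=base)
    gains = np.empty(family.l)
    for j in range(family.l):
        column = matrix[:, j]
        # 2 x 21 contingency table of class vs symbol
        counts_h = np.bincount(column[codes == 1], minlength=N_SYMBOLS)
        counts_l = np.bincount(column[codes == 0], minlength=N_SYMBOLS)
        totals = counts_h + counts_l
        nz = totals > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            p_h = counts_h[nz] / totals[nz]
            h_cond = np.where(
                (p_h > 0) & (p_h < 1),
                -(
                    p_h * np.log(np.where(p_h > 0, p_h, 1.0))
                    + (1 - p_h) * np.log(np.where(p_h < 1, 1 - p_h, 1.0))
                )
                / np.log(base),
                0.0,
            )
        gains[j] = h_y - float(np.dot(totals[nz] / n, h_cond))
    return np.clip(gains, 0.0, None)


def compute_site_statistics(
    family: AlignedFamily,
    partition: Partition,
    omega: float = 0.0478,
    *,
    base: float = 2.0,
) -> SiteStatistics:
    """Gains for all sites plus the selected set ``{k : gain[k] >= omega}``."""
    gains = compute_gains(family, partition, base=base)
    return SiteStatistics(
        gains=gains,
        H_y=label_entropy(family, partition, base=base),
        omega=omega,
        selected=select_sites(gains, omega),
        base=base,
    )


def select_sites(gains: np.ndarray, omega: float) -> frozenset[int]:
    """1-based sites whose gain is at or above omega (inclusive boundary)."""
    return frozenset(int(k) + 1 for k in np.flatnonzero(np.asarray(gains) >= omega))


def kl_distance(
    P: SiteDistribution | np.ndarray,
    Q: SiteDistribution | np.ndarray,
    *,
    base: float = 2.0,
    eps: float = 1e-6,
) -> float:
    """KL divergence ``sum_c P(c) log(P(c)/Q(c))`` between two column distributions.

    An additive pseudocount *eps* is applied to Q (and P) and renormalized so
    that empty cells of the reference distribution do not blow up; pass
    ``eps=0`` for the raw plug-in value, which raises if Q has a zero cell
    where P has mass.
    """
    p = np.asarray(P.probs if isinstance(P, SiteDistribution) else P, dtype=float)
    q = np.asarray(Q.probs if isinstance(Q, SiteDistribution) else Q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q must share an alphabet")
    if eps > 0:
        p = (p + eps) / (p + eps).sum()
        q = (q + eps) / (q + eps).sum()
    elif np.any((q == 0) & (p > 0)):
        raise ValueError("Q has zero mass where P is positive and smoothing is off")
    return float(rel_entr(p, q).sum() / np.log(base))
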