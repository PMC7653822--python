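"""Quantitative sequence scoring, pairwise ranking and repeated-split evaluation.

A sequence's predicted optimal condition is summarized by

    Score(a) = alpha * sum_k s(k, a_k)
             + (1 - alpha) * sum_{i<j} s(n_i, n_j) / l

with both sums restricted to the selected (information-gain >= omega) sites:
low-gain sites are conserved or uninformative and are excluded from the
score, mirroring how they are excluded from mutation.  Only relative scores
matter — two sequences are compared by Score, and ranking accuracy counts
how often the score ordering of a held-out pair matches the label ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding_model import EmbeddingTable, TrainingConfig, train
from .msa_io import AlignedFamily, AlignedSequence, Partition, partition_by_threshold
from .site_statistics import SiteStatistics, compute_site_statistics

TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class ScoreReport:
    """Decomposed quantitative score of one sequence."""

    sequence_id: str
    total: float
    single_term: float  # sum of capability scores over selected sites
    pair_term: float  # sum of suitability scores over selected pairs, / l
    alpha: float


@dataclass(frozen=True)
class RankingResult:
    """Pairwise ranking outcome on a labeled test set."""

    n_pairs: int
    n_correct: int
    accuracy: float
    per_repeat: tuple[float, ...] = ()


@dataclass(frozen=True)
class CrossValidationResult:
    accuracies: tuple[float, ...]
    mean: float
    std: float


def _selected_array(selected: set[int] | frozenset[int], l: int) -> np.ndarray:
    sel = np.array(sorted(selected), dtype=np.int64)
    if len(sel) and (sel[0] < 1 or sel[-1] > l):
        raise IndexError("selected sites out of range")
    return sel - 1


def quantitative_score(
    table: EmbeddingTable,
    seq: AlignedSequence,
    selected: set[int] | frozenset[int],
    alpha: float,
) -> ScoreReport:
    """Combined capability + suitability score of a sequence.

    The single term sums v_k . c_{a_k} over selected sites; the pair term
    sums (v_i + c_i-style concatenated) dot products over unordered pairs of
    distinct selected sites and divides by the aligned length l.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if len(seq) != table.l:
        raise ValueError(
            f"sequence length {len(seq)} does not match the model's l={table.l}"
        )
    sel = _selected_array(selected, table.l)
    encoded = seq.encoded()
    V = table.site_vectors[sel]
    Cm = table.symbol_vectors[encoded[sel].astype(np.int64)]
    single = float(np.einsum("nd,nd->n", V, Cm).sum())
    # sum over i<j of (v_i.v_j + c_i.c_j) via the square-of-sums identity
    sv, sc = V.sum(0), Cm.sum(0)
    pair_raw = 0.5 * (
        float(sv @ sv) - float(np.einsum("nd,nd->", V, V))
        + float(sc @ sc) - float(np.einsum("nd,nd->", Cm, Cm))
    )
    pair = pair_raw / table.l
    return ScoreReport(
        sequence_id=seq.id,
        total=alpha * single + (1.0 - alpha) * pair,
        single_term=single,
        pair_term=pair,
        alpha=alpha,
    )


def compare(
    table: EmbeddingTable,
    seq_a: AlignedSequence,
    seq_b: AlignedSequence,
    selected: set[int] | frozenset[int],
    alpha: float,
) -> str:
    """Order two sequences by predicted optimal condition.

    Returns ``"a_higher"``, ``"b_higher"`` or ``"tie"`` (score difference
    below 1e-9).
    """
    sa = quantitative_score(table, seq_a, selected, alpha).total
    sb = quantitative_score(table, seq_b, selected, alpha).total
    if abs(sa - sb) < TIE_TOLERANCE:
        return "tie"
    return "a_higher" if sa > sb else "b_higher"


def ranking_accuracy(
    table: EmbeddingTable,
    test_sequences: list[AlignedSequence],
    selected: set[int] | frozenset[int],
    alpha: float,
) -> RankingResult:
    """Fraction of held-out pairs whose score ordering matches the labels.

    All unordered pairs with distinct labels are judged; equal-label pairs
    are excluded (no ground-truth ordering) and score ties count as
    incorrect.
    """
    labeled = [s for s in test_sequences if s.label is not None]
    scores = {
        s.id: quantitative_score(table, s, selected, alpha).total for s in labeled
    }
    n_pairs = 0
    n_correct = 0
    for i in range(len(labeled)):
        for j in range(i + 1, len(labeled)):
            a, b = labeled[i], labeled[j]
            if a.label == b.label:
                continue
            n_pairs += 1
            diff = scores[a.id] - scores[b.id]
            if abs(diff) < TIE_TOLERANCE:
                continue  # tie: incorrect
            if (diff > 0) == (a.label > b.label):
                n_correct += 1
    if n_pairs < 2:
        raise ValueError("fewer than 2 usable (distinct-label) test pairs")
    return RankingResult(
        n_pairs=n_pairs, n_correct=n_correct, accuracy=n_correct / n_pairs
    )


def _stratified_split(
    family: AlignedFamily,
    partition: Partition,
    ratio: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Split labeled ids into train/test, stratified by condition class."""
    train_ids: list[str] = []
    test_ids: list[str] = []
    for members in (partition.S_h, partition.S_l):
        ids = sorted(members)
        perm = rng.permutation(len(ids))
        n_train = int(round(ratio * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids += [ids[i] for i in perm[:n_train]]
        test_ids += [ids[i] for i in perm[n_train:]]
    return train_ids, test_ids


def cross_validate(
    family: AlignedFamily,
    config: TrainingConfig,
    ratio: float = 0.8,
    repeats: int = 10,
    *,
    threshold: float | str = 7.0,
) -> CrossValidationResult:
    """Repeated stratified random-split evaluation of ranking accuracy.

    Each repeat: split the labeled family ``ratio : 1-ratio`` stratified by
    condition class, recompute gains and the selected-site set on the
    training split, train embeddings there, and measure pairwise ranking
    accuracy on the held-out split.  Seeded and reproducible.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    partition = partition_by_threshold(family, threshold)
    if len(partition.S_h) < 2 or len(partition.S_l) < 2:
        raise ValueError("each condition class needs >= 2 labeled sequences")
    accuracies = []
    for r in range(repeats):
        rng = np.random.default_rng((config.seed + 7919 * r) % (2**31))
        train_ids, test_ids = _stratified_split(family, partition, ratio, rng)
        train_family = family.subset(train_ids)
        train_partition = partition_by_threshold(train_family, partition.threshold)
        stats = compute_site_statistics(
            train_family, train_partition, omega=config.omega
        )
        table = train(
            [train_family[i] for i in sorted(train_partition.S_h)],
            [train_family[i] for i in sorted(train_partition.S_l)],
            stats,
            TrainingConfig(
                **{
                    **config.__dict__,
                    "seed": (config.seed + 104729 * r + 1) % (2**31),
                }
            ),
        )
        result = ranking_accuracy(
            table,
            [family[i] for i in test_ids],
            stats.selected,
            config.alpha,
        )
        accuracies.append(result.accuracy)
    acc = np.asarray(accuracies)
    return CrossValidationResult(
        accuracies=tuple(accuracies),
        mean=float(acc.mean()),
        std=float(acc.std(ddof=1)) if repeats > 1 else 0.0,
    )
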