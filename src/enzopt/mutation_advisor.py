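"""Rational-design mutation suggestion driven by the quantitative score.

Two eligibility rules restrict which sites may be edited: a gap in the wild
type is never mutated (the alignment length must be preserved) and sites
whose information gain falls below the threshold omega are never mutated
(they are conserved or uninformative).  Within the eligible sites the
advisor searches single-site and up-to-``max_sites`` (default 3) multi-site
substitutions for the mutant with the highest score, exhaustively when the
candidate set is small and greedily otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .embedding_model import EmbeddingTable
from .msa_io import ALPHABET, GAP, GAP_INDEX, SYMBOL_INDEX, AlignedSequence
from .scoring import quantitative_score
from .site_statistics import N_SYMBOLS, SiteStatistics

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class MutationSuggestion:
    """A proposed set of substitutions and the score change it buys."""

    wild_id: str
    edits: tuple[tuple[int, str, str], ...]  # (1-based site, from, to)
    score_wild: float
    score_mutant: float

    def __post_init__(self) -> None:
        if not self.edits:
            raise ValueError("a suggestion needs at least one edit")
        sites = [site for site, _, _ in self.edits]
        if len(set(sites)) != len(sites):
            raise ValueError("edit sites must be distinct")
        for site, frm, to in self.edits:
            if frm == GAP:
                raise ValueError(f"site {site}: gap positions are never mutated")
            if to == GAP:
                raise ValueError(f"site {site}: gap is never a target symbol")
            if frm == to:
                raise ValueError(f"site {site}: edit must change the symbol")

    @property
    def delta(self) -> float:
        return self.score_mutant - self.score_wild

    def notation(self) -> str:
        """Edits in compact 'S22P' form using aligned 1-based site numbers."""
        return "/".join(f"{frm}{site}{to}" for site, frm, to in self.edits)


def candidate_sites(
    seq: AlignedSequence, stats: SiteStatistics, omega: float | None = None
) -> frozenset[int]:
    """Sites eligible for mutation: wild symbol is not a gap AND gain >= omega."""
    w = stats.omega if omega is None else omega
    return frozenset(
        k
        for k in range(1, len(seq) + 1)
        if seq.residues[k - 1] != GAP and stats.gains[k - 1] >= w
    )


def apply_edits(
    seq: AlignedSequence, edits: tuple[tuple[int, str, str], ...]
) -> AlignedSequence:
    """Return the mutant sequence produced by a set of edits."""
    residues = list(seq.residues)
    for site, frm, to in edits:
        if residues[site - 1] != frm:
            raise ValueError(
                f"site {site}: wild symbol is {residues[site - 1]!r}, not {frm!r}"
            )
        residues[site - 1] = to
    return AlignedSequence(id=seq.id, residues="".join(residues), label=seq.label)


def _edit_deltas(
    table: EmbeddingTable,
    seq: AlignedSequence,
    sites: list[int],
    selected: frozenset[int],
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Score deltas of every single substitution at each candidate site.

    Returns (deltas, diff_vectors): deltas[i, s] is the score change from
    putting symbol s at sites[i]; diff_vectors[i, s] is c_s - c_wild, used to
    compose multi-site deltas.  Substitutions at non-selected candidate
    sites change nothing (the score never sees them), so their rows are 0.
    """
    encoded = seq.encoded().astype(np.int64)
    sel = np.array(sorted(selected), dtype=np.int64) - 1
    c_sum = table.symbol_vectors[encoded[sel]].sum(0)
    deltas = np.zeros((len(sites), N_SYMBOLS))
    diffs = np.zeros((len(sites), N_SYMBOLS, table.d))
    for i, site in enumerate(sites):
        if site not in selected:
            continue
        k = site - 1
        wild = encoded[k]
        d = table.symbol_vectors - table.symbol_vectors[wild]  # (21, d)
        diffs[i] = d
        single = table.site_vectors[k] @ d.T
        # pair c-term: sum_{j in sel, j != k} (c_s - c_w) . c_{a_j}
        pair = d @ (c_sum - table.symbol_vectors[wild])
        deltas[i] = alpha * single + (1.0 - alpha) * pair / table.l
    return deltas, diffs


def _multi_delta(
    deltas_rows: np.ndarray, diffs_rows: np.ndarray, alpha: float, l: int
) -> np.ndarray:
    """Score delta of every symbol combination over a fixed set of edit sites.

    Single-edit deltas add, but the pair c-term also picks up interactions
    between the edited sites: for edits with difference vectors d_p, d_q the
    correction is (1-alpha)/l * sum_{p<q} d_p . d_q.
    """
    m = deltas_rows.shape[0]
    total = deltas_rows[0]
    shape = [N_SYMBOLS] + [1] * (m - 1)
    total = deltas_rows[0].reshape(shape)
    for p in range(1, m):
        shape = [1] * m
        shape[p] = N_SYMBOLS
        total = total + deltas_rows[p].reshape(shape)
    for p in range(m):
        for q in range(p + 1, m):
            inter = diffs_rows[p] @ diffs_rows[q].T  # (21, 21)
            shape = [1] * m
            shape[p], shape[q] = N_SYMBOLS, N_SYMBOLS
            if p > q:
                inter = inter.T
            total = total + (1.0 - alpha) / l * inter.reshape(
                [N_SYMBOLS if i in (p, q) else 1 for i in range(m)]
            )
    return total


def _forbidden_mask(seq: AlignedSequence, sites: list[int]) -> np.ndarray:
    """(len(sites), 21) bool mask of disallowed target symbols (gap, wild)."""
    mask = np.zeros((len(sites), N_SYMBOLS), dtype=bool)
    mask[:, GAP_INDEX] = True
    for i, site in enumerate(sites):
        mask[i, SYMBOL_INDEX[seq.residues[site - 1]]] = True
    return mask


def _make_suggestion(
    seq: AlignedSequence,
    edit_sites: tuple[int, ...],
    symbol_idx: tuple[int, ...],
    score_wild: float,
    delta: float,
) -> MutationSuggestion:
    edits = tuple(
        (site, seq.residues[site - 1], ALPHABET[s])
        for site, s in zip(edit_sites, symbol_idx)
    )
    return MutationSuggestion(
        wild_id=seq.id,
        edits=edits,
        score_wild=score_wild,
        score_mutant=score_wild + delta,
    )


def best_single_mutation(
    table: EmbeddingTable,
    seq: AlignedSequence,
    candidates: frozenset[int] | set[int],
    alpha: float,
    *,
    selected: frozenset[int] | set[int] | None = None,
) -> MutationSuggestion | None:
    """Highest-scoring single substitution, or None when nothing improves.

    All (candidate site, non-gap, non-wild symbol) edits are scored
    exhaustively; ties resolve to the smallest (site, symbol) pair.
    ``selected`` is the score's site restriction (defaults to the candidate
    set itself, which already satisfies the gain rule).
    """
    if not candidates:
        return None
    sel = frozenset(selected) if selected is not None else frozenset(candidates)
    sites = sorted(candidates)
    score_wild = quantitative_score(table, seq, sel, alpha).total
    deltas, _ = _edit_deltas(table, seq, sites, sel, alpha)
    deltas[_forbidden_mask(seq, sites)] = -np.inf
    best = np.unravel_index(np.argmax(deltas), deltas.shape)
    best_delta = deltas[best]
    if not np.isfinite(best_delta) or best_delta <= _TIE_EPS:
        return None
    return _make_suggestion(
        seq, (sites[best[0]],), (int(best[1]),), score_wild, float(best_delta)
    )


def best_multi_mutation(
    table: EmbeddingTable,
    seq: AlignedSequence,
    candidates: frozenset[int] | set[int],
    alpha: float,
    max_sites: int = 3,
    *,
    selected: frozenset[int] | set[int] | None = None,
    exhaustive_limit: int = 15,
    mode: str = "auto",
) -> MutationSuggestion | None:
    """Best combination of up to ``max_sites`` single-site edits.

    ``mode`` is ``"exhaustive"``, ``"greedy"`` or ``"auto"`` (exhaustive when
    the candidate set has at most ``exhaustive_limit`` sites).  Exhaustive
    search enumerates every site combination and symbol assignment; greedy
    search repeatedly applies the best remaining single edit while the score
    improves.  Ties prefer fewer edits, then lexicographic (site, symbol).
    """
    if max_sites < 1:
        raise ValueError("max_sites must be >= 1")
    if mode not in ("auto", "exhaustive", "greedy"):
        raise ValueError("mode must be auto, exhaustive or greedy")
    if not candidates:
        return None
    if mode == "auto":
        mode = "exhaustive" if len(candidates) <= exhaustive_limit else "greedy"
    if mode == "greedy":
        return _greedy_multi(table, seq, candidates, alpha, max_sites, selected)

    sel = frozenset(selected) if selected is not None else frozenset(candidates)
    sites = sorted(candidates)
    score_wild = quantitative_score(table, seq, sel, alpha).total
    deltas, diffs = _edit_deltas(table, seq, sites, sel, alpha)
    forbidden = _forbidden_mask(seq, sites)
    deltas_masked = np.where(forbidden, -np.inf, deltas)

    best_delta = _TIE_EPS
    best_edit: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    for m in range(1, min(max_sites, len(sites)) + 1):
        for combo in combinations(range(len(sites)), m):
            grid = _multi_delta(
                deltas_masked[list(combo)], diffs[list(combo)], alpha, table.l
            )
            flat = np.argmax(grid)
            d = float(grid.flat[flat])
            if d > best_delta + _TIE_EPS:
                idx = np.unravel_index(flat, grid.shape)
                best_delta = d
                best_edit = (
                    tuple(sites[i] for i in combo),
                    tuple(int(s) for s in idx),
                )
    if best_edit is None:
        return None
    return _make_suggestion(seq, best_edit[0], best_edit[1], score_wild, best_delta)


def _greedy_multi(
    table: EmbeddingTable,
    seq: AlignedSequence,
    candidates: frozenset[int] | set[int],
    alpha: float,
    max_sites: int,
    selected: frozenset[int] | set[int] | None,
) -> MutationSuggestion | None:
    sel = frozenset(selected) if selected is not None else frozenset(candidates)
    score_wild = quantitative_score(table, seq, sel, alpha).total
    current = seq
    remaining = set(candidates)
    edits: list[tuple[int, str, str]] = []
    for _ in range(max_sites):
        step = best_single_mutation(table, current, remaining, alpha, selected=sel)
        if step is None:
            break
        (site, frm, to) = step.edits[0]
        edits.append((site, frm, to))
        remaining.discard(site)
        current = apply_edits(current, step.edits)
        if not remaining:
            break
    if not edits:
        return None
    score_mutant = quantitative_score(table, current, sel, alpha).total
    return MutationSuggestion(
        wild_id=seq.id,
        edits=tuple(edits),
        score_wild=score_wild,
        score_mutant=score_mutant,
    )
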