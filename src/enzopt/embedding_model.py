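"""Site/amino-acid embeddings trained by noise-contrastive estimation.

The model places every alignment site k and every alphabet symbol s in one
latent space R^d.  Two scores are read off the embeddings:

* capability score  s(k, a) = v_k . c_a            (single site + symbol)
* suitability score s(n_i, n_j) = (v_i + c_i) . (v_j + c_j) interpreted as
  the dot product of the concatenated vectors, i.e. v_i.v_j + c_i.c_j
  (joint effect of two occupied sites of the same sequence).

Softmax normalization over the full event space is sidestepped with NCE:
the log-normalizer becomes a learnable scalar C (one per objective) and the
model learns by logistic discrimination between events drawn from the
high-condition set S_h and noise events drawn from a distribution fitted on
the low-condition set S_l.  The two objectives are blended by alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .msa_io import ALPHABET, SYMBOL_INDEX, AlignedSequence
from .site_statistics import N_SYMBOLS, SiteStatistics
from . import sample_generator


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """log sigma(x), numerically stable."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def _log_one_minus_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """log(1 - sigma(x)) = log sigma(-x)."""
    return -np.logaddexp(0.0, np.asarray(x, dtype=float))


@dataclass(frozen=True)
class Event:
    """A symbol occupying an alignment site: the atom of the single objective."""

    site: int  # 1-based
    symbol: str

    def __post_init__(self) -> None:
        if self.symbol not in SYMBOL_INDEX:
            raise ValueError(f"symbol {self.symbol!r} outside the alphabet")
        if self.site < 1:
            raise ValueError("site indices are 1-based")


@dataclass(frozen=True)
class PairEvent:
    """Two events from the same sequence at distinct sites."""

    first: Event
    second: Event

    def __post_init__(self) -> None:
        if self.first.site == self.second.site:
            raise ValueError("pair events require two distinct sites")


@dataclass
class EmbeddingTable:
    """Learned parameters: l site vectors, 21 symbol vectors, two normalizers."""

    site_vectors: np.ndarray  # (l, d)
    symbol_vectors: np.ndarray  # (21, d)
    C: float = 0.0
    C_pair: float = 0.0

    def __post_init__(self) -> None:
        self.site_vectors = np.asarray(self.site_vectors, dtype=float)
        self.symbol_vectors = np.asarray(self.symbol_vectors, dtype=float)
        if self.site_vectors.ndim != 2 or self.symbol_vectors.ndim != 2:
            raise ValueError("vector tables must be 2-D")
        if self.symbol_vectors.shape[0] != N_SYMBOLS:
            raise ValueError(f"expected {N_SYMBOLS} symbol vectors")
        if self.site_vectors.shape[1] != self.symbol_vectors.shape[1]:
            raise ValueError("site and symbol vectors must share a dimension")

    @property
    def l(self) -> int:
        return self.site_vectors.shape[0]

    @property
    def d(self) -> int:
        return self.site_vectors.shape[1]

    def _site_index(self, site: int) -> int:
        if not 1 <= site <= self.l:
            raise IndexError(f"site {site} out of range [1..{self.l}]")
        return site - 1

    def save(self, path: str | Path) -> None:
        """Serialize as a plain TSV bundle at full decimal precision."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#d\t{self.d}\n#l\t{self.l}\n")
            fh.write(f"#alphabet\t{ALPHABET}\n")
            fh.write(f"#C\t{self.C!r}\n#C_pair\t{self.C_pair!r}\n")
            for k in range(self.l):
                row = "\t".join(repr(float(x)) for x in self.site_vectors[k])
                fh.write(f"site:{k + 1}\t{row}\n")
            for s, vec in zip(ALPHABET, self.symbol_vectors):
                row = "\t".join(repr(float(x)) for x in vec)
                fh.write(f"symbol:{s}\t{row}\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        meta: dict[str, str] = {}
        sites: dict[int, np.ndarray] = {}
        symbols: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                key, _, rest = line.partition("\t")
                if key.startswith("#"):
                    meta[key[1:]] = rest
                elif key.startswith("site:"):
                    sites[int(key[5:])] = np.array(
                        [float(x) for x in rest.split("\t")]
                    )
                elif key.startswith("symbol:"):
                    symbols[key[7:]] = np.array(
                        [float(x) for x in rest.split("\t")]
                    )
        l = int(meta["l"])
        table = cls(
            site_vectors=np.stack([sites[k + 1] for k in range(l)]),
            symbol_vectors=np.stack([symbols[s] for s in ALPHABET]),
            C=float(meta["C"]),
            C_pair=float(meta["C_pair"]),
        )
        if table.d != int(meta["d"]):
            raise ValueError("dimension header disagrees with vector rows")
        return table


def capability_score(table: EmbeddingTable, e: Event) -> float:
    """s(k, a) = v_k . c_a: how the symbol at that site shifts the condition."""
    k = table._site_index(e.site)
    return float(table.site_vectors[k] @ table.symbol_vectors[SYMBOL_INDEX[e.symbol]])


def joint_embedding(table: EmbeddingTable, e: Event) -> np.ndarray:
    """Concatenated site+symbol vector n_k^a in R^{2d} (site half first)."""
    k = table._site_index(e.site)
    return np.concatenate(
        [table.site_vectors[k], table.symbol_vectors[SYMBOL_INDEX[e.symbol]]]
    )


def suitability_score(table: EmbeddingTable, p: PairEvent) -> float:
    """Dot product of the two joint embeddings; equals v_i.v_j + c_i.c_j."""
    return float(joint_embedding(table, p.first) @ joint_embedding(table, p.second))


def unnormalized_logprob(table: EmbeddingTable, e: Event) -> float:
    """NCE model log-probability of a single event: s(k, a) + C."""
    return capability_score(table, e) + table.C


def pair_unnormalized_logprob(table: EmbeddingTable, p: PairEvent) -> float:
    """NCE model log-probability of a pair event: s(n_i, n_j) + C_pair."""
    return suitability_score(table, p) + table.C_pair


@dataclass
class NoiseModel:
    """Artificial noise distribution over events (and, factorized, pair events).

    A uniform choice over the allowed sites times a per-site symbol
    categorical; pair events use an ordered pair of distinct allowed sites
    and independent symbols.  Fitted on the low-condition set S_l with
    additive smoothing so every event has positive noise probability.
    """

    log_symbol_probs: np.ndarray  # (l, 21)
    sites: np.ndarray  # 0-based allowed site indices, sorted
    eps: float = 1e-3

    def __post_init__(self) -> None:
        self.log_symbol_probs = np.asarray(self.log_symbol_probs, dtype=float)
        self.sites = np.asarray(self.sites, dtype=np.int64)
        probs = np.exp(self.log_symbol_probs)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("per-site noise probabilities must sum to 1")
        if len(self.sites) == 0:
            raise ValueError("noise model needs at least one allowed site")
        self._cum = np.cumsum(probs, axis=1)
        self._cum[:, -1] = 1.0

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, sites: np.ndarray, eps: float = 1e-3
    ) -> "NoiseModel":
        """Fit per-site symbol frequencies (smoothed) from an encoded matrix."""
        l = matrix.shape[1]
        counts = np.stack(
            [np.bincount(matrix[:, j], minlength=N_SYMBOLS) for j in range(l)]
        ).astype(float)
        counts += eps
        return cls(
            log_symbol_probs=np.log(counts / counts.sum(1, keepdims=True)),
            sites=np.asarray(sites),
            eps=eps,
        )

    @classmethod
    def uniform(cls, l: int, sites: np.ndarray) -> "NoiseModel":
        return cls(
            log_symbol_probs=np.full((l, N_SYMBOLS), -math.log(N_SYMBOLS)),
            sites=np.asarray(sites),
        )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def event_logprob(self, sites0: np.ndarray, symbols: np.ndarray) -> np.ndarray:
        """log p_n of events (0-based site array, symbol index array)."""
        return -math.log(self.n_sites) + self.log_symbol_probs[sites0, symbols]

    def pair_logprob(
        self,
        sites_i: np.ndarray,
        sites_j: np.ndarray,
        syms_i: np.ndarray,
        syms_j: np.ndarray,
    ) -> np.ndarray:
        """log p_n of pair events: ordered distinct site pair x symbol product."""
        if self.n_sites < 2:
            raise ValueError("pair noise needs at least two allowed sites")
        return (
            -math.log(self.n_sites * (self.n_sites - 1))
            + self.log_symbol_probs[sites_i, syms_i]
            + self.log_symbol_probs[sites_j, syms_j]
        )

    def _sample_symbols(
        self, sites0: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        u = rng.random(len(sites0))
        idx = np.empty(len(sites0), dtype=np.int64)
        for pos, (s, uu) in enumerate(zip(sites0, u)):
            idx[pos] = np.searchsorted(self._cum[s], uu, side="right")
        return np.minimum(idx, N_SYMBOLS - 1)

    def sample_events(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        sites0 = self.sites[rng.integers(0, self.n_sites, size=n)]
        return sites0, self._sample_symbols(sites0, rng)

    def sample_pairs(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        i = rng.integers(0, self.n_sites, size=n)
        j = rng.integers(0, self.n_sites - 1, size=n)
        j = np.where(j >= i, j + 1, j)  # distinct ordered pair
        si, sj = self.sites[i], self.sites[j]
        return si, sj, self._sample_symbols(si, rng), self._sample_symbols(sj, rng)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the contrastive training loop."""

    d: int = 30
    alpha: float = 0.4
    omega: float = 0.0478
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    steps: int = 20000
    batch: int = 32
    noise_per_positive: int = 1
    seed: int = 0
    augment_factor: int = 10
    noise_model: str = "low_class"  # or "uniform"
    noise_smoothing: float = 1e-3
    init_scale: float = 0.1
    convergence_window: int = 500
    convergence_tolerance: float = 1e-4
    train_all_sites: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.d < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.noise_model not in ("low_class", "uniform"):
            raise ValueError("noise_model must be 'low_class' or 'uniform'")


def nce_loss_single(
    table: EmbeddingTable,
    positive: Event,
    noise_events: Sequence[Event],
    noise: NoiseModel,
) -> float:
    """Single-objective NCE loss for one positive and >= 1 noise events.

    -[log sigma(Delta+) + mean_noise log(1 - sigma(Delta-))] with
    Delta = (s + C) - log p_n.  Equals 2 ln 2 when model and noise
    log-probabilities coincide on every event.
    """
    if not noise_events:
        raise ValueError("at least one noise event is required")
    dpos = unnormalized_logprob(table, positive) - float(
        noise.event_logprob(
            np.array([positive.site - 1]), np.array([SYMBOL_INDEX[positive.symbol]])
        )[0]
    )
    dneg = np.array(
        [
            unnormalized_logprob(table, e)
            - float(
                noise.event_logprob(
                    np.array([e.site - 1]), np.array([SYMBOL_INDEX[e.symbol]])
                )[0]
            )
            for e in noise_events
        ]
    )
    return float(-_log_sigmoid(dpos) - np.mean(_log_one_minus_sigmoid(dneg)))


def nce_loss_pair(
    table: EmbeddingTable,
    positive: PairEvent,
    noise_pairs: Sequence[PairEvent],
    noise: NoiseModel,
) -> float:
    """Pair-objective NCE loss; same shape as the single loss with
    suitability scores and factorized pair noise probabilities."""
    if not noise_pairs:
        raise ValueError("at least one noise pair is required")

    def _delta(p: PairEvent) -> float:
        logpn = float(
            noise.pair_logprob(
                np.array([p.first.site - 1]),
                np.array([p.second.site - 1]),
                np.array([SYMBOL_INDEX[p.first.symbol]]),
                np.array([SYMBOL_INDEX[p.second.symbol]]),
            )[0]
        )
        return pair_unnormalized_logprob(table, p) - logpn

    dpos = _delta(positive)
    dneg = np.array([_delta(p) for p in noise_pairs])
    return float(-_log_sigmoid(dpos) - np.mean(_log_one_minus_sigmoid(dneg)))


def combined_loss(
    table: EmbeddingTable,
    single_terms: float | Sequence[float],
    pair_terms: float | Sequence[float],
    alpha: float,
) -> float:
    """alpha * L_T + (1 - alpha) * L_C (terms averaged when given as lists)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    lt = float(np.mean(single_terms))
    lc = float(np.mean(pair_terms))
    return alpha * lt + (1.0 - alpha) * lc


@dataclass
class Gradients:
    """Parameter-shaped gradient accumulator for one sampled batch."""

    site_vectors: np.ndarray
    symbol_vectors: np.ndarray
    C: float
    C_pair: float
    loss: float


@dataclass(frozen=True)
class _Batch:
    """Encoded sampled batch: 0-based site and symbol index arrays."""

    pos_sites: np.ndarray
    pos_syms: np.ndarray
    neg_sites: np.ndarray
    neg_syms: np.ndarray
    pair_pos: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    pair_neg: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]


def _single_deltas(
    table: EmbeddingTable, sites0: np.ndarray, syms: np.ndarray, noise: NoiseModel
) -> np.ndarray:
    scores = np.einsum(
        "nd,nd->n", table.site_vectors[sites0], table.symbol_vectors[syms]
    )
    return scores + table.C - noise.event_logprob(sites0, syms)


def _pair_deltas(
    table: EmbeddingTable,
    pair: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    noise: NoiseModel,
) -> np.ndarray:
    si, sj, ci, cj = pair
    scores = np.einsum(
        "nd,nd->n", table.site_vectors[si], table.site_vectors[sj]
    ) + np.einsum("nd,nd->n", table.symbol_vectors[ci], table.symbol_vectors[cj])
    return scores + table.C_pair - noise.pair_logprob(si, sj, ci, cj)


def batch_loss_and_gradients(
    table: EmbeddingTable, batch: _Batch, noise: NoiseModel, alpha: float
) -> Gradients:
    """Analytic loss and gradients of the combined NCE objective on a batch.

    The per-positive site-vector gradient reduces to
    -(1 - sigma(Delta+)) c_a for the single objective and
    -(1 - sigma(Delta+)) v_j (site half of n_j) for the pair objective;
    noise samples contribute with coefficient +sigma(Delta-).
    """
    dv = np.zeros_like(table.site_vectors)
    dc = np.zeros_like(table.symbol_vectors)
    dC = 0.0
    dCp = 0.0
    loss_t = 0.0
    loss_c = 0.0

    if alpha > 0.0:
        dpos = _single_deltas(table, batch.pos_sites, batch.pos_syms, noise)
        dneg = _single_deltas(table, batch.neg_sites, batch.neg_syms, noise)
        loss_t = float(
            -np.mean(_log_sigmoid(dpos)) - np.mean(_log_one_minus_sigmoid(dneg))
        )
        w_pos = -(1.0 - _sigmoid(dpos)) / len(dpos) * alpha
        w_neg = _sigmoid(dneg) / len(dneg) * alpha
        for sites0, syms, w in (
            (batch.pos_sites, batch.pos_syms, w_pos),
            (batch.neg_sites, batch.neg_syms, w_neg),
        ):
            np.add.at(dv, sites0, w[:, None] * table.symbol_vectors[syms])
            np.add.at(dc, syms, w[:, None] * table.site_vectors[sites0])
            dC += float(w.sum())

    if alpha < 1.0:
        ppos = _pair_deltas(table, batch.pair_pos, noise)
        pneg = _pair_deltas(table, batch.pair_neg, noise)
        loss_c = float(
            -np.mean(_log_sigmoid(ppos)) - np.mean(_log_one_minus_sigmoid(pneg))
        )
        w_pos = -(1.0 - _sigmoid(ppos)) / len(ppos) * (1.0 - alpha)
        w_neg = _sigmoid(pneg) / len(pneg) * (1.0 - alpha)
        for (si, sj, ci, cj), w in ((batch.pair_pos, w_pos), (batch.pair_neg, w_neg)):
            np.add.at(dv, si, w[:, None] * table.site_vectors[sj])
            np.add.at(dv, sj, w[:, None] * table.site_vectors[si])
            np.add.at(dc, ci, w[:, None] * table.symbol_vectors[cj])
            np.add.at(dc, cj, w[:, None] * table.symbol_vectors[ci])
            dCp += float(w.sum())

    return Gradients(
        site_vectors=dv,
        symbol_vectors=dc,
        C=dC,
        C_pair=dCp,
        loss=alpha * loss_t + (1.0 - alpha) * loss_c,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.exp(_log_sigmoid(x))


def _encode_sequences(seqs: Sequence[AlignedSequence]) -> np.ndarray:
    return np.stack([s.encoded() for s in seqs])


def _sample_batch(
    high: np.ndarray,
    sites: np.ndarray,
    noise: NoiseModel,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> _Batch:
    b = config.batch
    rows = rng.integers(0, len(high), size=b)
    pos_sites = sites[rng.integers(0, len(sites), size=b)]
    pos_syms = high[rows, pos_sites].astype(np.int64)
    n_noise = b * config.noise_per_positive
    neg_sites, neg_syms = noise.sample_events(n_noise, rng)

    prow = rng.integers(0, len(high), size=b)
    i = rng.integers(0, len(sites), size=b)
    j = rng.integers(0, len(sites) - 1, size=b)
    j = np.where(j >= i, j + 1, j)
    pi, pj = sites[i], sites[j]
    pair_pos = (pi, pj, high[prow, pi].astype(np.int64), high[prow, pj].astype(np.int64))
    pair_neg = noise.sample_pairs(n_noise, rng)
    return _Batch(pos_sites, pos_syms, neg_sites, neg_syms, pair_pos, pair_neg)


def train(
    S_h_sequences: Sequence[AlignedSequence],
    S_l_sequences: Sequence[AlignedSequence],
    stats: SiteStatistics,
    config: TrainingConfig,
    *,
    return_history: bool = False,
) -> EmbeddingTable | tuple[EmbeddingTable, np.ndarray]:
    """Learn an embedding table from the high/low condition sets.

    Positives are (site, symbol) occurrences drawn from S_h (augmented with
    pseudo-sequences when ``augment_factor`` > 0); noise comes from a
    smoothed per-site model fitted on S_l.  Optimized with Adam on sampled
    mini-batches; stops at the step limit or when the windowed mean loss
    stops moving.  Deterministic given ``config.seed``.
    """
    if not S_h_sequences or not S_l_sequences:
        raise ValueError("both S_h and S_l must be non-empty")
    l = len(S_h_sequences[0])
    high = _encode_sequences(S_h_sequences)
    low = _encode_sequences(S_l_sequences)
    if high.shape[1] != l or low.shape[1] != l:
        raise ValueError("all sequences must share the aligned length")

    if config.train_all_sites:
        sites = np.arange(l)
    else:
        sites = np.array(sorted(k - 1 for k in stats.selected), dtype=np.int64)
    if len(sites) < 2:
        raise ValueError(
            "fewer than 2 selected sites; lower omega or set train_all_sites"
        )

    rng = np.random.default_rng(config.seed)
    if config.augment_factor > 0:
        aug_seed = int(rng.integers(0, 2**31 - 3))
        hp = sample_generator.SiteProfile(
            class_label="high",
            distributions=_profile_matrix(high),
        )
        lp = sample_generator.SiteProfile(
            class_label="low",
            distributions=_profile_matrix(low),
        )
        n_h = config.augment_factor * len(high)
        n_l = config.augment_factor * len(low)
        high = np.vstack(
            [high, _encode_sequences(
                sample_generator.generate_pseudo_sequences(hp, n_h, seed=aug_seed)
            )]
        )
        low = np.vstack(
            [low, _encode_sequences(
                sample_generator.generate_pseudo_sequences(lp, n_l, seed=aug_seed + 1)
            )]
        )

    if config.noise_model == "uniform":
        noise = NoiseModel.uniform(l, sites)
    else:
        noise = NoiseModel.from_matrix(low, sites, eps=config.noise_smoothing)

    table = EmbeddingTable(
        site_vectors=rng.normal(0.0, config.init_scale, size=(l, config.d)),
        symbol_vectors=rng.normal(0.0, config.init_scale, size=(N_SYMBOLS, config.d)),
        C=0.0,
        C_pair=0.0,
    )

    adam = _AdamState(table, config)
    history = np.empty(config.steps)
    n_done = config.steps
    prev_window: float | None = None
    for step in range(config.steps):
        batch = _sample_batch(high, sites, noise, config, rng)
        grads = batch_loss_and_gradients(table, batch, noise, config.alpha)
        if not np.isfinite(grads.loss):
            raise FloatingPointError(
                f"training diverged at step {step}: loss={grads.loss!r} "
                f"(lr={config.learning_rate}, d={config.d})"
            )
        adam.update(table, grads)
        history[step] = grads.loss
        w = config.convergence_window
        if w > 0 and (step + 1) % w == 0:
            mean_w = float(history[step + 1 - w : step + 1].mean())
            if prev_window is not None:
                denom = max(abs(prev_window), 1e-12)
                if abs(mean_w - prev_window) / denom < config.convergence_tolerance:
                    n_done = step + 1
                    break
            prev_window = mean_w
    history = history[:n_done]
    return (table, history) if return_history else table


def _profile_matrix(matrix: np.ndarray) -> np.ndarray:
    counts = np.stack(
        [np.bincount(matrix[:, j], minlength=N_SYMBOLS) for j in range(matrix.shape[1])]
    ).astype(float)
    return counts / counts.sum(1, keepdims=True)


class _AdamState:
    """Plain Adam over the four parameter groups."""

    def __init__(self, table: EmbeddingTable, config: TrainingConfig) -> None:
        self.cfg = config
        self.t = 0
        self.m = {
            "v": np.zeros_like(table.site_vectors),
            "c": np.zeros_like(table.symbol_vectors),
            "C": 0.0,
            "Cp": 0.0,
        }
        self.s = {
            "v": np.zeros_like(table.site_vectors),
            "c": np.zeros_like(table.symbol_vectors),
            "C": 0.0,
            "Cp": 0.0,
        }

    def update(self, table: EmbeddingTable, grads: Gradients) -> None:
        cfg = self.cfg
        self.t += 1
        bc1 = 1.0 - cfg.beta1**self.t
        bc2 = 1.0 - cfg.beta2**self.t

        def step(m, s, g):
            m = cfg.beta1 * m + (1 - cfg.beta1) * g
            s = cfg.beta2 * s + (1 - cfg.beta2) * np.square(g)
            delta = cfg.learning_rate * (m / bc1) / (np.sqrt(s / bc2) + cfg.eps)
            return m, s, delta

        self.m["v"], self.s["v"], dv = step(self.m["v"], self.s["v"], grads.site_vectors)
        self.m["c"], self.s["c"], dc = step(
            self.m["c"], self.s["c"], grads.symbol_vectors
        )
        self.m["C"], self.s["C"], dC = step(self.m["C"], self.s["C"], grads.C)
        self.m["Cp"], self.s["Cp"], dCp = step(self.m["Cp"], self.s["Cp"], grads.C_pair)
        table.site_vectors -= dv
        table.symbol_vectors -= dc
        table.C -= float(dC)
        table.C_pair -= float(dCp)


def capability_matrix(table: EmbeddingTable) -> np.ndarray:
    """(l, 21) chart of capability scores v_k . c_s for every site and symbol."""
    return table.site_vectors @ table.symbol_vectors.T
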