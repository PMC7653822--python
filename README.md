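# enzopt

Sequence-embedding analysis of enzyme optimal conditions.

Enzymes in one family share a function but peak at different environmental
conditions — a GH11 xylanase may be most active at pH 5 or pH 9 depending on
a handful of non-conserved alignment positions. `enzopt` learns, from an
aligned protein family labeled with optimal-condition values (e.g. optimal
pH), which residues at which alignment sites push the optimum up or down,
and uses that to (a) rank sequences by predicted optimal condition and
(b) propose single- and multi-site substitutions toward an expected
condition (rational design). It is aimed at protein engineers and
computational biologists who have an MSA plus per-sequence condition labels
and no tertiary structures or free-energy data.

## Model

Every alignment site *k* and every symbol *a* (20 amino acids + the gap
`-`) gets a latent vector **v**ₖ, **c**ₐ ∈ ℝᵈ. Two scores are read off the
embeddings:

- capability score *s(k, a)* = **v**ₖ · **c**ₐ — how symbol *a* at site *k*
  shifts the optimal condition;
- suitability score *s(nᵢ, nⱼ)* = (**v**ᵢ ⊕ **c**ᵢ) · (**v**ⱼ ⊕ **c**ⱼ)
  = **v**ᵢ·**v**ⱼ + **c**ᵢ·**c**ⱼ — the joint effect of two occupied sites.

The labeled family is split at a pH threshold (default 7) into a
high-condition set S_h and a low-condition set S_l. Embeddings are trained
by noise-contrastive estimation: the softmax normalizer is replaced by a
learnable scalar *C*, and the model learns to discriminate (site, symbol)
events drawn from S_h against events from a noise distribution fitted on
S_l, for both the single-site and the pair objective, blended by a
preference α (default 0.4): L = α·L_T + (1−α)·L_C, optimized with Adam.

Training and scoring are restricted to *selected* sites — those whose
information gain about the high/low class, Gain(k) = H(y) − H(y|k), is at
least ω (default 0.0478 bits); the rest are conserved or uninformative. A
sequence's predicted condition is summarized by

    Score(a) = α · Σₖ s(k, aₖ) + (1−α) · Σᵢ<ⱼ s(nᵢ, nⱼ) / l

over selected sites. Because small families rarely support numeric
regression, sequences are compared pairwise by Score; accuracy is the
fraction of held-out pairs whose score order matches their label order.

Mutation suggestions maximize Score subject to two rules: never mutate a
gap position, never mutate a site with gain < ω; at most 3 sites are edited
(exhaustive search for small candidate sets, greedy otherwise).

A small-sample *approximation method* augments training: per-class,
per-site symbol frequencies are fitted on the training split and
pseudo-sequences are sampled from them site-independently.

## Worked example

No external data is needed — the package ships a synthetic-family generator
that plants condition-discriminative sites (Lys/Arg favoured in the
high-pH class, Asp/Glu in the low-pH class):

```
enzopt simulate --n 120 --length 60 --planted 8 --effect 0.9 --seed 7 \
    --out-msa synth.afa --out-labels synth.tsv
enzopt gain  --msa synth.afa --labels synth.tsv --omega 0.0478 --out gains.tsv
enzopt train --msa synth.afa --labels synth.tsv --dim 30 --alpha 0.4 \
    --steps 3000 --seed 7 --out model.tsv
enzopt rank  --msa synth.afa --labels synth.tsv --model model.tsv \
    --gains gains.tsv --out ranking.tsv
enzopt suggest --model model.tsv --msa synth.afa --labels synth.tsv \
    --wild low_0 --out suggestions.tsv
```

Output printed by these commands on this example:

```
planted sites: [14, 33, 34, 38, 45, 50, 51, 56]
wrote 60 sites, 38 selected, to gains.tsv
trained d=30 embeddings on 38 selected sites; saved to model.tsv
pairwise ranking accuracy 0.725 (5180/7140 pairs); ranking written to ranking.tsv
single: D56R  score 2.5272 -> 4.3197 (delta +1.7926)
multi: D56R/D50R/D38R  score 2.5272 -> 7.8928 (delta +5.3656)
```

The ranking accuracy is the fraction of sequence pairs whose score order
matches their label order. High-vs-low pairs are ordered almost perfectly;
the overall number is diluted by same-class pairs, whose labels this
generator draws independently of the sequence, so no scorer can order them
(see `docs/methods.md`). The suggestion lines read: mutating Asp→Arg at
aligned site 56 of the wild type `low_0` raises its quantitative score by
1.79, i.e. the model predicts a shift toward alkali tolerance; the 3-site
mutant swaps acidic for basic residues at three of the planted sites
(38, 50, 56).

The same pipeline is available as a library (`enzopt.generate_synthetic_family`,
`enzopt.train`, `enzopt.cross_validate`, `enzopt.best_multi_mutation`, ...).

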