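# camkit

Analysis toolkit for **cognitive-affective maps (CAMs)** — participant-drawn
belief networks in which concepts carry an affective valence on the integer
scale −3 (strongly negative) to +3 (strongly positive), or a distinct
*ambivalent* state, and are joined by signed connectors with strength in
{−3..−1, +1..+3} (positive = supporting, negative = opposing), optionally
directed. A CAM is a weighted, optionally directional simple graph; a CAM
study produces one such graph per participant.

camkit is written for behavioral researchers who collect CAMs online and need
a scriptable, auditable desk-analysis pipeline:

- **model** — parsing, invariant checking, validation against a study
  configuration (minimum concepts, word/character limits, feature switches),
  canonical byte-stable JSON, CSV/GraphML interop;
- **summarize** — computer-assisted grouping of raw concept texts under
  superordinate categories via optimal string alignment (OSA) distance,
  regular expressions (with POSIX classes), synonym dictionaries, and
  word-vector cosine similarity; application of a summary map with optional
  valence splitting (`Cost_positive` vs `Cost_negative`);
- **reliability** — partition-based inter-rater agreement: rater category
  names are aligned (greedy or optimal one-to-one assignment) before
  pairwise Cohen's κ, Fleiss' κ and category-wise κ are computed, so the
  coefficients depend only on *which concepts are grouped together*;
- **indicators** — macro (mean valence, density, diameter, class shares),
  micro (degree, betweenness, closeness), mezzo (greedy-modularity
  communities), and six neighborhood-valence variants with temporary
  edge/node removal for bridged study designs;
- **wordlevel / aggregate / cooccur / slicing** — word lists with
  valence/degree statistics, per-CAM frequency tables, canonical
  frequency-weighted aggregation across CAMs (duplicate labels renamed
  `cost_1`, `cost_2`, … by descending degree), pairwise φ coefficients on
  per-participant presence with χ²/Fisher significance, Ward/Euclidean
  clustering of z-scored valence profiles, and CAM slicing with validated
  component counts plus within-subject *t* tests;
- **synth** — a synthetic CAM generator (star, two-cluster, tree, mesh
  topologies; latent-attitude valence model; planted typo/synonym noise)
  with full ground truth, so every analysis is testable end to end;
- **protocol** — an append-only, hash-chained record of every analysis step
  that can be *replayed* against the raw inputs to verify all outputs.

## Key statistics

Edit distance (approximate matching): OSA — the restricted
Damerau–Levenshtein distance with insertions, deletions, substitutions and
adjacent transpositions; `osa("dreams", "dreasm") = 1`.

Cohen's κ = (p_o − p_e)/(1 − p_e); Fleiss' κ from the item×category count
table n_ij with P̄ = mean_i (Σ_j n_ij² − n)/(n(n−1)) and P̄_e = Σ_j p_j²;
category-wise κ_j = 1 − Σ_i n_ij(n − n_ij) / [N n (n−1) p_j(1−p_j)].

Co-occurrence: φ = (ad − bc)/√[(a+b)(c+d)(a+c)(b+d)] on the 2×2 per-CAM
presence table, with χ² = N·φ² (1 df).

## Worked example

```python
from camkit.synth import GenConfig, generate_cam_set
from camkit.indicators import macro_indicators
from camkit.cooccur import valence_clusters

cfg = GenConfig(topology="two_cluster", n_cams=5, seed=1)
cams, truth = generate_cam_set(cfg)
print({r.indicator: round(r.value, 3) for r in macro_indicators(cams[0])
       if r.indicator in ("mean_valence", "density", "diameter")})
```

prints

```
{'mean_valence': 0.154, 'density': 0.154, 'diameter': 7.0}
```

— the first participant's overall affect is mildly positive, 15% of possible
concept pairs are connected, and the longest shortest path spans 7 steps.
The `examples/` directory contains one narrative script per capability
(generation/validation, summarization, reliability, indicators,
aggregation/co-occurrence/clustering, slicing/protocol); each prints its
numbers with a line on what they mean. A thin `cam` command-line interface
exposes the same operations (`cam --help`).

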