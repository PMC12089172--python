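# Methods

## The data model

A CAM is one participant's belief network about a topic. Concepts carry free
text, an optional comment, a screen position (stored, never analyzed), and an
affective valence: an integer in −3..+3 (0 = neutral, a legal persistent
state) or the distinct *ambivalent* state. Ambivalence is kept as a symbolic
marker, never a number, so it cannot silently enter arithmetic; every
operation that needs a number resolves it through an explicit policy
(`as_zero` by default, `exclude` on request). Percentage-type outputs always
count ambivalent as its own class.

Connectors have integer strength in {−3..−1, +1..+3} (zero is not a legal
edge) and an optional direction. CAMs are simple graphs: no self-loops, at
most one connector per concept pair; parallel connectors are rejected at
parse time. All distance/degree computations run on the undirected
projection — in- and out-degree are deliberately not distinguished — while
the directed structure is preserved in the data model for future indicators.

Serialization is canonical: keys sorted, concepts and connectors ordered by
id, so equal CAMs produce byte-identical JSON and content digests are
meaningful. CAM equality is correspondingly order-insensitive. A legacy
import hook maps a configurable numeric ambivalent code (default 10, as found
in older Valence-derived exports) to the marker.

## Summarization

All text matching operates on a normal form (case-fold, trim, collapse
internal whitespace): the raw data contains trivially different spellings of
the same concept and the notion of a "unique concept" must not depend on
them.

The four suggestion routes are deliberately simple and transparent:

- **OSA distance** (restricted Damerau–Levenshtein: insert, delete,
  substitute, transpose-adjacent, no substring edited twice) with groups
  formed as connected components of the `distance ≤ max_dist` graph
  (single-linkage closure; default `max_dist = 1`, the typo regime). OSA is
  implemented here directly — it is the method's core matching primitive —
  and is verified in the tests against an independent dynamic program. Note
  OSA violates the triangle inequality (the classic `ca`/`abc` family), so
  single-linkage groups may contain pairs farther apart than the threshold;
  that is intended (a chain of typos is one group).
- **Regular expressions** in the host dialect with a POSIX-class translation
  layer (`[[:digit:]]` → `[0-9]`, …), case-insensitive by default.
- **Synonym dictionaries** (word → synonym list, symmetrized at load time):
  single-word texts are linked when their synonym sets (each including the
  word itself) intersect. A tiny built-in fixture dictionary ships for tests
  and examples; real thesauri plug in through the same mapping type.
- **Word-vector cosine similarity** above a researcher-chosen threshold.
  No language model is bundled; vectors come from any `text → vector`
  mapping or a CSV vector table. Texts without vectors are reported, not
  dropped.

Applying a `SummaryMap` replaces matched concept texts by their category
label (optionally suffixed `_positive`/`_negative`/`_neutral`/`_ambivalent`
by the concept's valence) and preserves the original in `raw_text`, making
the operation idempotent and reversible by inspection. It never touches
valences or connectors. Category *naming* is the researcher's act; the
toolkit only suggests groupings and records the applied map in the protocol.

## Inter-rater reliability

Raters code the same sampled concepts into categories using their own label
vocabularies. The partition is what should be reliable, so labels are first
aligned onto a shared index space:

- `exact_overlap`: greedy one-to-one matching in descending overlap count;
- `max_overlap`: the assignment maximizing total overlapping items, solved
  exactly with the Hungarian algorithm (category counts are small).

Ties in both variants are broken by the categories' *member-item
fingerprints* (the sorted set of items a category contains), not by the
raters' labels. This makes every coefficient exactly invariant under
category renaming — the defining requirement — which a label-lexicographic
tie-break would violate whenever two assignments are equally good. With more
than two raters, the rater with the most categories anchors the space and
the others are aligned to it sequentially.

Cohen's κ, Fleiss' κ and category-wise κ are computed from first principles
(formulas in the README); the degenerate single-category case (p_e = 1)
returns 1 for perfect agreement and 0 otherwise rather than 0/0.

**Null behavior of aligned κ.** Overlap-maximizing alignment picks the
luckiest matching, so under truly independent coding it inflates agreement:
for 4 equiprobable categories and 200 items the optimal matching of the
random 4×4 contingency table raises κ to roughly +0.08 on average. Null
calibration (and the corresponding test) therefore evaluates κ on a shared
label space directly; the aligned coefficients should be interpreted
against that positive floor, which is also why both alignment variants are
always reported side by side.

## Network indicators

Macro: mean valence, central-node valence (explicit id > predefined flag >
maximum degree, ties by lexicographic id), density m/[n(n−1)/2], diameter of
the largest connected component (flagged rather than infinite on
disconnected CAMs; undefined-flagged quantities are NaN throughout), node
and link counts, and the four valence-class shares (always summing to 1).
Micro: degree, betweenness, closeness (within the concept's component).
Mezzo: greedy modularity communities on the undirected projection with
deterministic ordering, per-community size, mean valence, internal density.

Neighborhood valence comes in six variants over N₁ (adjacent concepts) and
N₂ (distance ≤ 2), both excluding the focus: plain means (v1, v2),
strength-weighted means (v3 over N₁ with weight |strength|; v4 over N₂ with
weight = max over shortest paths of Π|strength|/3), and affect-adjusted
means (v5, v6: the numerator sums all numeric valences, the denominator
counts only non-neutral, non-ambivalent concepts — the mean "per
affect-carrying neighbor"). The affect adjustment is one defensible reading
of adjusting for rated concepts; the variant registry names every output so
an alternative adjustment can be swapped without touching callers. Temporary
edge/node removals support bridged designs where one side's neighborhood
must be measured without the other leaking in. Results of empty
neighborhoods (or empty denominators) are NaN, not 0.

## Aggregation, co-occurrence, clustering, slicing

Aggregation runs after summarization and matches labels by exact string
equality. Within each CAM duplicate labels are first canonicalized
(`cost_1`, `cost_2`, … by descending degree, ties by concept id). Node
frequency counts CAMs containing a label (not concept instances); edge
frequency counts CAMs connecting a pair, any sign or direction. Mean
strength is carried as an auxiliary attribute only — the aggregate's weights
are frequencies. Aggregation is order-independent and exports to
GraphML/DOT/adjacency-CSV.

Concept co-occurrence uses binary per-CAM presence (a participant counts
once however many instances they drew). φ is accompanied by the uncorrected
1-df Pearson χ² p-value (preserving the φ = sign(ad−bc)·√(χ²/N) identity
exactly) and by Fisher's exact p whenever an expected cell is below 5. Raw
p-values are primary; a Benjamini–Hochberg-adjusted column is provided as an
explicitly opt-in reading, since the pairwise matrix is a screening device.

Valence clustering builds the CAM × concept matrix of per-CAM mean valences
over concepts drawn at least twice, z-transforms columns on the *observed*
cells, imputes missing cells at the grand mean (0 after the transform,
flagged per cell), and clusters CAMs with Ward linkage on Euclidean
distance. The clustered objects are participants (to find groups with
similar affective profiles); a transpose switch clusters concepts instead.
The flat k-cut comes with a cluster × concept profile of mean z-scores for
interpretation.

Slicing addresses deletion targets by concept text (one spec must apply
across all participants); ambiguous duplicate texts are an error directing
the user to canonical suffixes. Validation criteria: component count equals
the expectation, no component below the configurable minimum size, and —
when anchors are given — anchors resolve one-to-one onto components.
Components become standalone CAMs re-ingestable by every other module. The
within-subject comparison runs a paired t test on component mean valence
(t = mean(d)/(sd(d)/√n), df = n−1, effect size d_z); zero difference
variance yields an undefined-flagged result, not 0 or ∞.

## Synthetic generator

The generator emulates the structural regimes that predefined starting
concepts induce: a single central concept (star), two opposing anchors with
one negative bridge (two clusters), predefined roots (random recursive
tree), and free drawing (random connected mesh). Concept valences follow a
latent-attitude model: per participant μ ~ Normal(μ₀, τ), per concept
valence = clip(round(Normal(μ, σ)), −3, 3), with an independent
`p_ambivalent` coin overriding the draw. Connector strengths are uniform on
{+1, +2, +3} within clusters and {−3, −2, −1} on bridges (supporting-within,
opposing-between). Optional attitude groups (`group_means`) split
participants into latent subpopulations — the planted structure the valence
clustering should recover.

Defaults (chosen once as a realistic mid-size online study): 30 CAMs of
8–14 concepts from a 40-term vocabulary, μ₀ = 0, τ = 1, σ = 0.8,
p_ambivalent = 0.05, p_typo = 0.1. The vocabulary terms are pairwise ≥ 3
apart under OSA, so a planted single-edit typo can never collide with
another base term — this is what makes typo-recovery scoring well posed.
Text noise replaces a recorded fraction of texts with typos at OSA distance
exactly 1 (adjacent transposition of differing characters, or letter
substitution) or with dictionary synonyms, and returns the planted grouping.

One pseudo-random stream is derived per CAM from (seed, CAM index), so CAM i
is identical whatever `n_cams` is, and equal seeds give byte-identical sets.

What the generator does **not** emulate: drawing order and paradata,
comment text, participant-specific vocabulary sizes, structurally missing
data, or any coherence dynamics between connected concepts (a concept's
valence depends only on the participant's latent attitude, not on its
neighbors). Passing recovery tests on this data therefore demonstrates that
the pipeline's machinery is correct under the stated model, not that real
CAM data satisfies that model.

## Protocol

Every recorded operation appends one JSON line: operation name, full
parameter snapshot (seeds included), SHA-256 content digests of inputs and
outputs, and a rolling hash chaining the entry to its predecessor.
Timestamps are recorded but excluded from all digests, so replay verdicts
ignore wall-clock time. Replay re-executes each step from a registry of
named operations against the recorded raw inputs and passes only if every
digest matches; editing any earlier entry breaks the chain, and forging a
consistent chain with altered parameters is caught at the first diverging
output digest. The registry covers the pipeline operations
(generate/summarize/indicators/aggregate/word-list) and is extensible by
registration.

## Problem sizes in the test suite

Oracle-equivalence checks run 200 random CAMs of ≤ 8 nodes against
exhaustive-path brute-force implementations; the κ null calibration uses
500 replicates of 200 items; the φ identity uses 1,000 random tables;
recovery tests use 40-CAM synthetic sets (100 CAMs across 20 seeds for the
slicing sweep; 200 CAMs for the law-of-large-numbers check). The whole
suite runs in well under a minute.

## Known limitations

- The six neighborhood variants implement one defensible reading of the
  "adjustment for positive concepts"; no parity with any external tool's
  33-indicator catalogue is promised (the registry documents exactly which
  indicators exist).
- Correlations between indicators are reported with plain two-sided
  p-values and no multiplicity correction (screening output).
- The greedy `exact_overlap` alignment is one reading of "assuming a perfect
  match of overlapping categories"; both alignment variants are therefore
  always reported together.
- Negations and questions in concept texts are not handled automatically;
  how they were summarized is the researcher's documented decision.
- Chart rendering is out of scope: word-level modules emit the data tables
  charts are built from.
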