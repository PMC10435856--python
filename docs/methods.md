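# Methods

## Model

The unit of analysis is the monthly co-occurrence snapshot
G_t = (V_t, E_t): V_t is the set of (cluster-level) tags appearing in papers
published in month t, E_t the pairs co-occurring in at least one of those
papers. Edges are undirected and weighted by the association strength
SA = c_ij / (s_i·s_j), computed from within-month counts only — a snapshot
is a self-contained picture of the field that month, not a cumulative graph.
Tags that appear but never co-occur stay as isolated nodes: peripheral and
disconnected behavior is part of what the role model must see.

Role discovery stacks, over all months, a matrix of recursive structural
features per node-month and factorizes it into nonnegative factors W
(node-time × role, the *role relevance*) and H (role × feature, the *role
definitions*). The underlying assumption is that the diversity of
node behavior is explained by a small number of structural roles, and that a
node's behavior over time is a mixture trajectory over those roles. Because
features are pruned and normalized globally across months, the role space is
shared by the whole series, making mixtures comparable through time.

## Parameters that matter

- `dbscan.eps` (cosine distance, default 0.35) and `dbscan.min_samples`
  (default 2) govern tag merging. With the built-in trigram embedder, an
  edit-distance-1 misspelling of a tag with n trigrams lies at distance
  ≈ 3/n — about 0.2–0.4 for realistic 6–15-character keywords — while
  unrelated tags lie near 1. The default 0.35 sits between the two
  populations. Shorter eps leaves typos unmerged; much larger eps risks
  merging related-but-distinct concepts that share long substrings.
- `embedding.dim` (default 1024): hashed trigram space; collisions are rare
  at realistic vocabulary sizes and only perturb distances slightly.
- `refex.depth` (default 2): aggregation path length. Depth 2 already
  captures regional structure (e.g. `degree(sum)(mean)`); deeper paths grow
  the candidate set threefold per level and are mostly pruned as redundant.
- `refex.prune_threshold` (default 0.95, absolute Pearson): duplicates and
  affine copies are dropped; the scan order (shorter path first, then base
  order, then sum before mean) makes the retained set deterministic.
- `rolx.r_min`..`r_max` (default 2..8) bound the MDL search;
  `rolx.restarts` (default 3) seeded random initializations compete with
  one SVD-based (NNDSVD-style) initialization per fit.
- `analysis.k` (default 20) and `analysis.min_freq` (default 2) shape the
  neighbor rankings and the transition rule.
- One `seed` drives every stochastic component (restarts, generator).

## Numerical choices

- Edge weights are stored as the exact IEEE quotient c/(s_i·s_j); writers
  serialize floats with shortest-repr so round trips are bit-identical. The
  pair count is recoverable as round(w·s_i·s_j).
- PageRank runs to tolerance 1e-12 so values are reproducible to more
  digits than any downstream use.
- Eigenvector centrality is computed per connected component (dense
  symmetric eigensolver, Perron vector, L2-normalized within the
  component; isolates score 0). Per-component normalization deliberately
  gives members of small components large values: it is a within-component
  importance, and the contrast with degree is informative for the
  peripheral roles.
- Betweenness and closeness use unweighted shortest paths: association
  strengths are similarities, and no principled distance transform of them
  is assumed. Closeness is the within-component form
  (reachable−1)/Σdistances.
- NMF uses Frobenius multiplicative updates (max 500 iterations, relative
  error-change tolerance 1e-6, epsilon-guarded denominators). Zero entries
  of an initialization are exact fixed points of the updates; rank
  selection exploits this by warm-starting r+1 from the rank-r solution
  padded with a zero role, and by admitting the warm point itself as a
  candidate, which makes the best fit error provably non-increasing in r.
- The MDL score prices the factors at log2(16) = 4 bits per entry
  (log-spaced 16-bin quantization) and the residual with a Gaussian code,
  N/2·log2(2πe·σ²) with σ² floored at 1e-12 — the standard two-part-code
  approximation: storage cost from the quantizer, error cost from the
  fitted factors. Ties in the score resolve to the smaller r.
- Correlations between a role and a measure are undefined (reported as
  NaN, never 0) when either column is exactly constant.
- All rankings break ties lexicographically; all iteration orders are
  sorted; dict orderings never leak into outputs. Rerunning any stage from
  its upstream artifacts reproduces downstream artifacts byte for byte.

## Design choices where the design was open

- **Clustering is global, not per-snapshot**: per-month merging would let
  the same surface form resolve to different clusters in different months,
  breaking node identity over time.
- **Noise tags become singleton clusters**, never dropped: noisy,
  randomly-attached tags are one of the behaviors the role model should
  represent, so they must survive into the graph.
- **Raw W feeds the correlation analysis; row-normalized mixtures feed
  trajectories.** Correlating against centrality measures needs the scale
  of the relevance; trajectory plots compare proportions within a node.
- **"Appears in role r at time t"** (for frequency tables and the
  transition rule) means membership in the top-k relevance ranking for
  role r relative to a chosen start tag. A global dominant-role reading
  (argmax of the mixture) is also provided (`dominant_role`); the ranking
  reading is the default because the frequency tables are defined relative
  to a neighborhood exploration.
- **Feature set is closed** at the six base features listed; an open-ended
  "and so on" is not reproducible. Pruning uses a correlation threshold
  rather than log-binning; same intent, deterministic and simpler.
- **Pruning and normalization are global across snapshots** so the stacked
  factorization sees one consistent feature space.

## The synthetic generator

The generator emulates the monthly paper stream the pipeline is built for:
Poisson paper counts per month (default mean 100 over 24 months), 3–8
keywords per paper, and a ~300-tag vocabulary partitioned into archetypes
with known structural signatures:

- *hubs* (4): included in core papers with probability 0.35 each — high
  degree and centrality every month;
- *themes* (6 groups of 8): each core paper samples one theme and 2–4 of
  its tags, padding with further tags of the same theme — dense topical
  blocks;
- *noise* (220): appear only in dedicated noise-only papers (20% of
  papers, 3–5 rare tags each) — rare, randomly attached, forming small
  fringe components;
- *emerging* (10): inclusion probability 0.02 before the changepoint month
  (default month 12), 0.30 after — peripheral then central;
- *peninsulas* (3 groups of 6): group papers contain only group members
  plus the group's bridge tag; the bridge also enters core papers with
  probability 0.08 — internally dense, attached to the core through a
  single cut vertex (verifiably: every member→hub shortest path passes the
  bridge);
- optional *typo variants*: each tag occurrence is replaced by a
  pre-generated edit-distance-1 variant with probability `typo_rate`.

Vocabulary entries are pronounceable pseudo-words (random CV syllables,
8–12 characters), so trigram distances between distinct tags behave like
distances between unrelated real keywords.

What the generator does **not** emulate: Zipfian keyword frequencies within
an archetype, author/venue effects, citation structure, semantically related
but textually dissimilar synonyms (the built-in embedder only merges
surface-level variants — a transformer provider is needed for true synonym
merging), or gradual topic drift. Passing tests on this corpus therefore
demonstrate that the machinery recovers planted *structural* signal at desk
scale, not that any particular real-world corpus will show the same
patterns.

## Problem sizes

The default test and acceptance conditions are 24–25 months × ~100 papers
per month over a ~300-tag vocabulary (≈ 3,000–3,700 node-months, 15–20
retained features), factorized at 5 roles or with MDL selection over 2..8.
Counting oracles run on 200 random mini-corpora (≤ 50 papers); feature
oracles on all 143 connected graphs with ≤ 6 nodes plus 100 random graphs
with ≤ 8 nodes. A full pipeline run at the default scale completes in well
under a minute on one CPU.

## Known limitations

- DBSCAN with a single global eps cannot adapt to tag-length-dependent
  typo distances; very short tags (≤ 4 characters) may need a larger eps
  or an external embedder.
- NMF is non-convex: restarts mitigate but do not eliminate dependence on
  initialization; role indices are arbitrary and only meaningful relative
  to the correlation table.
- The MDL score compares models on one fixed quantization budget; it is a
  selection heuristic, not a posterior.
- Betweenness is exact (Brandes), which is the cost ceiling for very large
  snapshots; sampling-based approximations are out of scope.
- Role trajectories are only defined for months where a tag appears;
  absence itself (the missing marker) carries signal that the current
  queries surface but do not model.
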