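# Methods

## Hit filter

A paired pulldown yields, per protein, sequence (spectral) counts and
summed ion intensities in the WT control and the TG bait sample. Every
record maps to exactly one branch: `tg_only` (WT count 0, TG ≥ 1; always a
hit — a protein absent from the nonspecific-binding control needs no ratio
evidence), `wt_only` (never a hit), `shared_pass` / `shared_fail` (both
detected; pass requires both criteria):

- count criterion: TG count ≥ 2 × WT count. The phrase "two or more
  sequence counts in the TG sample compared to the WT sample" also admits a
  difference reading (TG ≥ WT + 2); the ratio reading is the default
  because it parallels the unambiguously ratio-phrased intensity criterion,
  and the alternative is exposed as `count_rule="difference"`.
- intensity criterion: TG intensity ≥ 2 × WT intensity. A WT protein
  detected with zero summed intensity is a degenerate comparison (anything
  is ≥ 2·0); we require a strictly positive TG intensity there.

Both criteria are inclusive at the boundary ("two or more", "at least
twice"). Increasing TG evidence can never remove a hit (monotonicity,
property-tested).

## Set comparison

Percentages of the common set are rounded half-up to one decimal, matching
how such shares are conventionally printed (e.g. 47/211 → 22.3%,
47/255 → 18.4%). Venn-region counts are computed by exhaustive membership
enumeration, which is exact and cheap at interactome sizes.

Region-enriched proteome: protein p is enriched in region r iff its
abundance there strictly exceeds `fold_threshold` (default 4) times the
median of its abundances across the *other* regions. With an even number of
other regions the midpoint median (mean of the two central values) is used
— the source proteome study does not restate its estimator, and the
midpoint convention is the standard one. Zero handling follows from the
strict rule: positive vs all-zero others is enriched, 0 vs 0 is not. A
protein may be enriched in several regions.

## Network topology

Subnetworks are induced on an undirected simple background PPI graph; query
proteins absent from the background are kept as isolated nodes and counted
among the orphans (nodes of degree 0), which figure legends report
separately. Orphans are excluded from path and degree statistics.

Average path length is the mean shortest-path length over all unordered
pairs of distinct nodes *within the same connected component*; disconnected
pairs are excluded rather than penalized, because a single finite value is
reported for networks that contain several components. Harmonic-mean or
giant-component conventions would be alternatives; connected-pairs is the
package's convention throughout, including inside the resampling null, so
observed and null statistics are always comparable. Computation uses
C-implemented sparse-graph BFS (scipy.sparse.csgraph), verified against an
independent pure-Python all-pairs BFS oracle in the tests.

Degree distributions are summarized by a discrete power-law exponent α
fitted by maximum likelihood: P(x) = x^−α / ζ(α, x_min) for integer
x ≥ x_min, α maximizing the likelihood via bounded scalar minimization of
the negative log-likelihood. Default x_min = 1 (no binning or tail-cut
decisions); for generators with a built-in minimum degree (preferential
attachment adds m edges per node, so degrees start at m) pass x_min = m,
otherwise the flat head biases α down. The fit is reported as absent for
fewer than 10 usable degrees or an all-equal degenerate sample. Parameter
recovery (±0.1 at 10,000 draws, α = 2.5) and the preferential-attachment
asymptote (α → 3) are under test. Published exponents fitted with an
unknown procedure are not implementation targets; the estimator here is the
package's own, stated choice.

### Resampling null

Each of n resamples draws |query| nodes uniformly *without replacement*
from the full background node list (nodes that end up orphaned in the
induced subgraph are legitimate draws — the published procedure selects
proteins, not connected proteins), and the empirical P-value is
N_i/n with N_i the count of resample statistics strictly smaller than the
observed one — no +1 pseudocount, ties count as not-smaller, exactly the
printed formula. Resamples with an undefined statistic (no connected pair)
count as not-smaller; an undefined observed statistic behaves as +∞. The
estimator's resolution is 1/n (published analyses used n = 10,000; the
analysis scripts here default to n = 1,000, ample for the synthetic study
and resolved well past the planted effects). Calibration is verified by a
null-of-null experiment: with the observed set itself drawn at random, the
empirical P is approximately uniform (Kolmogorov–Smirnov across 100
repetitions at n = 200).

## Enrichment

For query size m, gene-set size K and universe size N (all after
intersection with the universe — the universe is an explicit argument, not
an implicit default, precisely because published analyses switch between a
proteome and an interactome background), the raw P-value is the exact
upper tail P(X ≥ k) = sf(k − 1) of Hypergeometric(N, K, m). BH step-up
adjustment is applied across the collection (statsmodels; an independent
brute-force step-up implementation serves as the test oracle), and
adjusted P < 0.05 is flagged significant.

**Tail conventions.** R's `phyper(q, m, n, k)` returns the *lower* tail
unless `lower.tail=FALSE` is passed; the enrichment idiom is
`phyper(overlap − 1, ..., lower.tail=FALSE)`. For the published overlap of
10 between a 208-protein query and a 372-protein set in a 7,880-protein
universe, the upper tail is 0.523 while the literal `phyper` call without
`lower.tail=FALSE` gives P(X ≤ 9) = 0.477 — and 0.48 is the published
value. `hypergeom_lower_tail` reproduces that convention so published
values can be audited; `run_enrichment` always uses the upper tail (the
only reading under which strong over-representation yields small P-values,
as in the published disease-association results). Either way the
conclusion there is unchanged: the overlap is indistinguishable from
chance (expected overlap 208·372/7880 ≈ 9.8 vs observed 10).

## Synthetic data

The generators define the study conditions; all defaults are fixed:

- **Detection table** (composition 137 TG-only / 74 shared-pass / 185
  shared-fail, the published partition): shared-pass rows sample WT count
  in 1–9, TG count = 2·WT + jitter (jitter 0–7, forced ≥ 1 when WT = 1 so
  the row passes under both count-rule readings) and TG intensity
  2·WT·U(1, 3); shared-fail rows violate exactly one randomly chosen
  criterion, so each criterion is exercised independently. Intensities are
  log-normal (meanlog 12, sdlog 1 — a realistic summed-ion-current scale).
- **Background graph**: Barabási–Albert preferential attachment, chosen
  because region-specific interactome degree distributions follow a
  power-law decay; defaults 788 nodes with 40 edges per new node, a
  1/10-scale emulation of the published brain interactome (7,880 nodes,
  319,756 edges; the scaled graph has 29,920 = m(n − m) edges, the
  generator's closed form, asserted in tests).
- **Abundance matrix** (1,000 proteins × 10 regions, 30 planted enriched
  per region ≈ the published proteome's fraction of region-enriched
  proteins): a log-normal(0, 1) per-protein level shared across regions
  with log-normal(0, 0.15) per-cell region jitter, then planted cells set
  to 4 × other-region median × U(1.25, 2.5). The small jitter keeps
  baseline between-region ratios orders of magnitude below the 4-fold
  bound, so the planted labels are *exactly* the rule's output — a fully
  independent log-normal per cell would plant false positives. Real
  proteomes have heavier region covariance and missing values; passing
  these tests shows the rule and plumbing are correct, not that the
  thresholds are biologically tuned.
- **Gene sets**: null sets are uniform draws from the universe; planted
  sets force the query overlap to 3 × its null expectation.

Every generator is a pure function of its spec (seed included): identical
seeds give byte-identical outputs.

## Pipeline

One master seed spawns per-stage seeds through `numpy.random.SeedSequence`,
so the consolidated report is byte-identical across runs of the same config
while stages remain individually reproducible. Any stage failure aborts
with the stage name. Stage outputs on disk are exactly the values embedded
in the report (tested).

## Known limitations

- The published network statistics (131/344 nodes/edges, path lengths
  2.89/2.27, α 2.98/2.75) depend on a specific APID database snapshot and
  supplementary protein lists and are not recomputable from first
  principles; the package reproduces the *procedures* and validates them on
  planted synthetic truth instead.
- Peptide-level identification, FDR control and homolog conversion are
  upstream of this package's protein-level inputs (a user-supplied mapping
  table replaces live homolog lookups).
- The connected-pairs path-length convention rewards sparse subgraphs whose
  few connected pairs are adjacent; comparisons are therefore only made
  between equally-sized sets on the same background, as in the resampling
  null.
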