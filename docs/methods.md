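# Methods

## The enrichment model

The pipeline treats tissue identification as a set over-representation
problem. The universe is the set of N proteins detected by mass
spectrometry in the queried sample — a cell is *detected* when it carries
any reported intensity, including 0 (detected-absent); empty/NA cells are
*missing* and excluded everywhere. The query is the sample's top
percentile band: with q the query percentile (default 98) and m detected
values sorted ascending, the threshold is the value at nearest rank
⌈q/100·m⌉ and every protein at or above it is selected. Nearest-rank was
chosen over interpolating percentile definitions because it is
deterministic, needs no convention for the interpolation weights, and
matches the "proteins present in the q-th percentile" reading; the
inclusive tie policy means the query can exceed m·(1−q/100) when values
tie at the threshold.

For each tissue with M characteristic proteins inside the universe and
overlap k with the query, the p-value is the hypergeometric upper tail
P(X ≥ k). The universe intersection is applied *before* M is counted:
the formula requires M ≤ N, and a tissue protein never detected in the
sample cannot contribute to the overlap. Tissues left with M = 0 are
skipped with a warning and do not count toward the Bonferroni family, so
the family size T is the number of tissues actually tested. Adjusted
p-values are min(1, p·T) via statsmodels' multiple-testing machinery.
Records are ordered by adjusted p with alphabetical tie-break — ties are
common in null-like data where p depends only on k — making outputs
byte-stable.

A lower tail P(X ≤ k) is provided for describing under-represented
tissues, but it is deliberately non-canonical: the enrichment test is
upper-tail only, and no depletion test is part of the standard run.

## Reference construction

The annotation route declares a protein tissue-specific when at least
one annotation row in that tissue has exactly the configured staining
level and stained-cell fraction (defaults: strong, 25–75%). The literal
25–75% window is kept as the default rather than folding in >75%; both
choices are one argument away.

The expression route applies the same nearest-rank cutoff per tissue
column of a protein × tissue matrix (default 80th percentile) over that
tissue's detected values, storing the per-tissue thresholds in the
library provenance so the selection is auditable.

The promiscuity filter removes proteins occurring in **more than**
`max_tissues` (default 2) tissue sets. The alternative literal reading —
discarding proteins found in at most two tissues — is expressible as
`max_tissues=1` plus inversion of perspective, but the default follows
the filter's purpose: a protein in many tissues carries no
tissue-identity information, whereas a protein in one or two tissues is
exactly the signal the test needs. The filter is idempotent and records
itself in provenance.

## Numerical choices

Binomial coefficients are computed as log-gamma differences and tail
terms combined with log-sum-exp. The requested tail is always summed
*directly*: its terms are all positive, so direct summation is
cancellation-free whether the tail is 10⁻³⁰⁰ or 1−10⁻¹⁶, whereas
computing a tiny tail as 1 − (other tail) destroys it at double
precision. Against exact rational enumeration over every valid
(N ≤ 25, M, n, k) the worst relative error is ~10⁻¹⁴, and against an
independent implementation it stays below ~10⁻¹¹ at N in the thousands.
P-values are floored at the smallest positive double (≈ 4.9·10⁻³²⁴) and
the floor is logged; a reported p of exactly 0 is never emitted.

## Tissue-sharing network

Nodes are tissues with overlap k ≥ 1 — not only significant ones, since
the display encodes significance continuously through node size
−log10(p_adj); a `significant_only` switch restricts to p_adj < α. Edges
connect tissues sharing at least one *query* protein (the overlap sets,
not the full tissue sets), weighted by the shared count. Adjusted p was
chosen for node size over raw p so node size and the reported ranking
agree; both values are carried as attributes. GraphML export writes
nodes and edges in sorted order, so identical networks serialize to
identical bytes.

## Marker fold-change calls

Fold change is late/early intensity (week 7 over week 4; the day-based
labels D45/D28 alias the same collections). Calls are upregulated at
FC ≥ 2.0 and downregulated at FC ≤ 0.5, both boundaries inclusive;
zero intensities produce gained/lost/absent instead of a fold change,
and a missing cell is treated as not-detected for calling. In the
heatmap matrix, log10 of a zero intensity is floored one decade below
the smallest positive intensity among the calls and flagged in a mask
column — the floor keeps the matrix renderable without inventing a
detection value. Calls are scale-invariant by construction.

## Stability metric

"The qualitative result is stable across cutoffs" is operationalized as:
sweep the query percentile over {95, 97, 98, 99}, rank tissues by
adjusted p at each cutoff, and score each pair of cutoffs by
|top-k ∩ top-k| / k with k = 3. Top-k overlap was preferred to rank
correlation because the claim concerns which tissues *lead* the ranking,
not the ordering of the insignificant tail; Spearman over the full
ranking is available as an alternative. Note that rankings at nearby
cutoffs are intrinsically correlated (a lower cutoff's query nests the
higher cutoff's), so even null data shows moderate stability; the
discriminating property is the conjunction "tracked tissue in every
top 3 *and* mean stability > 0.66".

## Timeline statistics

Pearson r with the two-sided p from t = r√(n−2)/√(1−r²) on n−2 degrees
of freedom; the trend is ordinary least squares with a pointwise t-based
confidence band for the mean at level 0.95 — a linear fit, consistent
with pairing the curve with a correlation test, rather than a local
smoother. Composition summaries compute per-differentiation category
percentages (always summing to 100) and report the across-unit mean with
SEM = s/√U using the n−1 sample standard deviation; a single unit yields
a missing SEM rather than 0.

## Synthetic data: what it emulates, and what it does not

Background intensities are log-normal with location 20 and scale 1.5 on
the natural-log scale of arbitrary units, mimicking the ~5-decade
dynamic range of label-free MS. The reference generator plants exact
tissue sets (default 20 tissues × 100 proteins over 2000) with a
controlled fraction of proteins shared across 2–3 tissues
(`overlap_rate`, default 0.2) so the promiscuity filter has work to do;
the emitted annotation rows reconstruct the planted library exactly
under the default filters, with decoy rows at other levels/fractions.

Signal is planted by rank surgery: the query sample's top band is
assembled so that a fraction `effect_fraction` (default 0.5) of it comes
from the planted tissue's set, making the realized overlap k* exact and
recovery tests sharp; the planted/tracked tissue is drawn uniformly per
seed, since a fixed label would interact with the alphabetical tie-break
of the result ordering and bias null studies. With no effect the top
band is a uniform random subset, so the tracked-tissue overlap is
exactly hypergeometric — the property the calibration study checks.

Study sizes — 2000 proteins, 20 tissues, query ≈ 41, 100 recovery
seeds, 200 null seeds, 20 sweep seeds per condition — are scaled-down
but structurally faithful stand-ins for a ~40-tissue resource over a
several-thousand-protein proteome, chosen so a full validation sweep
completes in well under a minute per study.

What the generator does *not* emulate: peptide-level quantification and
razor-protein assembly, intensity-dependent (non-random) missingness
(only optional uniform dropout is offered), correlated expression between
biologically related tissues beyond literal set overlap, and batch
effects. Passing tests therefore demonstrate the pipeline's statistical
correctness under its own model, not robustness to every artifact of
real label-free data.

The timeline generator places ages on a half-week grid over weeks 3–9
and draws counts as intercept + slope·x + Gaussian noise truncated at 0,
with defaults (n = 14, slope 3 counts/week, noise sd 5) that produce
correlations around 0.6–0.8, the regime of the motivating organoid
counts; the recorded generating correlation is exact only when
truncation does not bite.

## Known limitations

* The hypergeometric test assumes exchangeable draws; co-regulated
  protein families violate this, as they do in any over-representation
  analysis.
* Identifier mapping is a flat table lookup — no isoform resolution or
  history-aware accession mapping.
* The Bonferroni default is deliberately conservative; the
  `statsmodels`-backed adjustment could expose FDR control, but that is
  intentionally not the default since family-wise control is the
  documented procedure.
* The stability metric's 0.66 bar is a convention (two of the top three
  conserved on average); single seeds of genuinely planted data can dip
  below it when the chance-ranked tissues behind the leader churn.
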