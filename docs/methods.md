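# Methods

## Model and rationale

Amplicon genus tables are compositions: each sample's relative
abundances sum to 100%, so the observed value of genus *g* in sample
*s* is

    x(g, s) = 100 · A(g, s) / Σ_h A(h, s)

where *A* is the unobserved absolute abundance. Any between-group shift
in the denominator (total microbial load) moves every genus's *x*
without moving its *A*. The internal-reference idea removes the
denominator by dividing by a co-measured reference genus *r*:

    RCQ(g, s) = x(g, s) / x(r, s) = A(g, s) / A(r, s)

If the reference's absolute abundance is comparable across the groups
being contrasted, RCQ differences track absolute differences. The
reference is screened distributionally: present in the target host at
every site, absent from every companion plant (a co-located background
that shares soil, water and air but not roots), and with a group-mean
relative abundance at or above a floor in every host group so the
denominator is well away from the detection limit.

Assumptions worth keeping in mind: (i) the reference taxon's absolute
level is stable across the *host* groups being compared — the screen
checks host specificity and abundance, not stability, which is why all
passing candidates are reported and ranked rather than one being chosen
silently; (ii) presence/absence is taken at the detection level of the
dataset, so "absent in companions" means "never detected", not "truly
absent"; (iii) RCQ is semiquantitative — ratios to the reference, not
cell counts.

## Zero handling

The pseudo-count rule is asymmetric by design. A zero *denominator*
(reference undetected) is replaced by half the detection limit
(default limit 0.002% relative abundance ⇒ pseudo-count 0.001%),
because the reference was presumably present below detection and a zero
would make the ratio undefined. A zero *numerator* stays exactly zero:
an undetected genus is reported as absent, never inflated by the
pseudo-count. Every sample where the pseudo-count fired is flagged in
the RCQ table's audit trail and in the pipeline manifest. A warning is
logged whenever a denominator sits within 2× the detection limit, where
the ratio is numerically legitimate but biologically noisy.

Two normalization modes are exposed and recorded in every output.
`per_sample` (default) divides by the sample's own reference abundance;
the rank tests downstream need per-sample values, so this is the mode
the screens use. `group_mean` divides all samples of a group by the
group-mean reference abundance; in that mode, each sample's RCQ column
sums to exactly 100 / (group-mean reference %), an identity the test
suite asserts. The per-group mean RCQ column sums are reported as a
diagnostic of how far the data moved from closure; they are a
descriptive readout, not a validated quantity.

## Statistical screens

Two-group contrasts use the two-sided Wilcoxon rank-sum test: the exact
null distribution when both groups have ≤ 8 observations and the pooled
data are tie-free, otherwise the normal approximation with tie and
continuity corrections. k-group contrasts use tie-corrected
Kruskal-Wallis with a χ²(k−1) p-value; all observations identical is
defined as H = 0, p = 1. For two tie-free groups the χ²(1)
Kruskal-Wallis p equals the square of the no-continuity normal Wilcoxon
z — an identity used as a cross-check in the tests, with the exact test
verified against exhaustive enumeration of all rank splits for group
sizes up to 6.

The low-abundance filter (group-mean relative abundance strictly above
0.005% in at least one group) is evaluated on the percent scale for
*both* screens, including the RCQ screen. This keeps the two methods'
genus universes identical so their result sets are comparable, at the
cost of letting the percent scale decide admissibility for a ratio
test; the choice is recorded in every output.

Significance defaults to raw p < 0.05 with no multiplicity adjustment,
matching common practice in this literature; Benjamini-Hochberg is
available by option and, when enabled, the significance flag uses the
adjusted p. Direction is called from per-group means (medians by
option): `up` when the reference group's center strictly exceeds every
comparator, `down` when strictly below all, `none` otherwise — never an
arbitrary sign on a tie. The "wild-enriched" set is the conjunction of
k-group significance, the abundance filter, and the target group's
center strictly exceeding every comparison group's center, on the same
scale the test ran on.

Spearman correlations (used to relate a focal genus to pathogen genera
on corrected abundances) report an exact permutation p for n ≤ 9 (all
n! pairings) and the t approximation above that.

## Synthetic communities

The generator works at the genus-table level. Per-taxon baseline
absolute abundances are log-normal (log-mean 0, log-sd 0.3 by default);
each sample multiplies its group's expected abundances by independent
log-normal noise (log-sd 0.3). Group effects are multiplicative folds
on the absolute scale: *differential* taxa carry planted signal,
*bloomer* taxa create total-load shifts. Samples are closed to
proportions and sequenced as one multinomial draw per sample at a fixed
depth (default 50,000), from which the percent table derives. The
designated reference taxon's absolute level is set directly per group —
constant across target groups, zero in companion groups — so the
host-specificity screen is exercised end to end. Truth flags are a pure
function of the configuration: a taxon is truly differential between
two groups iff its net absolute-scale fold (or reference level)
differs. All randomness flows through one `numpy.random.default_rng`
stream per draw; benchmark replicate *i* uses seed `master_seed + i`.

What the generator does **not** emulate: taxon-taxon correlations,
overdispersion beyond the log-normal/multinomial hierarchy, sequencing
error or chimeras, taxonomy misassignment, and rank-abundance tails
wider than the configured log-sd. Passing benchmarks therefore show
that the ratio screen removes *closure-induced* false positives under a
clean load-shift mechanism, not that it is robust to every artifact of
real amplicon data.

Two built-in scenarios fix the study conditions:

* `null_load_shift` — 200 taxa, three target groups × 6 samples (plus a
  companion group per site), no planted signal; one bloomer taxon
  surges 20-fold in the two cultivated-analog groups. The bloomer's
  baseline is pinned at half the summed baseline of the other taxa
  (~1/3 of pre-bloom load), so the bloom shifts total load by roughly
  an order of magnitude — the regime the closure argument describes,
  where relative abundances of unchanged taxa are visibly compressed.
  The reference taxon holds absolute level 1 in all target groups.
* `planted_signal` — 50 taxa, same group layout, no bloomer; taxa
  g001–g010 enriched 4-fold (absolute) in the wild-analog group. Fifty
  taxa is a realistic size for a post-filter genus panel and keeps the
  expected number of chance wild-enriched calls (k-group α = 0.05,
  top-rank requirement) well below the planted ten, so the
  false-discovery fraction of the recovered set is interpretable.

The benchmark scores, per method and replicate, the per-taxon
false-positive rate (truly-null taxa called significant) and
true-positive rate (planted taxa recovered) for a two-group Wilcoxon
screen at α = 0.05, 100 replicates by default.

## Numerical and design choices

* Internal canonical unit is percent; counts and fractions are
  total-sum scaled at the boundary. RCQ is computed after scaling, so
  counts and percent input give bit-identical ratios.
* The reference-eligibility floor is inclusive (mean ≥ 0.005% in every
  host group); the differential filter is exclusive (mean > 0.005% in
  ≥ 1 group). Candidates are ranked by their minimum across-group mean,
  descending, ties broken lexicographically.
* Presence defaults to any-sample detection (> 0); a
  `prevalence:<f>` rule is available since a single-read detection may
  be too permissive for noisier datasets. Companion absence is always
  "never detected in any sample of any companion group at the site",
  evaluated per companion group, not pooled.
* Duplicate taxa rows are an error, never merged; `unclassified_*`
  labels are ordinary taxa.
* Outputs are plain TSV/JSON with repr-faithful floats; reruns with the
  same inputs and configuration are byte-identical, and every output
  carries its provenance (method, mode, thresholds, reference genus).

## Limitations

* A single reference genus concentrates all denominator noise; samples
  where it is near or below detection produce unstable ratios (flagged,
  not fixed). No multi-reference or log-ratio (e.g. ALR/CLR ensemble)
  variant is implemented.
* The screen cannot verify absolute stability of the reference without
  external calibration (spike-ins, qPCR); it verifies host specificity
  and an abundance floor only.
* Exact Wilcoxon p-values are unavailable in the presence of ties;
  ties fall back to the corrected normal approximation regardless of
  group size.
* The benchmark's conclusions are conditional on the generator's
  mechanism (single-bloomer load shift, independent log-normal taxa);
  see the generator caveats above.
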