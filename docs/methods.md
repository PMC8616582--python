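# Methods

## Enrichment model

Spectral counts are treated as already-normalized, semi-quantitative
abundance measurements; no further normalization is applied by default
(an optional total-count scaling exists behind
`EnrichmentConfig(normalize_totals=True)` but is off, since inputs are
expected to be normalized upstream).  Proteins absent from a sample are
counts of zero, not missing values.

For each protein the caller compares the arithmetic mean over the bait
replicates to the mean over the control replicates.

* **Fold change** uses a pseudo-count `c = 0.01` on both means,
  `FC = (x̄_b + c)/(x̄_c + c)`, so the ratio is finite when the control
  mean is zero.  The enrichment thresholds are `log₂FC ≥ 3` (inclusive)
  and `p < 0.05` (strict); by monotonicity of log₂ the fold-change form of
  the threshold, `FC ≥ 8`, is exactly equivalent.  Note the pseudo-count
  makes a raw ratio of exactly 8 fall just below the threshold
  (8.01/1.01 < 8).
* **The t-test** is a one-tailed (bait > control) two-sample Student test
  with pooled variance and `df = n₁ + n₂ − 2`, computed from the closed
  form.  Welch's unequal-variance form is available via
  `variance_model="welch"`.  The pseudo-count enters only the fold change
  by default; `pseudo_count_scope="fold-change-and-test"` adds it to every
  count before testing (a shift, so for the pooled statistic it matters
  only through degenerate handling; the switch exists to probe
  reproduction variants).
* **Degenerate replicates.** Count data at n = 3 regularly produces zero
  pooled variance.  The limits of the t statistic are used: zero variance
  with zero mean difference gives p = 1; zero variance with a difference
  pointing into the tested tail gives a p reported as 1e−300 with a
  `degenerate` flag in the output table.
* **Multiple testing.** The enriched flag always uses raw p-values;
  Benjamini–Hochberg adjusted p-values can be emitted as an extra column
  (`p_adjust="benjamini-hochberg"`) and never change the flag, because the
  procedure being implemented filters on raw p < 0.05 combined with a
  strong fold-change cutoff.

Output tables are sorted by protein id; the module has no randomness, so
results are permutation-invariant in the sample order within groups.

## Reference-set recovery

Recovery of a curated granule list is plain set intersection after id
harmonization: aliases are resolved transitively (cycles and conflicting
alias rows are errors), then ids are case-folded to upper case, since
C. elegans gene and protein symbols differ only by case.  The default
candidate set for recovery is the union of both baits' enriched lists —
the labeling experiments jointly define the recovered neighborhood — with
per-bait recovery also reported.  An empty reference set yields fraction 0
with an explicit flag rather than an error.

## Disorder comparison

Per-residue disorder scores are consumed as input (any predictor emitting
[0, 1] per residue works; the reader records a `mode` label but does not
interpret it).  Scores are summarized per protein as length, total, and
mean = total/length, on the longest isoform per gene (ties broken by
lexicographically smallest isoform id).  Score files must cover positions
1..L without gaps; missing positions are rejected, not imputed.

The target-vs-control comparison draws `|target|` proteins uniformly
without replacement from the summarized proteome.  By default the target
proteins are excluded from the sampling pool — sampling targets into their
own control only dilutes the contrast — with `exclude_targets=False`
restoring naive whole-proteome sampling for comparison with single-draw
analyses.  The draw is seeded and mandatory-explicit; with `n_draws > 1`
the median p across draws is reported along with every per-draw result.
The test is two-sided by default (the direction of the disorder difference
is a finding, not an assumption); one-sided alternatives are available.

**Wilcoxon rank-sum.** The statistic is the rank sum W of the first sample
with midranks for ties.  When the smaller sample has ≤ 8 observations and
there are no ties, the p-value is exact: the null distribution of W is
enumerated by a subset-sum dynamic program over all C(N, n) rank
assignments (two-sided p = 2·min(P(W≤w), P(W≥w)), capped at 1).
Otherwise a normal approximation is used with the standard tie-corrected
variance and a 0.5 continuity correction.  Two identical samples return
p = 1 with a degenerate flag.  The exact path is verified in the test
suite against full brute-force enumeration and against an independent
library implementation.

## ROI ratio

The dispersal readout divides background-corrected rachis intensity by the
average background-corrected edge intensity,
`2·(rachis − b) / (edge1 + edge2 − 2·b)`.  A "literal" mode that subtracts
the background only once in the numerator, `(2·rachis − b)/(…)`, is kept
behind a flag: printed versions of this formula sometimes carry that form,
which we read as a typesetting artifact since it breaks invariance under a
detector offset while the symmetric form is invariant under any affine
intensity change `v → a·v + β`.  Averaging versus summing the two edge
ROIs cancels in either mode.  A non-positive corrected denominator makes
the ratio undefined; the record is flagged and excluded from group
aggregates.  Genotype groups are compared with a two-tailed pooled t-test;
identical constant groups give p = 1 under the same degenerate rule as the
enrichment test.

## Synthetic data

The generator exists so that every stage of the pipeline can be exercised
end-to-end with known ground truth.  All generators are pure functions of
a `SimulationSpec`; RNG sub-streams are derived from the master seed via
`SeedSequence` spawn keys, one fixed key per generator, so outputs are
bit-reproducible and adding a generator never perturbs another.

* **Counts** are zero-inflated negative binomial.  Defaults: 2,000
  proteins, 3 replicates per group, background mean 5 spectral counts
  (typical of contaminant background in streptavidin pull-downs),
  overdispersion 0.1 (variance = m + 0.1·m²), detection dropout 0.02 per
  observation.  Dropout applies to the background/null model and control
  samples only; the planted enriched proteins' bait counts are drawn at
  `effect_fold × background_mean` (default 16×) without dropout, since
  abundant bait-proximal proteins do not stochastically vanish from
  identification.  The count model is the package's own idealization — it
  is not fitted to any real data set, and it omits real-data features such
  as correlated replicates, abundance-dependent detection, shared-peptide
  ambiguity, and batch effects; passing tests show the procedure behaves
  correctly under the stated model, not that any particular real data set
  will reproduce.
* **Dual-bait design.** `simulate_bait_pair` plants two enriched sets with
  a configured overlap, default 155 and 127 proteins sharing 78, the
  headline structure of a dual-bait P-granule labeling design.
* **Disorder.** Protein lengths are log-normal (median 400 aa, log-sd
  0.4, floor 30).  Each protein has a latent mean disorder drawn from a
  Beta centered at 0.35 with concentration 6 (proteome-wide spread of mean
  disorder ≈ 0.18); target proteins' latent means are shifted by
  `disorder_shift` (default +0.2) and clipped into (0.01, 0.99) with a
  warning; residue scores are Beta draws around the latent mean with
  concentration 10.  Within-protein residue correlation of real disorder
  tracks is not modeled; it is irrelevant to the per-protein mean that the
  analysis consumes.
* **References.** Reference sets are drawn with configured overlap against
  the planted *union* truth (recovery is scored against the union
  candidate list), default 18/20, 2/2, 0/11 — so the structural recovery
  fractions 90%/100%/0% are reproduced by construction when the caller
  recovers the truth.
* **ROI.** Records are planted-signal-plus-background with additive
  Gaussian noise (sd 2 gray values by default); with zero noise the
  symmetric ratio returns the planted value exactly.  Default planted
  ratios (wild-type 0.30, single mutants 0.60/0.35, double mutant 0.90,
  n = 4 animals) emulate a perinuclear-to-dispersed phenotypic series.

## Numerical and testing choices

Simulation sizes in the test suite — 2,000 proteins × 200 seeds for null
calibration, 10 seeds for spike-ins, 400-protein proteomes × 200 seeds for
disorder power — were chosen as the smallest designs whose binomial
sampling error is well below the margins being asserted; the whole suite
runs in well under a minute.  Null calibration of the t-test on discrete
3v3 counts is asserted within the 3σ binomial band of a single
2,000-protein experiment: no t-test is exactly calibrated on skewed
discrete data at n = 3, and the observed false-positive rate (~4.9%)
sits comfortably inside that band.  Spike-in specificity is asserted as
the false-positive rate among true nulls (≤ 1%); the measured rate is
~0.03%.  Expressed instead as a false-discovery proportion over a
50-protein spike-in it averages about 1%, driven almost entirely by
detection dropout producing all-zero control triplets whose pseudo-counted
fold change explodes — the same behavior the pseudo-count produces on real
data, and worth remembering when reading candidate lists: an enriched call
with an all-zero control row rests on the pseudo-count, not on a measured
ratio.

## Limitations

* The enrichment procedure is the simple mean/pseudo-count/t-test scheme;
  it is not a probabilistic interaction scorer and inherits the
  pseudo-count's sensitivity to all-zero control rows described above.
* Disorder prediction itself is out of scope; results are conditional on
  whatever per-residue scores are supplied.
* GO enrichment and protein-interaction networks are deliberately not
  pipeline stages (their results depend on external database versions);
  the pipeline exports plain candidate lists for those tools.
* Image segmentation and ROI drawing are upstream of this package; only
  ROI mean intensities are consumed.
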