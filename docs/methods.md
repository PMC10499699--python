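# Methods

This note documents the statistical procedure the package implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## The index-construction procedure

The toolkit builds a diatom-based multimetric index for lakes (an
IBDL-style index) in three steps.

**1. Alert taxa per pressure gradient (TITAN).**
Index taxa are those occurring (count > 0) in at least `min_occurrence`
(default 3) calibration samples.  For each environmental variable, every
index taxon is scanned over all admissible binary partitions of the
samples along the gradient: a partition is a threshold between two
consecutive distinct gradient values with at least `minsplit` (default 5)
samples on each side.  At each partition the two-group indicator value
(IndVal) is computed per side:

    IndVal_g = 100 * A_g * B_g,
    A_g = mean abundance in g / (sum of both group mean abundances),
    B_g = occurrence frequency in g,

on relative abundances (counts / total count).  The taxon's change point
is the partition maximizing the larger side IndVal; the maximizing side
gives the response direction (increaser "plus" / decreaser "minus").  The
observed maximum IndVal is standardized into a z-score against `n_perm`
permutations of the gradient pairing, and `n_boot` bootstrap resamples
yield *purity* (fraction of replicates reproducing the observed
direction) and *reliability* (fraction of replicates whose own
permutation p-value is <= 0.05).  Taxa with purity and reliability both
>= 0.95 are classified Z+ or Z-; everything else is indifferent,
including taxa whose permutation sd is zero (z set to 0).

Community-level shift thresholds are located by summing, at every
candidate partition, the direction-specific z profiles of all Z+ (resp.
Z-) taxa and taking the argmax (ties toward the lower gradient value).
Each taxon's z profile is its side-specific IndVal profile normalized by
the scalar permutation mean/sd of its max-IndVal statistic.  This scalar
normalization (rather than per-partition permutation moments) follows the
"observed versus permuted maximum" convention and has a useful exactness
property: with a single classified taxon the community threshold
coincides with that taxon's change point.

**Alert rule.**  Alert taxa are classified taxa on one side of the
community threshold.  Which side is a genuinely open convention; the
default keeps taxa whose individual shift occurs at or before the
community shift (`change_point <= community threshold` for both Z+ and
Z-): tolerant taxa that arrive early and sensitive taxa that are lost
early are the most informative early warnings.  All four sign
conventions are selectable (`alert_rule` in {"le_le", "le_ge", "ge_le",
"ge_ge"}).

**2. Metrics and their transformation.**
For each variable with a non-empty alert set, the raw metric of a sample
is one minus the alert fraction of the present index taxa
(`Metric = 1 - Alert_taxa / Index_taxa`, both counted as presences).
Samples presenting no index taxon have an undefined metric and are
flagged.  Raw values are standardized per sample group — substrate type
x lake alkalinity metatype — `SES = (Metric - M_group) / sd_group`,
rescaled by the calibration extremes `SESnor = (SES - Min)/(Max - Min)`,
and expressed as an ecological quality ratio `EQR = SESnor / SESnor_ref`
capped at 1.  The reference expectation `SESnor_ref` is the mean (median
selectable) normalized value over all valid samples of reference lakes —
lakes with < 0.4 % artificial land use and < 20 % agriculture in the
catchment (strict inequalities; lakes with missing land use are excluded
from the pool).  Metrics are screened by the Pearson correlation between
the OU-scale raw metric and the variable's lake value; |r| > 0.6 keeps
the metric (the absolute value is used — informative metrics are
negatively correlated with pressure).  A paired Wilcoxon signed-rank
test per metric reports (without gating) whether substrate type shifts
OU-scale EQRs.

**3. Aggregation.**
The OU x substrate score is the mean of the selected metrics' EQRs; with
both substrates scored, the lower value is kept (worst-case rule).  OU
scores are averaged within each riparian-zone type and combined with the
perimeter fractions Pc_type: `IBDL = sum_type mean(Score_OU|type) *
Pc_type`.  Types carrying weight but no scored OU are dropped and the
remaining weights renormalized, keeping the index a convex combination
of OU scores (the dropped weight is reported); the alternative — counting
missing types as zero — would bias scores downward.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_occurrence` | 3 | samples a taxon must occur in to be an index taxon |
| `minsplit` | 5 | smallest group size a partition may create |
| `n_perm` | 250 | permutations for the z-score / p-value |
| `n_boot` | 500 | bootstrap replicates for purity/reliability |
| `purity_min`, `reliability_min` | 0.95 | classification screen (inclusive) |
| `r_threshold` | 0.6 | Pearson screen on candidate metrics |
| `alert_rule` | `le_le` | side convention of the alert extraction |
| `reference_stat` | mean | reference expectation over reference-lake samples |

`n_perm`/`n_boot` defaults follow common TITAN practice; the end-to-end
tests and the acceptance script run at 100/100, which keeps a full
11-variable calibration of a 30-lake survey within a few minutes on one
core while leaving the permutation and bootstrap screens meaningful.

## Randomness and determinism

One master seed drives everything.  Each (variable, taxon) analysis uses
an independent substream derived by stable (CRC-32) hashing of the
variable and taxon names, so results are invariant to taxon ordering and
to how work is scheduled.  Within a taxon the draw order never consults
the gradient values, which makes the analysis exactly symmetric under
gradient negation: directions flip, change points negate, z-scores are
bit-identical.  Lake aggregation sorts before averaging so scores are
bit-identical under any OU ordering.

## The synthetic-data generator

The generator emulates the structure of a national lakeshore-diatom
survey: `n_lakes` (default 30) lakes of three alkalinity metatypes
(LA/MA/HA in proportions 0.15/0.30/0.55), 3-6 observation units per lake
(national protocols scale OU number with lake perimeter; real surveys
average about seven per lake), one mineral and one macrophyte sample per
OU, 400-valve multinomial counts, and a lake-scale physico-chemical
table.  Each lake carries a latent eutrophication pressure p drawn
Beta(1.2, 1.8) — monitored lake populations over-represent
low-eutrophication sites, so the gradient is mildly skewed toward the
pristine end.  Reference lakes are the lowest quartile of p; their
land-use fields are drawn to satisfy the reference criteria.

Environmental variables are `(a + b p) * exp(N(0, sigma) - sigma^2/2)`:
a positive linear baseline with mean-preserving lognormal noise, giving
the right-skewed strictly positive values concentration data show.  The
Kjeldahl-nitrogen, BOD5, total-phosphorus and suspended-particle
analogues are strongly coupled (sigma 0.25-0.3, Pearson ~0.85 with p);
orthophosphate is intermediate (sigma 0.6, r ~ 0.5) and conductivity and
the remaining variables weak, so the |r| > 0.6 screen has realistic
negatives to reject.

Of the 60 taxa, 30 % are increasers, 10 % decreasers and 60 %
indifferent: eutrophication typically recruits many tolerant taxa while
a smaller sensitive pool declines, and this asymmetry is what lets a
presence-based alert-richness metric respond monotonically on
compositional data.  Responders follow a step (or logistic) response
with a 25-fold change across their change point.  Change points are
partially synchronized — truncated normal around a community threshold
(increasers N(0.5, 0.15), decreasers N(0.25, 0.10), i.e. sensitive taxa
are lost earlier than tolerant taxa arrive) — because the
threshold-indicator paradigm presumes taxon thresholds cluster around a
community-level shift; with fully diffuse thresholds the community
change point would be ill-defined.  Expected weights receive
multiplicative lognormal sample noise (log-sd 0.3) before renormalization
and multinomial draws.

**What the generator does not emulate.**  Abundances are compositional,
so indifferent taxa acquire mild compensatory trends; effect sizes are
chosen so planted responders dominate, but a synthetic "indifferent"
taxon is not a perfect null.  No taxonomic structure, no spatial or
temporal autocorrelation, no inter-annual variability, and by default no
substrate effect (a pressure offset for macrophyte samples is available
via `substrate_effect`).  Tests passing on this generator show the
machinery is correct and recovers planted structure; they do not certify
performance on real survey data, where gradients are shorter, noisier
and confounded.

## Numerical conventions and degenerate inputs

* Partitions never split tied gradient values; ties in the scan are
  broken toward the lower gradient value, and within a partition the
  "plus" side wins only on exact IndVal equality.
* Permutation p-values use the add-one convention
  `(1 + #{perm >= obs}) / (n_perm + 1)`; the comparison carries a 1e-12
  slack against floating-point jitter.  z uses the sample sd (ddof 1);
  sd = 0 yields z = 0 and an indifferent taxon.
* Bootstrap replicates without any admissible partition are redrawn up
  to 10 times, then skipped and counted.
* Samples with a missing gradient value are dropped from that variable's
  TITAN run only.  Environmental values match a sample's year, then the
  year before, then the year after; rows without a year act as wildcards.
* Variables whose TITAN run yields no alert taxa, or whose metric is
  degenerate (a group without spread, or Max = Min after SES), are
  excluded from metric building with a `no_signal`/`degenerate` status
  instead of aborting the calibration; calibration fails only when no
  variable survives or the reference pool is empty.
* At scoring time, unseen substrate x metatype groups fall back to
  substrate-pooled statistics (stored in the model as `"<substrate>|*"`),
  out-of-range SESnor values are clamped to [0, 1], and the EQR cap at 1
  keeps final scores in [0, 1]; the uncapped ratio is retained in the
  calibration diagnostics.
* The compiled scan kernel (numba, when available) and the numpy
  reference path implement the identical statistic; a test asserts their
  agreement.

## Known limitations

* The alert-rule convention is ambiguous in the field; results can
  depend on it.  The default is documented above and the alternatives
  are one setting away.
* The community threshold is the raw sum(z) argmax — no robust
  (filtered or bootstrapped) community threshold is used for alert
  extraction.
* Ecological status class boundaries (High/Good/...) are deliberately
  out of scope; the index is delivered as a continuous [0, 1] score.
* Pearson screening at OU scale inherits pseudo-replication (lake
  values broadcast to OUs); this mirrors the operational convention and
  is reported per variable with the pair count.
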