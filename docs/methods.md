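# Methods

This note documents the models, conventions and design choices behind
`cnvreclass`: what is computed, under which assumptions, and what the
packaged fixture and generator do and do not establish about real cohorts.

## Coordinates and domain model

All internal coordinates are 1-based inclusive (the ISCN convention in
which clinical array results are printed); `length = end − start + 1`.
BED export and chain-file parsing convert to/from 0-based half-open at the
I/O boundary only. Intervals carry their genome build (NCBI36/hg18,
GRCh37/hg19, or unspecified) and every cross-object operation checks build
compatibility — mismatches raise instead of silently converting.

Copy states are integer ranges `low..high` (`low == high` when non-mosaic;
`x2~3` models a duplication–triplication). CNV type (loss/gain) is derived
from the copy state against expected ploidy: 2 on autosomes; on chrX/chrY
ploidy depends on patient sex (X: 2/1 for F/M; Y: 0/1). A state is a loss
iff `high < expected` and a gain iff `low > expected`. States the
arithmetic cannot resolve — `x2` on a female X (where the array ratio
depends on the comparator), or mosaic ranges straddling ploidy — are
accepted only with an explicit loss/gain label; a non-mosaic autosomal
`x2` is never a CNV, label or not, because there the arithmetic is
unambiguous. Classifications form the total order
B < LB < VUS < LP < P, which defines up/downgrade direction (LB→B counts
as a downgrade).

Reciprocal overlap — `min(overlap/len(a), overlap/len(b))` — is the
"same CNV" criterion used for matching calls against population and
literature records, with the community-conventional default threshold 0.7.

## ISCN notation

The parser accepts the array-CNV subset of ISCN: optional `arr` prefix,
optional `[hgNN]` build tag, loci of the form
`<chrom><band>(<start>-<end>)x<n>[~<m>]` or `chr<chrom>:(<start>-<end>)x<n>`,
both `-` and `_` as coordinate separators, multiple comma/whitespace-
separated loci, and trailing `dn`/`mat`/`pat`/`inh` inheritance tokens.
Full karyotype grammar (translocations, complex rearrangements) is out of
scope. Formatting emits a single canonical form (band style, hyphen
separator), so parse→format→parse is a fixed point.

## Liftover

Chain files are parsed per the UCSC chain format (header + ungapped block
triplets; source strand always `+`; negative-strand target coordinates are
converted to the forward strand). CNV intervals are lifted with **span
semantics**: within the best-covering chain, the image is the min..max of
the images of the interval's aligned bases. Rationale: aCGH boundaries
are breakpoint estimates bounded by probe spacing, not base-level
alignments, so per-base splitting would manufacture precision. A result
is `mapped` when a single chain covers at least `min_match` of the source
bases (default 0.95, the liftOver convention), `partial` below that,
`split` when several chains each cover part (conservative: such calls go
to an exception report for manual review rather than being auto-resolved),
and `unmapped` with no aligned base. Batch lifting never drops a call
silently. Multi-hop conversion (hg18→hg38) is out of scope.

## Knowledge snapshots

A snapshot is a dated, assembly-locked bundle of five record tables (gene
models; dosage-sensitivity records with HI/TS levels; recurrent-CNV regions
with established class and penetrance; population-CNV frequency entries;
aggregated literature case counts), stored as TSVs with a YAML manifest
and indexed by interval tree. Records post-dating the snapshot are
rejected — the snapshot date is what makes "initial-era" versus
"current-era" reanalysis a well-defined comparison. ClinVar/DECIPHER-style
case assertions are entered as literature rows (with the one-star-style
minimum review level applied at ingest) rather than modeled as a separate
table; live database queries and dump-format adapters are out of scope.

## Evidence mapping (automatic mode)

`build_evidence` derives the machine-derivable subset of the 2020
ACMG/ClinGen CNV rubric from snapshot queries, one bundle per CNV:

* **Section 1** — protein-coding content present (1A, 0 points) or absent
  (1B, −0.60).
* **Section 2** — established dosage-sensitive genes and recurrent
  regions. Complete overlap of a sufficient-evidence HI gene (losses) or
  TS gene (gains), or of an established pathogenic recurrent region
  (region contained in the call, or reciprocal overlap ≥ 0.8), scores 2A
  (+1.0). Partial overlap of an HI gene involving coding sequence scores
  2C at the suggested +0.90 pending breakpoint review. A call contained
  in an established benign region scores −1.0.
* **Section 3** — protein-coding gene-count bins (losses: 0–24 / 25–34 /
  ≥35 → 0 / +0.45 / +0.90; gains: 0–34 / 35–49 / ≥50).
* **Section 4** — benign direction: the best common population match
  scores −1.0 when a cohort frequency reaches 1 %, −0.90 when at least 5
  carriers are seen in one cohort below that frequency (the two arms of
  "seen in the general population", both configurable). Pathogenic
  direction: phenotype-consistent published de novo case counts map to
  +0.45 / +0.60 / +0.90 for 1 / 2 / ≥3 cases, capped at the section
  range.
* **Section 5** — proband inheritance. De novo occurrence is recorded as
  a 5A item with 0 automatic points: the rubric conditions those points on
  phenotype consistency, which is curator judgement, so the value is
  assigned via manual items (range 0–0.45). Inheritance from a documented
  unaffected parent scores −0.30; maternal/paternal transmission with
  unassessed parental phenotype, non-maternal, and unknown contribute 0.

Curator items (`merge_manual`) replace automatic items of the same section
code and are range-checked against the rubric; the result is flagged
`curated`. Sections requiring segregation counts, case-control data or
phenotype-similarity scoring are reachable only through manual items —
mirroring the automatic-screen-then-expert-curation workflow the package
models. Automatic HPO-based phenotype matching is a non-goal.

## Scoring and classification

Point ranges, defaults and thresholds live in a versioned config
(`rubric_v2020.yaml`) shipped as package data, so the transcription is
auditable and swappable. Each item is clamped to its section's range
*before* summation (per-category maxima, not a global clamp), and the sum
is accumulated in integer hundredths so that the category boundaries
(0.99 / 0.90 / −0.90 / −0.99) are decided exactly, never by float
rounding: +0.90 is likely pathogenic and +0.89 uncertain, always. The
five category ranges partition the reals, so every finite score has
exactly one class. SNV/indel criteria and Bayesian re-formulations of
the rubric are out of scope.

## Reanalysis, triage, statistics

`reanalyze` rescoring = automatic evidence → optional manual merge →
score, per call, against one snapshot; calls whose initial class is not
VUS are excluded at load (the study population is VUS-only). `triage`
runs the same scorer in automatic-only mode and flags calls classified
LP/P — the screen that decides which CNVs deserve curation time. Because
curation can only refute or confirm flagged evidence in this design, the
flag set is a superset of the final LP/P calls (sensitivity 100 % by
construction when curators add no new pathogenic evidence of their own).

Statistics are computed from integer counts with exact rational
arithmetic, rounded to one decimal only for reporting. A patient counts
as reclassified when ≥ 1 of their calls changed class. The cumulative
trend is an ordinary least-squares fit of the cumulative reclassified
fraction (denominator: all calls) against test year, slope in % per year;
two fits are compared by a t-test on the slope difference
(`SE = sqrt(se₁² + se₂²)`, df = n₁ + n₂ − 4). Size breakdowns use bins
<100 kb / 100–500 kb / 500 kb–1 Mb / ≥1 Mb, and the under-500 kb share is
reported for three subsets (all VUS, downgraded, benign-only) because
published summaries quote it under slightly different subset definitions.
The recommended reanalysis cadence (≤ 24 months) is documentation plus a
CLI warning, not an enforced scheduler.

## Synthetic cohorts

**Fixture** (`build_fixture`): fully deterministic, no sampling. Twelve
anchor CNVs carry published coordinates, transmission, copy states and
target scores; 360 synthetic CNVs are laid out non-overlapping on
chromosomes unused by the anchors, with lengths cycling fixed menus and
every construction freedom (year ladder, patient multiplicity, triage
false-positive mechanisms, schematic gene extents) documented in the
fixture's own README, including the source material's internal
discrepancies it preserves or resolves. Snapshot deltas (population
records for downgrades, dosage/recurrent/literature records for upgrades
and triage false positives) are exactly the records that produce the
configured outcome of every call, so the initial-era snapshot yields no
changes and the current-era snapshot reproduces all headline marginals
simultaneously.

**Generator** (`generate`): seeded sampling with the same mechanisms.
Defaults are the study conditions: 372 CNVs / 259-patient scale from 1641
tests, years 2010–2017 with uniform volume, loss fraction 0.54, 86.5 %
inherited among known inheritance, P(length < 500 kb) = 0.76 realized as
a two-bin log-uniform mixture over [25 kb, 500 kb) and [500 kb, 3 Mb)
(25 kb = platform resolution; a bin fraction is the published summary
statistic, so no density beyond it is assumed), outcome probabilities proportional to 52/60/248/5/7, and 1–4
CNVs per patient. From 2016 the reporting thresholds (500 kb prenatal /
200 kb postnatal) censor the length draw within its bin; for prenatal
tests from 2016 the small bin is unavailable, so the realized under-500 kb
fraction is `0.76 × (1 − prenatal_fraction × censored_years/years)`,
exposed as `CohortConfig.expected_under_500kb()` and used as the
calibration target. The seed is mandatory — no wall-clock default — and
equal seeds give byte-identical cohorts. Interval placement is
non-overlapping up to the synthetic genome's capacity (ample for
study-scale cohorts); far larger cohorts wrap with a phase offset and are
intended for marginal statistics only, since overlapping placements could
in principle let one call match another call's evidence records.

What passing on synthetic data does **not** show: the generator emulates
marginal distributions and knowledge-delta mechanisms, not real CNV
landscapes — no segmental-duplication hotspots, no correlated gene
density, no probe-level noise or segmentation artifacts, and phenotype
terms are carried as opaque strings. Results on it validate the
pipeline's arithmetic and bookkeeping, not clinical performance on any
real population.

## Numerical and degenerate-input choices

Scores: integer hundredths; round-half-away-from-zero when converting
curator-supplied floats. Empty evidence bundles score 0 → uncertain.
Query results are sorted (overlap descending, then coordinates) so reports
and result files are byte-stable; regenerated audit reports are identical.
Degenerate confusion tables (no positives / no negatives) are returned
with exact `Fraction` metrics rather than NaN-laden floats; the trend fit
requires ≥ 3 distinct test years and errors otherwise; empty cohorts are
rejected where a rate would divide by zero.

## Known limitations

* The evidence mapping implements the machine-derivable rubric subset;
  curator-only sections are expressible but nothing in the package
  proposes their values.
* Liftover is single-hop and span-based by design; calls needing per-base
  resolution should be re-segmented, not lifted.
* Snapshot tables are a normalized local schema; importing real DGV /
  ClinVar / DECIPHER dumps requires external format adapters.
* The triage model assumes curation refutes or confirms automatic
  evidence; a curator introducing novel pathogenic evidence for an
  unflagged call would break the sensitivity-by-construction property.
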