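# Methods

## The adjudication model

A database search for a barcode query returns a ranked hit table. The
package treats identification as a decision over the *top-match set*: the
records whose match statistics tie the best record.

**Ordering and ties.** GenBank-style records are ordered lexicographically
by (e-value ascending, bit score descending, percent identity descending);
BOLD-style records by similarity descending. Because search engines print
statistics at fixed precision, equality is judged at printed precision:
bit score, percent identity and similarity tie within an absolute tolerance
of 0.005 (values printed to two decimals), e-values within a relative
tolerance of 1e-9, with 0 == 0 exact. For GenBank records all three
statistics must tie for top-set membership. Tolerance-based equality is not
transitive, so membership is defined relative to the strict-order best
record: the best is located with exact comparisons (input-order
independent), then every record tying it joins the set. Enlarging
tolerances can only grow the set.

**Classification.** With the vouchered specimen's lineage as truth:

- *reliable_correct*: every top-set record's parsed species equals the
  truth species (after synonym resolution);
- *ambiguous_correct*: the truth species is in the top set together with at
  least one other identity; each co-hit is categorized as congeneric
  (correct genus, wrong species), heterogeneric, undetermined species
  ("Genus sp." and code-like labels), or uncultured (environmental
  records);
- *misidentified*: no top record names the truth species. The deepest rank
  at which any top-set member still agrees with the truth is reported
  (a top set of only "Amanita sp." records against an *Amanita* truth is
  misidentified at species but correct at genus). All members of a top set
  are equally best-ranked, so the roll-up takes the deepest rank achieved
  by any member — the most favourable reading of a tied output.
- *no_match*: the search returned nothing (including explicit no-match rows
  mapped to empty tables by the readers).

Ambiguity categories are recorded only for ambiguous_correct queries; a
misidentification's congeneric context is conveyed by its genus-level
roll-up instead, keeping the category set a property of ambiguity alone.

**Label parsing.** Database labels are normalized case- and
whitespace-insensitively; subspecific epithets are truncated to the
binomial. Epithets in {sp., spp., ssp., indet.} or containing digits mark a
record undetermined; leading "uncultured"/"environmental"/"unidentified"
tokens mark it uncultured (and undetermined); cf./aff./nr. set a qualifier
flag without blocking the binomial. Synonymy is resolved at species rank
only, through a user-supplied alias → canonical CSV that must be idempotent
and cycle-free; no live taxonomy service is consulted. The truth table's
genera provide a genus → family/order/class backbone so that label-only
(BLAST) records can still be rolled up above genus.

**Confidence.** The top similarity statistic (BOLD similarity, or GenBank
percent identity) below a threshold flags a low-confidence match. Default
96%, the regime in which restricted reference subsets tend to return no
match at all; boundary inclusive-high (96.0 is not low).

**Multi-locus combination.** Per-specimen, loci are combined within one
database and parameter set. The default *intersection* strategy intersects
top-set identity keys across informative loci (no_match loci are dropped;
a specimen with only no_match loci is itself no_match): the combined
candidate set can never exceed any single locus's, so adding a locus never
manufactures ambiguity, and a locus whose top set contains the truth can
never turn a correct call into a misidentification. *union* and
*best_locus* (fewest tied identities; ties broken by the configurable
priority rbcL > matK > trnH-psbA > ITS2) are provided because the
appropriate operator is a study-design choice; intersection is the default
as the only strategy that is monotone in loci. Identity keys are casefolded
binomials, "genus sp." for undetermined records, and "uncultured [genus]"
for environmental ones, so like co-hits intersect across loci. ITS subunit
searches (ITS1, ITS2) are compared side-by-side with the combined spacer,
which is its own locus read from its own hit tables, never synthesized from
the subunits.

## Summaries and statistics

Species-level accuracy counts reliable_correct and ambiguous_correct;
accuracy at a shallower rank additionally counts misidentified queries
whose roll-up reaches that rank. No-match queries stay in the denominator,
making rank-wise accuracy monotone within any group. Ambiguity is
summarized among correct matches only — 100·|ambiguous| / (|ambiguous| +
|reliable|) per (taxon group × database × locus) cell, pooled as the
cross-cell mean ± sample sd (n−1); cells without correct matches contribute
no term and are logged. Which cells enter the pooled figure is a reporting
choice, so the per-cell table is always emitted alongside the mean.

Between-database and between-run differences are tested with two-sample
t-tests (Welch by default — the pooled variant is available but the equal
variance assumption is rarely defensible here) and one-way ANOVA, operating
on per-query binary correctness indicators at the stated rank. Degenerate
inputs are defined, not errors: identical constant samples give t = 0,
p = 1, and an all-constant ANOVA gives F = 0, p = 1. Run comparisons align
runs on their shared queries, report per-run accuracy, pairwise
status-agreement percentages, and the set of queries whose status changes
across runs. No multiple-testing correction is applied; p-values are
reported raw.

## The synthetic-data generator

The generator emulates the error structure of public barcode repositories,
not their sequences — the pipeline never aligns, so fixture FASTA content
is random and only lengths matter.

**Taxonomy and database.** A regular taxonomy (classes × orders × families
× genera × species; default 2 × 3 × 3 × 4 × 4 = 288 species) with
alphabetic synthetic names. Each species present in the database receives
`records_per_species` records (default 5); each record is independently
mislabeled as a uniformly chosen congener (`mislabel_rate`, default 0.05;
single-species genera fall back to a confamilial swap), left undetermined
as "Genus sp." (`undetermined_rate`, default 0.10), or written as an
uncultured clone (`uncultured_rate`, default 0.05). A species is dropped
from the database entirely with `missing_species_rate` (default 0 —
study taxa are chosen for having reference records). An optional
`synonym_rate` aliases species and lets correct records carry the alias,
exercising synonym resolution.

**Match statistics.** A query's percent identity against a record is drawn
from a normal distribution by taxonomic distance between query and the
record's *true* source — conspecific 99.6 ± 0.3, congeneric 96.5 ± 1.2,
confamilial 92 ± 2, ordinal 88 ± 2.5, background 82 ± 3 — truncated to
[50, 100] and rounded to two decimals as printed. These defaults place
correct matches near 99–100%, congeneric competitors around the 96%
confidence boundary, and require strictly decreasing means. GenBank-dialect
scores follow a Karlin–Altschul-shaped convention: raw score from
match/mismatch reward/penalty +1/−2, bit score (λ·s − ln K)/ln 2 with
generator constants λ = 1.28, K = 0.46, e-value N·L·2^(−bit) with
N = 10⁷. The e-value is derived from the *rounded* bit score so that
printed-equal bit scores carry exactly equal e-values, keeping tie
structure identical in memory and on disk. The formulas are a generator
convention for realistic-looking numbers, not a claim about search-engine
internals. With probability `tie_rate` (default 0.3) the runner-up's
statistics are copied from the best hit, manufacturing the printed ties
that drive ambiguous matches; under the defaults roughly a fifth of correct
matches come out ambiguous.

**Queries.** Default 94 specimens, drawn from database-covered species
(optionally from all species, to probe missing-reference behaviour).
Amplicon lengths mix a full-length class (614 ± 34 bp) with a 30%
mid-length class (340 ± 65 bp), reflecting degraded-material studies.
Everything derives from the config seed through fixed substreams; the same
config writes a byte-identical fixture bundle.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence evolution (no chimeras, pseudogenes or
alignment artefacts; only their label-level consequences), any dependence
of discrimination power on query length, non-uniform taxon coverage, and
correlated errors between databases (each locus's database is generated
independently). Results on fixtures validate the adjudication logic, not
the field performance of any real reference database.

## Verification design

The tie machinery is checked against an exhaustive pairwise oracle on
random tables whose statistics are drawn from small discrete pools (so
printed ties are frequent). Misidentification calibration is checked
against an independent Monte-Carlo oracle that redraws record error types
and scores with plain array arithmetic and declares a misidentification
when no correctly labelled record comes within printed-tie distance of the
best hit — sharing the generative equations but none of the hit-table,
tie-policy or classification code; the pipeline side uses one query per
species across several independently seeded fixtures so outcomes are
independent and a 99% binomial interval applies. Recovery scenarios
(all-clean → 100% species accuracy; undetermined-only → 0% species, 100%
genus) use a near-noiseless similarity model (sd 0.01) so the expected
outcome is deterministic. The archived-workbook dialect adapter is tested
against a synthetic stand-in workbook with hand-counted expected summaries.

## Numerical and interface choices

- `max_hits` defaults to 10 (the common search-engine default for retained
  alignments); configurable since BOLD pages differ.
- Alignment coordinates from BLAST tabular input are passed through
  (1-based, inclusive) and never interpreted.
- e-value "0.0" parses to exact zero and compares equal to zero; decimal
  points are locale-independent.
- Percentages are kept unrounded internally and rounded only at
  presentation.
- Query-coverage is deliberately ignored throughout: it exists in only one
  of the two dialects, so no comparison could use it symmetrically.
- Exit codes: 0 success, 2 usage/config error, 1 runtime data error.

## Problem sizes

The test suite and `scripts/acceptance.py` run entirely on generated data:
1,000 random tables for the tie oracle, 10⁴ Monte-Carlo replicates and
~480 pipeline queries for the misidentification calibration, and studies of
17–94 queries for the summary-stage checks — sizes at which the stochastic
checks are well inside their binomial intervals while the whole suite runs
in seconds.
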