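# Methods

## Model and procedure

`isoora` takes four inputs: a Gene Ontology release (OBO or obographs
JSON), gene-level GO annotations (two-column TSV or GAF 2.x), isoform-level
predicted GO annotations (two-column TSV, accession → semicolon-separated
term list), and a differential-result table in the four-column HBA-DEALS
dialect (`Gene`, `Isoform`, fold change, PEP, with gene-expression rows
marked by the literal `Expression`).  An optional isoform → InterPro/ProSite
table enables domain-level ORA and an optional two-column interaction list
enables the PPI statistics.

The pipeline is: (1) parse the ontology into a validated DAG; (2)
ancestor-close all GO annotations; (3) call differential genes and isoforms
with the mean-PEP rule; (4) run overrepresentation tests; (5) correct for
multiple testing and write ranked tables.

## Ontology handling

Closure walks `is_a` and `part_of` edges, the standard relation set for GO
annotation propagation; `regulates`-family edges are excluded by default
because their semantics do not support the true-path rule cleanly
(configurable via `relations=`).  Alternate ids resolve silently to primary
ids.  Obsolete terms are retained in the graph but carry no parents, are
excluded from closure queries, and annotations referring to them are
dropped with a logged count.  Construction validates acyclicity, one root
per namespace, and that every term reaches exactly one namespace root.
Namespaces are analysed jointly (published enrichment tables mix
biological-process and molecular-function terms in one ranking); a caller
can pre-filter annotations per namespace if desired.

## Differential calling

The PEP of an item is the posterior probability that it is *not*
differential, so the expected number of false discoveries in any called set
is the sum of its PEPs and the expected false discovery proportion is their
mean.  Items are sorted ascending by (PEP, id) — the id breaks ties
deterministically — and the called set is the **maximal** prefix whose mean
PEP does not exceed the target α (default 0.05).  Because prefix means of a
sorted sequence are non-decreasing, that boundary prefix is unique; a
"smallest qualifying set" reading would always return a single item, so the
maximal-prefix interpretation is used.  The achieved FDR reported is the
mean PEP of the called set (NaN when empty).

DGE is called over all genes in the table from the expression rows.  The
DAS population is restricted to isoforms of genes with at least two
expressed isoforms — a single-isoform gene cannot shift isoform
proportions.  A gene is differentially spliced if it owns at least one
called isoform.  Expression and splicing are thresholded separately, each
with its own achieved FDR.  Fold changes are stored in log2; `ln` and raw
ratio inputs are converted at parse time via a flag.

## Enrichment statistics

All tests are one-sided (overrepresentation only).  The population includes
the study set, giving the 2×2 table (k, n−k, K−k, N−n−K+k).  The tail
P(X ≥ k) is summed in log space from gammaln-based log-pmf terms
(`logsumexp`), so p-values below the smallest positive double stay exact as
log-probabilities; the linear value is also reported and may underflow to 0.
Tests against exact rational combinatorial sums over every valid table with
N ≤ 60 bound the relative error below 1e-12.

Parent–child variants condition term t's test on the items annotated to its
direct parents: the conditioning population is the union (any parent) or
intersection (all parents) of the parents' annotated items, intersected
with the population; the study-side conditioning set is defined analogously;
K is the number of conditioning-population items annotated to t (a subset,
by the true-path rule).  Roots have no parents and receive p = 1, as do
terms whose conditioning population is empty (both flagged).

Multiple-testing corrections (Bonferroni, Holm, Benjamini–Hochberg step-up
with monotonicity enforcement) run through `statsmodels.multipletests`.
The default correction family is every term attached to the population
(K ≥ 1), the Ontologizer convention; `family="study"` restricts to terms
with study hits.  Domain ORA is identical but over flat domain entries (an
isoform with one or more annotations of an entry is annotated to it), with
Bonferroni as the default correction, and no closure.

Ranked outputs break p-value ties by accession so reports are reproducible
byte for byte.  Study/population proportions are printed as percentages at
one decimal.

## Profile comparison

"Enriched" for profile construction means adjusted p < 0.05 under the
configured correction (threshold configurable).  The Jaccard index of two
term sets is |A∩B|/|A∪B|, defined as 0 for two empty sets.  Called-set
overlap significance is the hypergeometric tail P(X ≥ k) in log10 space;
the universe N must be supplied by the caller because it is not derivable
from the two sets — the CLI defaults to the smaller run's observed-gene
count and records the choice.  PPI proportions divide the number of
interacting unordered pairs within a called set by C(m, 2); cohorts are
compared with a two-sided Mann–Whitney U test whose sampling unit is the
dataset (per-dataset proportions; per-pair indicators would be the
alternative but are strongly dependent within a dataset).  Domain-pair
co-enrichment frequency (fraction of datasets where both entries are
enriched) is correlated with co-occurrence (Jaccard of the entries' isoform
sets) by Spearman rank correlation — frequencies are bounded and heavily
tied, so Pearson would be inappropriate.  The correlation is undefined
(NaN, with the pair count reported) below two co-observed pairs.

## Synthetic cohorts

The simulation module emulates the *products* of an RNA-seq differential
pipeline, not the pipeline itself: no read counts, alignment or
quantification are modelled — generation starts at the differential-result
level the tool consumes.

* **Ontology**: a single-rooted random DAG; each term receives a level
  1..`dag_depth` and 1–2 parents from the level above (80% `is_a`, 20%
  `part_of`).  `dag_depth=1` gives a flat "star" ontology useful as a
  control in which a term's only ancestor is the root.
* **Annotations**: each isoform draws each non-root term independently at
  `base_annotation_rate` (default 0.08); a gene's annotation is the union
  of its isoforms' — consistent with isoform functions aggregating to gene
  level.  Genes get 1 + Poisson(0.8) isoforms, so single-isoform genes occur
  and exercise the DAS-population exclusion.
* **Differential table**: a fraction (default 0.1) of genes and isoforms is
  truly differential.  True items draw PEPs from Beta(0.5, 9) (mass near
  0); null items draw from Uniform(0, 1).  Planted enrichment draws the
  true isoforms without replacement with weight = fold for isoforms
  annotated to the planted term.
* **Calibrated PEPs** (`simulate_calibrated_peps`): for auditing the
  mean-PEP rule, PEPs are drawn from the mixture marginal and each item is
  then null with probability equal to its own PEP, making the PEP exactly
  the per-item error probability, so E[false-discovery proportion] of any
  selection equals its mean PEP by construction.  Note the distinction: in
  the planted-signal generator truth is assigned first and PEPs second,
  which is deliberately *not* self-calibrated (true items keep their Beta
  PEPs even when large); realized false-discovery proportions there exceed
  the nominal mean-PEP level, which is why the calibration property is
  tested with the calibrated generator.

All generators are bit-reproducible under `SimulationConfig.seed`, and all
writers emit exactly the dialects the parsers read (floats at full `repr`
precision so round-trips are identity).

## Test problem sizes and thresholds

Chosen once as study conditions:

* Type-I control: 40-term ontology, 150 genes, 1000 uniform-null study
  draws of 30 isoforms; average fraction of terms with p < 0.05 must not
  exceed 0.05 + 3 SE (the hypergeometric's discreteness keeps it below
  0.05 on average).
* Planted recovery: 800 genes (~1500 isoforms), 15% differential, flat
  ontology, planted term directly under the root at fold 5; the planted
  term must rank first in ≥95% of 200 replicates.  The flat ontology is
  used because in a deep DAG a planted internal term's closed annotation
  set is inflated by its descendants, which probes DAG position rather than
  the statistic.
* FDR calibration: 1000 replicates of 400 calibrated items at α = 0.05;
  the mean realized false-discovery proportion must match the mean achieved
  FDR within 2 Monte-Carlo SE.
* Oracle equivalence: all valid 2×2 tables with N ≤ 60 against exact
  integer combinatorial suffix sums, relative error < 1e-12.

## Numerical and degenerate-input choices

Thresholds are accepted in (0, 1]; α = 1 calls everything and drives all
ORA p-values to 1 (study = population).  Empty selections report NaN FDR.
k = 0 terms are retained with p = 1 (flagged, suppressible).  Isoform
accessions are version-stripped (`ENST….8` → `ENST…`) before joining across
files.  Annotation files with more than 50% unknown term ids are rejected
as probably mismatched with the ontology release (threshold configurable).

## Limitations

Isoform GO annotations are predictions, not curated assignments; enrichment
over them inherits their biases, and the synthetic generator models neither
annotation prediction error nor the correlation structure of real GO
(term sizes here are roughly exchangeable, whereas real term sizes span
four orders of magnitude).  Passing planted-recovery and type-I tests
therefore demonstrates correctness of the statistics under exchangeable
annotations, not power on any particular real dataset.  The per-gene report
is textual; genomic exon/domain graphics are out of scope.
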