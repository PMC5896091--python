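# Methods

## Motif model

Substitutions are classified against three APOBEC-like trinucleotide
motifs written 5′→3′ with IUPAC ambiguity codes, the substitution in
parentheses: T(C>K)W, T(C>D)R, T(C>D)D with K = {G,T}, W = {A,T},
R = {A,G}, D = {A,G,T}. A plus-strand match requires the reference-strand
triplet (5′ flank, C, 3′ flank) and an alternate base in the allowed set;
a minus-strand match requires the reverse-complemented triplet (so the
reference base is G) with the complemented substitution. The center base
is C on exactly one strand, so a (motif, SNV) pair can match at most one
strand. Both narrow motifs are strict subsets of T(C>D)D: their
(alt × 3′ flank) sets are contained in D × D, so every narrow match
implies a same-strand T(C>D)D match. An SNV matching several classes
contributes one event to each class; the three classes are analyzed
independently throughout (per-class tallies, never deduplicated across
classes).

Only single-base flanks are consulted. Records whose flank is N or
missing (chromosome edge) are excluded from motif analysis but still
count toward the total SNV tally, which is defined on all substitutions.

## Catalog filtering and mutation counts

Population-common variants are removed with a strict rule: panel allele
frequency > 0.01 drops the record; a record exactly at the threshold, or
with no panel frequency at all, is kept (absence from the panel is read
as rarity). Seven per-cell-line counts are computed: C>G, C>T and
C>K = C>G + C>T on the reference strand; the same three categories on
both strands, where the both-strand counter adds the reverse-complement
change as read on the reference strand (C>T + G>A, C>G + G>C); and the
total SNV count. C>G is intrinsically strand-symmetric (its reverse
complement is G>C), but its both-strand counter follows the same additive
rule so all categories are computed uniformly. Coordinates are 1-based
inclusive everywhere; the only 0-based, half-open conversion happens in
the BED exporter.

## Kataegis detection

A criterion (k, w) asks for k same-motif, same-strand events within a
w-bp window; the two used are 5/1000 and 6/10000. Window membership uses
span ≤ w − 1: a w-bp window covers w bases, so k events fit iff the
coordinate difference between the first and last is at most w − 1. Events
are partitioned by (chromosome, strand, motif class); a run of k
consecutive events in a partition whose span fits is a qualifying window;
an event is clustered iff it lies in at least one qualifying window; and
qualifying windows sharing at least one event merge transitively into one
maximal region. This yields distinct, non-overlapping, never-touching
clusters with no tie-breaking. Cluster extent is event-bounded — start
and end are the first and last member positions, length is
end − start + 1 — rather than extended to window edges or the 3-bp motif
footprint, the minimal convention consistent with reporting combined
cluster lengths. Duplicate positions within a partition are collapsed
with a warning. Four abundance measures summarize each (cell line, motif,
criterion): total motif events, events inside clusters, number of
clusters, combined cluster length in bp.

The implementation marks qualifying k-runs with a linear scan and merges
overlapping index ranges; tests verify it against an O(n²) enumeration of
every event interval fitting the window, on 2000 random catalogs plus
adversarial cases, and check monotonicity in k and w and translation
invariance.

## Phenotype harmonization

Probe-level log2 expression collapses to gene level by the arithmetic
mean over a probe→gene map; means ignore missing entries cell-wise, so a
gene×cell value is missing only when all its probes are. Drug response is
stored on the log10(IC50) scale: natural-log sources are divided by
ln 10, linear sources are log10-transformed (nonpositive IC50 is a hard
error), already-log10 input passes through, making the operation
idempotent; replicate measurements of one (cell line, agent, source) are
averaged on the log10 scale. Copy-number loss is called at log2
normalized ratio < −0.75, with the boundary assigned to "intact". Missing
values propagate (no imputation): downstream correlation uses
pairwise-complete observations and reports per-pair n. Cell-line identity
across sources is reconciled only through an explicit synonym table; no
fuzzy matching.

## Correlation and multiple testing

Spearman's ρ is the Pearson correlation of tie-averaged ranks. The
two-sided p-value uses t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom.
At |ρ| = 1 that approximation degenerates, so the exact two-sided
permutation tail 2/n! is reported instead — a deliberate choice: a
correctly specified test at n = 5 and |ρ| = 1 cannot produce p-values
many orders of magnitude below 2/120, whatever a particular software
stack prints. Pairs with fewer than three complete observations or zero
rank variance are untestable; they are excluded from the family and
logged rather than assigned p = 1, which would silently inflate the
family size.

A test family is the cross of a left variable set, a right variable set
and a set of strata (cancer categories, or the single pan-cancer
stratum). A (pair, stratum) combination enters the family only when it
has at least min_n = 5 pairwise-complete cell lines — eligibility is per
pair, not per table. All raw p-values of a family are adjusted jointly by
the Benjamini–Hochberg step-up rule with m equal to the number of tests
actually computed, and that m is reported as N_tests on every result so
alternative family accountings can be audited. The significance filter is
strict on both margins: p_adj < 0.05 and |ρ| > 0.25. Output ordering and
all floating-point reductions are fixed-order, so results are
deterministic.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth. Its defaults describe a desk-scale whole-exome
panel:

- **Genome**: three chromosomes totalling 1.5 Mb, i.i.d. bases at 25%
  each. Composition is multinomial, so observed frequencies are within 1%
  of target for chromosomes ≥ 100 kb.
- **Background SNVs**: 1.5 × 10⁻³ per bp per cell line (Poisson), the
  post-filter exome SNV density typical of heavily mutated cancer cell
  lines, placed uniformly with a uniform alternate base. 10% of
  background variants are flagged common (panel AF drawn above 1%); the
  rest carry either no panel frequency or one below 1%.
- **Planted clusters**: sites are *searched* in the existing genome, never
  mutated into existence, so classification runs against realistic
  context scarcity. Site patterns are motif-specific — T(C>K)W is planted
  with 3′ T (not a T(C>D)R context), T(C>D)R with 3′ G (not T(C>K)W), and
  T(C>D)D with 3′ T and alt A (neither narrow motif) — so each planted
  cluster appears under exactly its own class plus the umbrella T(C>D)D
  class; the truth table enumerates those implied umbrella clusters
  explicitly. Every planted cluster keeps an isolation gap (default
  10,001 bp > both window widths) from other planted regions and from
  background placements, so planted (start, end, n) match detection
  exactly in noiseless runs. Defaults plant one narrow-motif cluster
  (6 events / ≤ 800 bp) and one broad cluster (7 events / ≤ 5000 bp) per
  cell line.
- **Expression**: five candidate genes by default; APOBEC3B follows a
  two-component Gaussian mixture (means 4 and 10 log2 units, 35% in the
  low mode, emulating the bimodal expressor/deletion-carrier pattern),
  the others are unimodal with means and spreads typical of large
  cell-line panels.
- **Drug response**: log10(IC50) columns centered at 0.5 with SD 0.8. A
  planted association maps the partner variable's ranks to standard
  normal scores z, then sets the latent response to r·z + √(1−r²)·ε with
  r = 2·sin(π·ρ_S/6) — the Gaussian-copula identity ρ_S = (6/π)·arcsin(r/2)
  solved for the latent correlation — so the response is a monotone
  function of the variable plus noise whose population Spearman
  correlation equals the target. Associations can be scoped to one
  category or pan-cancer.
- **Randomness**: one child stream per output table (genome, catalogs,
  phenotypes), spawned from the master seed, so any table can be
  regenerated without disturbing the others; all outputs are bit-exact
  functions of (config, seed).

What the generator does *not* emulate: read-level sequencing error,
exome capture bias, trinucleotide-composition bias of real genomes,
correlated mutational processes beyond the planted clusters, probe-level
microarray noise, and dose–response curve fitting upstream of IC50.
Passing tests therefore demonstrate correctness of the analysis logic
under the stated statistical model, not robustness to every artifact of
real panels.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for a
single CPU: the end-to-end determinism check uses a 50-cell-line,
three-category panel on the 1.5-Mb genome; cluster-detection equivalence
uses 2000 random catalogs of ≤ 200 events; planted-cluster recovery uses
100 noiseless two-cell-line configurations on a 120-kb chromosome; null
FDR calibration uses families of 500 tests × 200 replicates (the realized
false-discovery proportion in a fully null family is 1 when anything is
rejected, so its mean estimates the FDR and is compared to 0.05 plus a
three-sigma Monte-Carlo margin); association recovery uses 500 replicates
at n = 100. TSV writers emit floats with `%.17g` and readers parse with
round-trip precision, so written tables reproduce in-memory values
bit-exactly. BH adjustment and Spearman agree with independent reference
implementations (statsmodels, scipy) to 10⁻¹²; the only deliberate
divergence is the |ρ| = 1 permutation tail described above.

## Known limitations

- Kataegis calling is threshold-based by design; no inter-mutation
  distance (rainfall) model or cluster significance probability is
  provided.
- The combined-length convention is event-bounded; analyses that extend
  clusters to window edges or motif footprints will report longer
  regions.
- AID-type motifs (WRCY/RGYW), other APOBEC family members, and
  96-trinucleotide signature deconvolution are out of scope.
- The AF filter is the only germline screen; without matched normals no
  somatic status is assigned.
- CCLE/GDSC-scale results depend on the external data themselves and are
  not reproduced here; the package reproduces the *method* and validates
  it on synthetic ground truth.
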