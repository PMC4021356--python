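# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions.

## Seed networks and valence

A *seed network* is the neighborhood of three human gene symbols in a
multi-species interaction database. Per species, any gene sharing an edge
with a seed orthologue becomes an interactor; interactors are collapsed to
human symbols through the orthology map (one-to-many mappings expand to
every symbol; unmapped genes are counted and logged, never silently
dropped). A member's **valence** is the number of distinct seeds it
touches, pooled across species — a gene touching seed A in yeast and seed
B in fly is bivalent. Seeds that interact with each other remain members
but are never counted as interactors of themselves.

After extraction, `k_augment` connector genes are appended: non-member
symbols ranked by their number of edges into the current members, ties
broken lexicographically. This replaces the label-propagation step that
interaction services use to pad networks with "predicted" genes. The
default `k_augment = 15` reflects that such padded networks typically
carry a modest tail of non-interactor genes; the valence statistics are
insensitive to the rule because connectors are excluded from all valence
counts (augmentation changes only `n_total`, a tested invariant).

Evidence types form a closed vocabulary (coexpression, genetic, physical,
shared_domain, colocalization, predicted). Edge weights are parsed and
carried but unused in counting — every network statistic here is
count-based. Duplicate undirected edges of one species/evidence collapse
keeping the maximum weight.

## Randomly-seeded null model

Null seed triples are drawn uniformly (3 distinct symbols per set, sets
may recur) from a declared pool — either a negative list of non-modifier
genes or the genome-wide symbol set. Triples containing a symbol with no
orthologue in the database are redrawn, not skipped, so the ensemble size
is exact; redraws are logged. One network and one valence summary are
computed per triple (the ensemble default is 120: 20 from a negative list
plus 100 genome-wide, mirrored by the `n_sets` option).

Two comparison families are exposed, because both appear in practice and
they answer subtly different questions:

* **one-sample t**: null per-network totals (or proportions) against the
  observed value, two-sided. Zero-variance ensembles are flagged
  degenerate with p = 1 (mean equals observed) or p = 0 (it does not).
* **Fisher's exact**: the observed network's composition against the
  *pooled* counts of all null networks, one-tailed (`greater`) by default
  since the hypothesis is enrichment. Pooling keeps the table integer for
  an exact test, at the price of treating null networks as exchangeable;
  the per-network-proportion t variant is the robustness check. For
  valence `ge1` the columns are {interactors, other members}; for
  `exactly2`, {bivalent genes, other interactors}.

An empirical-percentile p is available as a diagnostic only.

## Rare-CNV inclusion cascade and burden

Calls are 0-based half-open intervals (1-based inclusive input is
convertible on read). The cascade applies five rules in a fixed order and
records, per removed call, the first rule it failed:

1. whole-chromosome proxy: span ≥ 90% of the chromosome (array calls are
   intervals, so trisomy/monosomy appear as near-full-length calls; the
   fraction is configurable);
2. interstitial heterozygous deletions/duplications only;
3. size strictly greater than 300 kb;
4. merged segmental-duplication coverage strictly below 50% of the call;
5. control carrier frequency strictly below 0.1%.

Control frequency is not well defined for a single call without a locus
convention. The convention here: same-type calls cluster by single-linkage
at ≥50% reciprocal overlap; a call's frequency is the number of distinct
control samples in its cluster over the control denominator. A case call
clustering with no control call has frequency 0. Both the reciprocal
fraction and the threshold are parameters. Frequencies are computed on
the calls that survived rules 1–4, i.e. among comparable quality-filtered
events.

One consequence worth knowing: a gene whose per-gene carrier rate is near
`max_control_freq × control_n` carriers concentrated at a single locus
can see its whole cluster classified as common and removed — the rule
conditions on control counts only, so control-heavy loci are pruned while
case-heavy loci survive. This mirrors how "rare in controls" behaves on
real locus maps; it slightly inflates case/control asymmetry under the
null (measured at roughly 1–2 points above the nominal 5% in simulation)
and costs power when true signal is recurrent at one locus.

Carriers: a sample carries a gene if ≥1 surviving call overlaps it by
≥1 bp (half-open adjacency is zero overlap); multiple calls count once.
Burden per gene is a one-tailed (`greater`) Fisher's exact test on
[[case carriers, case non-carriers], [control carriers, control
non-carriers]]; the combined test counts a sample once if it carries any
gene of the set. Probe coverage is modeled as per-gene assayable case
denominators; the combined test uses the full cohort. Deletions and
duplications are pooled, with a per-type breakdown available as a
diagnostic. No multiple-testing correction is applied by default (per-gene
results are reported as such); Bonferroni is a caller-side option via the
stats layer.

## Statistics layer

All procedures are implemented here; only distribution tail functions
(t, χ², F, standard normal, and the hypergeometric pmf via log-gamma) come
from standard numerics.

* **Fisher's exact**: conditioned on both margins; `greater` is the upper
  tail on cell *a*; two-sided sums all tables in the support whose
  probability ≤ the observed table's, with 1e-7 relative slack for float
  ties (the probability-mass convention of standard implementations,
  rather than doubling the one-tailed p). Zero margins give p = 1 with a
  degenerate flag.
* **Mann–Whitney U**: midrank ties; exact mode enumerates every
  assignment of the pooled values to the two labels (correct under ties)
  and is selected automatically at pooled n ≤ 12; otherwise a
  tie-corrected normal approximation with a 0.5 continuity correction
  (toggleable) — severity data at n ≈ 300/group always take this path,
  matching the behavior of the commercial packages traditionally used for
  such data. The exact path exists primarily as an oracle and for tiny
  samples.
* **Kruskal–Wallis**: H with the tie correction `1 − Σ(t³−t)/(N³−N)`, p
  from χ² with k−1 df. All-identical data give H = 0, p = 1.
* **Dunn's post hoc**: z from pooled mean ranks with the tie-corrected
  variance `[N(N+1)/12 − Σ(t³−t)/(12(N−1))](1/nᵢ + 1/nⱼ)`; two-sided
  normal p, Bonferroni-multiplied over all k(k−1)/2 pairs and capped at 1.
* **One-way ANOVA**: F = MS_between/MS_within; pairwise t on the pooled
  within-group variance with N−k df, Bonferroni over all pairs.
* **Severity encoding**: normal/none → 0, slight → 1, mild → 2,
  moderate → 3; unknown labels are errors, never coerced.

Every p-value is clamped to [0, 1] by construction and checked by
property tests; rank tests are invariant under strictly monotone
transforms of the pooled data.

## Synthetic data: what it emulates, what it does not

**Interactome.** Background edges are independent per species and
evidence type (Erdős–Rényi per type) — the simplest null with tunable
density, sufficient to calibrate count statistics. Gene index *j* maps to
human symbol index *j* in every species (with probability
`orthology_coverage`, default 0.8), which is what gives cross-species
collapsing its meaning. A planted triad injects its three seed symbols at
indices 0–2 (seed orthologues always mapped) and wires each planted gene,
in a randomly chosen species, to exactly 2 (bivalent) or 1 (univalent)
seeds; background edges that would raise a planted gene's valence are
suppressed, so planted counts are exact by construction, and the planted
set is a prefix of a fixed permutation so growing it never re-rolls
earlier genes (planted-signal monotonicity). No claim of realism is made
about degree distributions, edge weights, tissue specificity, or real
nomenclature (identifiers are `sp1_g0001` / `HG0001`-style) — passing
calibration tests shows the counting and testing machinery is correct,
not that real databases look like this.

**CNV cohort.** Default cohort scale follows large clinical series: five
thousand cases against 8,329 controls. Per sample and gene, call counts
are Poisson with mean `baseline_carrier_rate` (default 0.2%, the scale of
collectively-common rare CNV carrier rates) times the gene's relative
risk in cases; calls anchored to a gene overlap it by construction with
log-uniform sizes on (301 kb, 3 Mb) — above the size filter, since the
size rule is exercised separately. Unanchored background calls (Poisson,
default 0.05 per sample — large rare CNVs are uncommon per genome) are
placed uniformly; recurrent "common" loci contribute the configured
fraction of calls as exact duplicate intervals (which the frequency rule
should remove); whole-chromosome events cover a full chromosome. Probe
coverage masks a fixed random subset of cases per gene, removing their
calls at that gene and shrinking that gene's denominator. Breakpoints
have no positional model and no genome build; linkage disequilibrium,
batch effects and call-quality variation are not modeled.

**Phenotypes.** Ordinal mode draws per-genotype multinomials over scores
{0,1,2,3}; continuous mode draws normals; an optional batch column splits
rows evenly (severity data are typically compiled from two independent
experiments). No inter-batch effect is simulated.

All three generators are deterministic under `rng_seed`, with sub-streams
derived per species/sample/gene so outputs are order-stable.

## Pipeline and reproducibility

A run is one YAML file; unknown keys are errors. One top-level seed fans
out to per-stage sub-seeds through a seed sequence, so a single integer
reproduces the whole report; the report carries a provenance block
(analysis-config hash, seed, version, timestamp) and is byte-identical
across reruns apart from the timestamp. `validate_report` re-checks the
structural invariants (p ∈ [0,1], the valence chain inequality
`n₃ ≤ n₂+n₃ ≤ n_{≥1} ≤ n_total−3`, carriers ≤ denominators).

## Problem sizes used in tests and the acceptance script

Simulation-backed checks use 5 species × 500 genes with 120-network null
ensembles, 200 observed triads for calibration, 50 replicates for
planted-triad recovery and for CNV burden power (5,000/8,329 samples at
0.2% baseline), and exhaustive enumeration up to margins of 12 (Fisher)
or pooled n of 10 (rank tests). These sizes make the Monte-Carlo error
bounds quoted in the tests meaningful while keeping any single check to
seconds.

## Known limitations

* The augmentation rule is a stand-in: real interaction services rank
  predicted genes by label propagation over weighted networks.
* Pooled-null Fisher tables treat the 120 null networks as one
  exchangeable population; between-network variance is only addressed by
  the t variant on proportions.
* The control-frequency convention (50% reciprocal, single linkage) is
  one of several in use; locus definitions materially affect which calls
  are "rare", as noted above.
* The burden analysis assumes carrier status is binary per gene and
  sample; dosage, inheritance and breakpoint-level recurrence are out of
  scope.
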