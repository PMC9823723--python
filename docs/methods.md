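# Methods

This note records the models, conventions and numerical choices behind
`cherry-curator`, in the order the pipeline applies them.

## Data model

A collection is a list of accession records: a unique accession id,
collection site, assumed cultivar name, laboratory batch, a pomological
status (determined with a name / no reference available / not determined /
approved with reservation, with a name), and a diploid SSR genotype — per
locus an unordered pair of fragment lengths in bp, stored sorted ascending
with homozygotes duplicated, or missing. Fragment lengths are plain
integers; sub-bp sizing is out of scope.

## Harmonization

Two corrections make fragment lengths comparable.

**Inter-laboratory offsets.** Capillary platforms and ladders shift whole
loci by small constant amounts. For reference genotypes run in more than
one batch, the offset of (batch, locus) is the median of
(reference-batch size − batch size) over the references' sorted allele
pairs, rounded half toward zero so a symmetric tie never overcorrects.
Offsets are integers; loci without shared reference data keep offset 0 and
are flagged. Corrected records carry the reference batch label, which
makes the correction idempotent.

**±1 bp binning.** Within a platform, sizes are only trustworthy to about
1 bp. Distinct observed sizes at a locus are sorted and maximal runs with
consecutive gaps ≤1 bp merged into one bin; the bin center is the modal
observed size (ties to the smaller size). Binning is dataset-dependent
rather than a fixed grid because panels mix motif lengths and a tolerance,
not a ladder, is what the sizing uncertainty justifies. The pairwise ±1 bp
rule is ambiguous for chains (150, 151, 152 all pairwise-close): chains are
merged but logged for curator review. A consequence worth knowing: if
*every* observation of a true allele jitters away from it in both
directions, the bridge size is unobserved and the run can split; with
realistic jitter rates this is vanishingly rare, and it is why the
duplicate-detection threshold tolerates residual mismatches anyway.

## Molecular groups and trueness-to-type

Similarity between two genotypes is the simple matching coefficient over
loci typed in both: matched alleles (greedy multiset matching of the two
pairs, exact for pairs of size two) divided by 2 × shared loci. Pairs
sharing fewer than 8 of 16 loci are not comparable (configurable). Using
mutually typed loci as the denominator, rather than all alleles, keeps
PCR dropouts from deflating similarity. A locus-fraction variant
(whole-locus matches / shared loci) is available behind a flag.

Accessions are joined by an edge when similarity exceeds the threshold
(default 0.90, chosen to absorb the ~10% per-reaction artifact rate of
routine SSR genotyping) and groups are the connected components — single
linkage, because group membership in curation practice is "included in one
molecular group", not complete-linkage cliques. Transitive merges are
logged. The group representative is the most frequent exact genotype, ties
broken by completeness then smallest accession id.

Categories per accession: a pomological determination matching the group's
majority determined name → category 1 (true-to-type); a determination
conflicting with the consensus → category 1 under the consensus name with
a relabel flag (the genetic evidence overrides the single determination,
but the conflict is surfaced); no pomological reference in a group without
any determined member → category 3; no determination → category 4;
approved with reservation → category 5. When two determined names tie
within a group, its determined members are reported unresolved instead of
being forced into a category; an undetermined accession in a group that
does have a consensus is resolved to that name and flagged as a relabel.
Category 2 is reserved for sour-cherry workflows and never emitted.

## Diversity statistics

Allele frequencies are tabulated on deduplicated unique genotypes (one
representative per molecular group), matching reporting practice — clonal
copies would otherwise distort frequencies. Each genotype contributes two
gene copies per typed locus; N is per-locus.

Per locus: `Na` = distinct alleles; `Ne = 1/Σp²`; `He = 1 − Σp²`;
`Ho` = heterozygotes/N; rarefied allelic richness
`Ar(g) = Σᵢ [1 − C(N−nᵢ, g)/C(N, g)]` computed in exact rational
arithmetic (no log-gamma rounding), with g defaulting to twice the
smallest per-locus sample size so every locus supports it. Panel means are
unweighted arithmetic means over loci.

Identity probabilities per locus assume Hardy–Weinberg equilibrium, which
is what the standard formulas encode (no correction for the clonal,
self-incompatible mating system):

    PI     = 2 (Σpᵢ²)² − Σpᵢ⁴
    PI_sib = 0.25 + 0.5 Σpᵢ² + 0.5 (Σpᵢ²)² − 0.25 Σpᵢ⁴

Cumulative products run over loci sorted by ascending single-locus value.
The minimal marker set has two modes: *empirical* adds loci in
ascending-PI order until every pair of genotypes differs at ≥1 included
locus (pairs identical across the full panel are returned unresolved);
*sib* orders by PI_sib and stops when the cumulative product falls below
1/C(n,2) — the point where the expected number of coincidentally matching
sib-level pairs drops below one. The sib stopping rule is an
interpretation (the conventional analyses do not publish one) and the
threshold is configurable.

Pairwise Fst between supplied cluster labels (cluster inference itself,
e.g. Bayesian admixture modeling, is out of scope — labels are inputs)
uses the heterozygosity form: per locus `Fst = (Ht − Hs)/Ht` with Hs the
unweighted mean of the two clusters' expected heterozygosities and Ht the
expected heterozygosity of their unweighted mean frequencies; the reported
value averages loci with Ht > 0. Clusters with fewer than two genotypes
are excluded.

## Neighbor joining and bootstrap

The dissimilarity matrix is 1 − similarity; non-comparable pairs are an
error because NJ needs a complete matrix. "Unweighted NJ" is read as the
classic Saitou–Nei agglomeration (not UPGMA): minimize
`Q(i,j) = (m−2)D(i,j) − r(i) − r(j)`, join, recompute. Ties in Q (within
1e-12) are broken toward the lexicographically smallest pair of cluster
labels, a cluster labeled by its smallest leaf, so runs are deterministic
and label-order invariant. Negative branch lengths are clamped to zero
with the deficit logged. The result is an unrooted tree stored with a
trifurcating root.

Bootstrap resamples loci (columns) with replacement — the natural unit for
marker matrices with fixed genotypes; allelic-column resampling would
break the diploid pair structure. Support of an internal edge is the
percentage of replicate trees containing the same leaf bipartition.
A single integer seed spawns one deterministic substream per replicate, so
supports are exactly reproducible and independent of replicate order.
Replicates in which some genotype loses all typed loci are dropped (they
cannot produce a comparable tree).

## Parentage verification

The engine scores pedigree *hypotheses* (the analysis verifies literature
claims rather than searching all candidates). Per locus, the LOD
contribution is `ln L(child | named parents) / L(child | unrelated HWE
parents)`, with Mendelian transition probabilities and the classic
genotyping-error model: each observed single-locus genotype is,
independently per individual with probability e (default 0.1), a random
HWE genotype rather than the true one. Marginalizing over mistyping
status gives, for a trio,

    L = (1−e)[(1−e)² T2 + e(1−e)(T1m + T1f) + e² T0] + e T0

(T2/T1/T0 = likelihoods given both/one/no true parents; pairs analogous).
With e = 0 a single Mendelian exclusion drives the LOD to −∞; with e > 0
exclusions are penalized but finite. Alleles absent from the frequency
table (e.g. introduced by typing error) get a floor frequency of half a
gene copy. Loci missing in the child or in all named parents are skipped;
hypotheses with fewer than 13 usable loci are unevaluated.

Confidence is calibrated by simulation under the study parameters
(100,000 progeny by default — scaled runs use fewer and say so; 95% of
candidate parents sampled; 90% of loci typed; 10% mistyped; candidate set
sizes 31 parent-pairs / 18 mothers / 7 fathers). For single-parent modes
the most likely of the candidates is assigned; for trios the candidate
*mother × father pairs* compete, each side containing the true parent
independently with probability 0.95 — this matters, because the dominant
error mode is a half-right pair (true mother, wrong father), and only a
pair-level simulation places the strict threshold above it. The strict
(95%) and relaxed (80%) thresholds are the smallest LOD values at which
simulated assignment precision reaches the level, where precision is
assessed by its one-sided Wilson lower bound with z = 3 so the guarantee
is conservative to simulation noise and holds out-of-sample rather than
only in-sample. The assignment statistic is the hypothesis LOD by
default; a Δ (best-minus-second) statistic is available when ranking
candidate lists. Verdicts: `*` (≥ strict), `+` (≥ relaxed), `−` (below).

## Synthetic collections

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

- **Loci**: default 16, allele ladders strictly 2 bp-spaced (dinucleotide
  motifs), 8–22 ladder alleles per locus (mean 15). Frequencies are
  symmetric Dirichlet draws, concentration 0.25, giving an expected
  locus heterozygosity `1 − (α+1)/(kα+1)` ≈ 0.72 on the default ladder
  range — inside the 0.55–0.80 band typical of polymorphic SSR panels.
  Because the Dirichlet is strongly skewed, the number of alleles
  *observed* in a modest sample is well below the ladder size; sample He
  also sits slightly below the analytic expectation. That mirrors real
  panels (few common alleles, a tail of rare ones) but means small
  synthetic collections are less allele-rich than a 383-genotype real
  collection at the same ladder size.
- **Cultivars**: HWE founder draws, plus designed trio children and
  full-sib families (Mendelian crosses of founders, exclusion-free by
  construction).
- **Clones**: 2–6 trees per cultivar. Corruptions per clone, each logged:
  per-locus mistyping at the ~10% per-reaction artifact rate (optionally
  capped per clone, to plant a bounded-corruption condition such as
  "≤5% of alleles"), ±1 bp sizing jitter per allele (5%), missing loci
  (3%), and constant per-(batch, locus) size offsets for multi-laboratory
  scenarios, with pristine reference genotypes emitted in every batch for
  offset estimation.
- **Certification**: the generator reports the worst within-cultivar clone
  similarity (after ideal harmonization, i.e. mistypes and missingness
  only) and the best between-cultivar similarity, so a test can verify the
  margins on which perfect duplicate recovery depends instead of assuming
  them. Replaying the logged corruptions onto the pristine genotypes
  reproduces the emitted records exactly.
- **Labels**: pomological statuses follow configurable per-cultivar
  reference availability (default 90%) and per-tree
  no-determination/reservation rates (defaults 4.4% and 1.6%).

What passing on synthetic data does *not* show: real collections have
relatives at all degrees (not just planted trios), null alleles, stutter,
and laboratory effects beyond constant offsets; none of these are
simulated, so synthetic recovery rates are upper bounds on real-data
performance.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: collections of
25–100 cultivars (150–400 trees), bootstrap with 20–200 replicates on
10–30 taxa, Monte-Carlo identity-probability oracles at 10⁶ genotype
pairs per locus, and parentage calibration at 10,000 simulated progeny —
sizes chosen so the whole pipeline reruns in about a minute while keeping
every estimate's sampling error far below the asserted margins. Every
stochastic component takes an explicit integer seed; derived substreams
use `numpy.random.SeedSequence`, so all outputs are bit-reproducible for a
fixed seed on any platform.

## Known limitations

- Binning assumes integer sizes; mixed-motif panels with true 1 bp allele
  classes (mononucleotide runs) would be over-merged.
- The single-linkage 90% rule can chain distinct but very similar
  cultivars into one group (logged); conversely, heavily corrupted clones
  (>~3 mistyped loci of 16) can split off — both are inherent to the
  tolerance, not implementation artifacts.
- PI/PI_sib assume HWE and independence across loci; clonal sampling and
  population structure bias them downward, which is why the sib variant
  and the deduplicated frequency base are used.
- Parentage thresholds assume candidates unrelated to the true parents;
  collections dense in close relatives will show lower real-world
  precision than the simulation promises.
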