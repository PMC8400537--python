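# Methods

`hybridscan` detects recent hybrids and tests species boundaries in
target-capture multilocus data from closely related plant (or other diploid)
species.  It integrates four lines of evidence — observed heterozygosity,
phased-allele placement in per-locus gene trees, nucleotide diversity /
weighted FST between groups, and ABBA-BABA trio tests — and ships a
multispecies-coalescent simulator so the whole chain is testable without
external data.  This note records the models, the defaults and why, the
numerical choices, and what the synthetic data do and do not emulate.

## The coalescent simulator

Genealogies are drawn from the structured (multispecies) coalescent via
msprime: within a population of diploid effective size `N`, each pair of
lineages coalesces at rate `1/(2N)`; populations merge rootward at the
species tree's divergence times; migration moves single lineages between
populations, either continuously over a time window or as an instantaneous
admixture pulse (the natural model for a recent introgression event, and the
configuration used for f4-ratio recovery checks).  Sequences evolve under
Jukes–Cantor on a discrete genome, so multiple hits occur and the closed
forms `E[T2] = 2N` and `p_diff = (3/4)(1 − e^{−8μt/3})` hold and are asserted
in the test-suite, together with the 3-taxon incomplete-lineage-sorting
probability `(2/3) e^{−T/2N}`.

Units are explicit everywhere: times in generations, diploid `N`, mutation
and migration rates per generation.  Randomness flows from a single root
seed; each locus derives its ancestry and mutation seeds from a
counter-keyed substream, so any locus is reproducible in isolation and the
whole dataset is byte-identical across runs.

**F1 hybrids.**  A first-generation hybrid carries, at every locus, one
haplotype from each parental gene pool.  The simulator realises this by
sampling one extra lineage in each parent population and pairing them as the
hybrid's two haplotypes.  Because adding a specimen *after* simulation must
not perturb anyone else's sequences, datasets can carry per-species reserve
lineages (`pool_reserve_per_species`) simulated jointly with everything
else; `make_f1_hybrid` then promotes one reserve per parent into the new
specimen — fresh coalescent samples from the parental pools, never copies of
existing specimens, and bit-identical non-hybrid output before and after.

**Default study conditions.**  The test-suite's standard system is a
three-species radiation `(((P1,P2),P3),OUT)` with `N = 10,000`, splits at
40/80 kyr (in generations) for the D-statistic calibrations — deep enough to
polarise alleles, shallow enough that incomplete lineage sorting is
appreciable (internal branch of `2N` ⇒ ~9% discordant gene trees) — and
deeper splits (150/300/600 k generations) for the placement demonstrations,
where species must be identifiable clades in single-locus trees.  Loci are
1 kb with `μ = 3×10⁻⁸` per site per generation, giving within-species
diversity `4Nμ ≈ 1.2×10⁻³` per site, a realistic magnitude for nuclear loci
in long-lived plants.  Calibration suites use 500 loci × 100 replicates
(null) and 50 replicates (power); the end-to-end pipeline demonstrations use
300 loci × 20 replicates with 4 specimens per species plus a 2-specimen
outgroup.  These sizes were fixed once as the package's standard conditions.

What the generator does **not** emulate: within-locus recombination,
selection, backcrosses/F2s (an F1-only hook exists), read-level errors,
alignment error, and phasing failure.  Missingness is available only as
whole-specimen-per-locus dropout.  Passing tests therefore demonstrate the
statistical machinery under clean phasing and correct alignments; on real
herbarium-grade data the placement diagnostic inherits whatever error the
upstream phasing and tree estimation introduce.

## Genotype matrix and filters

Biallelic SNPs only.  From phased alignments, exactly the columns with two
segregating nucleotides among non-missing haplotypes are emitted
(three-or-more-allele columns are skipped and counted); the reference allele
is the majority allele with ties broken alphabetically, a convention chosen
so the two extraction paths (from alignments and from simulated variants)
agree exactly — downstream statistics are either label-invariant or
outgroup-polarised, so the choice is inert.

Site filtering mirrors the vcftools idiom `--minDP 8 --remove-indels
--min-alleles 2 --max-alleles 2 --max-missing 0.8`.  Note the trap:
`--max-missing 0.8` *keeps* sites with at least 80% of genotypes called.
Depth masking happens before the missingness count; depth is optional and
simulated data carry none, making the minDP step a no-op there.  Specimen
filtering removes specimens with more than 20% missing calls *first*, then
re-screens positions at the same threshold — the order matters and is
asserted by a test in which a site survives only because a bad specimen was
removed before the site was judged.

## Observed heterozygosity

`H_obs` = heterozygous calls / non-missing calls, per specimen; missing
genotypes enter neither side, keeping `H_obs ∈ [0,1]` under any missingness.
The outlier scan compares each specimen to the *other* members of its
putative species (leave-one-out mean and SD).  With the candidate included,
a group of n bounds every member at `|z| ≤ (n−1)/√n` (≈1.8 at n=5), which
would make a z>3 rule unsatisfiable in small groups; leave-one-out removes
the bound and is the scan's documented behaviour.  Groups with fewer than
three other members are flagged `insufficient group size` rather than
z-scored.  The default flag threshold is z > 3; leave-one-out z-scores in
tiny groups are heavy-tailed (t-like), which is why the pipeline's combined
verdict never relies on this gate alone.

## Nucleotide diversity and FST

Per-site π for a group is the sample-size-corrected mean pairwise difference
`2j(n−j)/(n(n−1))` over the group's non-missing alleles, averaged over SNP
sites (not divided by locus length — the statistic is per *variable site*,
matching per-site vcftools output).  Its per-site maximum is `n/(2(n−1))`,
not 1/2: at `n = 2` a single differing pair gives π = 1.

FST is Weir & Cockerham's (1984) estimator: per-site variance components
`a` (among populations), `b` (among individuals within populations), `c`
(within individuals, i.e. heterozygosity), with per-site sample sizes from
the non-missing calls.  The headline number is the weighted ratio
`Σa / Σ(a+b+c)`; the mean and SD of per-site ratios are reported alongside
because group tables in this field print "weighted mean ± SD".  Negative
per-site components are kept in the sums (the W&C convention), so weakly
differentiated pairs can print slightly negative FST.  The test-suite checks
the components against an independent ANOVA mean-squares implementation
(`a = (MSP−MSI)/(2n_c)`, `b = (MSI−MSG)/2`, `c = MSG`) to 1e−12.

Hybrid-candidate specimens (role `query` in the species map) are excluded
from every group frequency computation — a specimen of mixed ancestry inside
its putative species' pool would otherwise bleed its other parent's alleles
into π, FST and D.

## Trio allele-sharing tests

Patterson's D uses the frequency-weighted formulation: with group alt-allele
frequencies polarised so the outgroup's major allele is ancestral,
`abba = (1−p1)p2p3(1−pO)`, `baba = p1(1−p2)p3(1−pO)`, and
`D = Σ(abba−baba)/Σ(abba+baba)`.  Outgroup-polymorphic sites are retained
with their frequency weight.  When the outgroup frequency is exactly 1/2 the
ancestral state is ambiguous; both polarisations are averaged, which makes
every statistic exactly invariant to which allele the matrix labels "alt"
(a property test).  Significance comes from a delete-one block jackknife
with the locus as block — the natural linkage unit of target capture; site
order within the matrix is irrelevant by construction.  Reported trios are
arranged so D ≥ 0, with the original order kept.

The f4-ratio admixture fraction uses the two-subsample form: P3 is split
into seeded random halves and
`f = N(P1,P2,P3a,O) / N(P1,P3b,P3a,O)` with `N` the D numerator.  Without
gene flow the numerator's expectation is 0; with a fraction α of P2's
ancestry from P3 the ratio recovers ≈α (the calibration suite recovers a
20% pulse to within ±0.1, with a small downward bias from post-admixture
drift).

Dmin is the minimum |D| over the three arrangements of a trio, reported
with the jackknife Z and p of the minimising arrangement; a significantly
positive Dmin means no single species tree relates the trio even allowing
incomplete lineage sorting.  Across all `C(k,3)` trios, raw p-values are
adjusted by Bonferroni (`min(1, m·p)`) and Benjamini–Hochberg step-up.

## Phased-allele placement

Every diploid specimen contributes tips `{specimen}_h0` / `{specimen}_h1`
to each rooted gene tree (a bare `{specimen}` tip — an unphased or
homozygous locus — stands for both alleles).  "Nesting" is operationalised
deterministically: walk rootward from the allele tip; the first ancestor
whose subtree contains at least `min_reference_tips` (default 2) reference
tips — the query's own tips excluded — decides.  If at least `purity`
(default 0.90) of those tips belong to one species, and the clade's support
clears `min_support` (default 0 = off, since manual inspection protocols
rarely state a support cut-off), the allele is assigned there; otherwise it is
`unsupported`, with the cause (purity, support, or no informative clade)
logged separately.  A locus is *monospecific* if both alleles assign to the
same species, *heterospecific* if to different species, and
*missing/unsupported* otherwise.

Summary percentages are computed over assigned alleles only, and
mono/heterospecific percentages over classified loci, rounded half-up to one
decimal (spreadsheet-style, the usual convention of summary tables; note
Python's built-in `round` is half-even and would differ).

The F1 test: among alleles assigned to the two top parental species, an
exact two-sided binomial test against 0.5.  Verdicts are a pure rule table —
`insufficient data` under 10 informative alleles; `not-hybrid` when the
minor parent holds under 10% of alleles or the heterospecific fraction is
below 0.2; `consistent-with-F1` when balance is not rejected at α;
otherwise `skewed` (the backcross / unbalanced-introgression signature —
also what a genuinely balanced F1 with many uninformative loci can drift
toward).

Gene-tree input is Newick (one file per locus or a multi-tree file) with a
`locus<TAB>alignment_length` sidecar; the locus-length filter keeps trees
whose alignment is *strictly longer* than the threshold (default 900 bp —
"more than 900" semantics: 901 kept, 900 dropped).  For self-contained runs
a neighbor-joining builder on Jukes–Cantor distances is provided as
plumbing: NJ is exact on additive matrices and adequate for well-separated
species; saturated distances (p ≥ 3/4) are capped and counted.  Trees are
rooted on the configured outgroup tips; inputs without outgroup tips are
rejected rather than midpoint-rooted, because a silently flipped root can
invert nestings.

## Pipeline and the combined verdict

Stages (simulate/ingest → filter → heterozygosity → π/FST → trios →
placement → evidence) communicate only through files, so any stage can be
rerun or replaced.  The consolidated report flags a specimen as a hybrid
when all three gates hold: leave-one-out `H_obs` z above `z_threshold`
(default 3), heterospecific fraction above
`max(background × het_factor, het_floor)` (defaults 3× the median across
reference specimens, floor 0.1), and parental balance not rejected
(binomial p ≥ α, default 0.05).  The conjunction is deliberately
conservative: single gates misfire (small-group z-scores are heavy-tailed;
incomplete lineage sorting produces a nonzero background heterospecific
fraction), but their joint false-positive rate on pure-species simulations
is near zero, which the null calibration suite asserts.

## Numerical and degenerate-input choices

- Division-free guards everywhere: zero denominators yield explicit
  `None`/flags (undefined D, undefined FST, undefined H_obs), never NaN
  propagation.
- Jackknife Z needs ≥2 blocks with non-zero leave-one-out denominators.
- W&C sites require ≥1 called diploid in each group and `n̄ > 1`; skipped
  sites are counted.
- JC distances cap the mismatch fraction just below 3/4 (where the
  correction diverges) and flag the pair.
- Percentages: decimal half-up at one decimal, via `decimal.Decimal`.
- All report JSON is key-sorted with no timestamps, so fixed seeds give
  byte-identical bodies.

## Known limitations

- The placement rule is a deterministic stand-in for expert manual tree
  inspection; it has no notion of branch lengths, only clade composition.
- The NJ plumbing underperforms ML trees near saturation or under strong
  rate heterogeneity; import externally built trees for real analyses.
- f4-ratio assumes the donor is P3 (or a proxy subgroup of it); "ghost"
  donors bias the estimate downward.
- The simulator's reserve-lineage mechanism supports F1s only; backcross
  and F2 designs would need explicit pedigree simulation.
- Continuous migration windows use a single backward-time rate; asymmetric
  two-way flow must be specified as two entries.
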