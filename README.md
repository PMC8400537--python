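# hybridscan

Species delimitation and hybrid detection from target-capture multilocus
data.

Taxonomically difficult groups — recent radiations, species complexes with
incomplete lineage sorting, sporadic hybridisation — often defeat any single
analysis.  `hybridscan` implements the combination of population-genetic and
phylogenetic diagnostics that resolves such cases in practice, around one
central idea: **in a first-generation hybrid, the two phased alleles of each
nuclear locus nest in different parental species**, roughly half toward each
parent, while heterozygosity is sharply elevated and four-taxon
allele-sharing statistics reveal gene flow between the parental lineages.

The toolkit:

- **Simulator** — multispecies coalescent (msprime backend) with named
  species trees, diploid specimens, optional F1 hybrids (one haplotype per
  parental gene pool), pulse or continuous introgression, Jukes–Cantor
  mutations, FASTA/VCF/Newick/TSV output.  Every downstream stage is
  testable without external data.
- **Genotypes** — biallelic SNP matrix with the standard filter chain
  (`minDP`, biallelic-only, per-site and per-specimen missingness; note
  vcftools' `--max-missing 0.8` *keeps* sites ≥80% called).
- **Heterozygosity** — per-specimen observed heterozygosity
  H_obs = het / (het + hom) with a leave-one-out z-score outlier scan per
  putative species.
- **popgen** — per-site nucleotide diversity π = 2j(n−j)/(n(n−1)) and
  Weir–Cockerham weighted FST = Σa/Σ(a+b+c), missing-data aware.
- **dstats** — Patterson's D (ABBA-BABA) with locus-block jackknife Z,
  f4-ratio admixture fraction (split-donor form), Dmin over all trio
  arrangements, Bonferroni and Benjamini–Hochberg corrections across all
  C(k,3) trios.
- **placement** — the core hybrid diagnostic: assign each phased allele of a
  query specimen to the species whose reference tips it nests among
  (deterministic clade-composition rule), classify loci as mono- vs
  heterospecific, summarise per specimen, and test the F1 balanced-parents
  expectation with an exact binomial test.
- **pipeline** — one configured run joining all evidence into a
  machine-readable report with an explicit, overridable combined hybrid
  verdict.

## Worked example

A three-species system with one planted F1 hybrid between species A and B,
100 loci of 1 kb, via the command line:

```bash
hybridscan run --config demo.yaml
```

with `demo.yaml`:

```yaml
out: runs/demo
seed: 42
simulation:
  n_loci: 100
  locus_length: 1000
  mutation_rate: 3.0e-8
  n_specimens_per_species: {A: 4, B: 4, C: 4, OUT: 2}
  outgroup: OUT
  species_tree:
    species: [A, B, C, OUT]
    pop_sizes: {A: 10000, B: 10000, C: 10000, OUT: 10000,
                ancAB: 10000, ancABC: 10000, root: 10000}
    joins:
      - {time: 150000, derived: [A, B], ancestral: ancAB}
      - {time: 300000, derived: [ancAB, C], ancestral: ancABC}
      - {time: 600000, derived: [ancABC, OUT], ancestral: root}
  hybrids:
    - {specimen: hyb1, parent_a: A, parent_b: B}
```

prints (abridged):

```
hybridscan evidence report
==========================

seed: 42
sites kept: 5626  specimens kept: 15

specimen        species          H_obs       z  het.frac  balance_p  verdict
A_1             A               0.0176   -0.51     0.000   4.98e-60  not-hybrid
A_2             A               0.0183   -0.50     0.000   1.24e-60  not-hybrid
...
hyb1            A               0.1740  123.47     1.000          1  consistent-with-F1  << HYBRID

trio tests (D / f4 / Dmin):
  (A,B;C) D=+0.410 Z=1.78 f4=0.006 Dmin=0.410 p_BH=0.0743
```

Reading it: the planted hybrid's observed heterozygosity (0.174) is an
extreme outlier against its putative species (leave-one-out z ≈ 123 vs
H_obs ≈ 0.018 in pure A specimens); its heterospecific-locus fraction is
1.0 (every classified locus has one allele nested in A and the other in B)
against 0.0 for every pure specimen; and the parental balance is not
rejected (exact binomial p = 1), so the combined rule flags it —
`<< HYBRID` — while no pure specimen trips all three gates.  The trio test
is correctly non-significant (Z = 1.78, f4 ≈ 0): there is no migration in
this simulation, and at these deep divergences so little incomplete lineage
sorting survives that the tiny ABBA/BABA sums make the *point estimate* of
D noisy — which is exactly why significance rests on the jackknife Z, not
on |D|.  (Hybrid candidates are excluded from group allele frequencies, so
the F1 itself cannot masquerade as gene flow between its parents.)

The same analyses are available piecemeal (`hybridscan simulate / filter /
het / pi / fst / dstats / place`) and as a library:

```python
from hybridscan.placement import PlacementSummary, f1_test

s = PlacementSummary.from_counts(
    "191", {"oblongifolium": 192, "perrieri": 2, "pervillei": 144},
    missing_unsupported=137, monospecific=101, heterospecific=68,
)
print(s.species_pct)            # {'oblongifolium': 56.8, 'perrieri': 0.6, 'pervillei': 42.6}
print(f1_test(s).verdict)       # 'skewed'  (balanced bi-parental, p < 0.05)
```

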