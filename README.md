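# beepop

Population-genomic statistics and wing geometric morphometrics for
honey bee (*Apis cerana*) cohorts — and, more generally, for any small
diploid resequencing panel with an accompanying landmark-morphometric
survey.

The package is aimed at population geneticists who have a multi-sample
SNP VCF, a sample-to-population map, a GFF3 gene annotation and
(optionally) TPS landmark files from wing photographs, and who want the
standard regional-differentiation workup:

- **Windowed nucleotide diversity** π and **windowed Weir–Cockerham
  Fst** (default 40-kb windows, 20-kb steps), pairwise-Fst matrices
  with unweighted pair summaries.
- A **selective-sweep scan**: per 20-kb/10-kb window, Fst between a
  candidate and a reference cohort plus the within-cohort diversity
  ratio; Fst is Z-transformed and θπ-ratio log₂-transformed, and
  windows in the top 5% of *both* are selected, merged into regions and
  annotated with overlapping genes.
- **LD decay** (composite genotype-dosage r² binned by distance, decay
  distance at the r² < 0.1 crossing), per-individual **heterozygosity
  and inbreeding** (He, Ho, F), and a minimal **genotype PCA**.
- **Geometric morphometrics**: TPS I/O, centroid size (CS), Bookstein
  baseline registration, Generalized Procrustes Analysis with a GLS
  consensus, shape PCA, one-way ANOVA with Fisher's LSD letters, and
  stepwise regression of site-mean CS on latitude/longitude/altitude.
- A **synthetic-data generator** (Balding–Nichols genotypes with
  injectable sweeps, landmark configurations with group shape offsets
  and nuisance similarity transforms) so the whole pipeline can be
  exercised with known ground truth and no sequencing data.

## The statistics at the core

Per biallelic site the Weir–Cockerham (1984) variance components are
computed from the per-population sample sizes *nᵢ*, allele frequencies
*pᵢ* and heterozygote proportions *hᵢ*: *a* (among populations), *b*
(among individuals within populations) and *c* (within individuals).
Windowed and genome-wide Fst are ratios of sums, Σa / Σ(a+b+c), which
can be slightly negative — and is reported as such.  Per-site diversity
is π = n_ref·n_alt / C(n, 2) over non-missing alleles, and window π
divides the per-site sum by the window length in bp.

For the sweep scan, each window carries Z(Fst) and
log₂(π_reference / π_candidate), so a sweep in the candidate cohort
(diversity depleted, differentiation elevated) lands in the upper tail
of both.

For morphometrics, CS = √Σᵢ‖xᵢ − x̄‖², and GPA centers every
configuration, scales it to unit CS and iteratively rotates it onto the
GLS consensus (rotation only, no reflection).

## Worked example

```python
from beepop import (GenoSimSpec, SweepSpec, simulate_genotypes, genome_fst,
                    compute_sweep_stats, select_top_intersection, merge_regions)

spec = GenoSimSpec(n_pops=2, n_per_pop=20, n_snps=5000, fst=0.05,
                   sweeps=(SweepSpec(900_000, 1_000_000),), seed=1)
g, pops, truth = simulate_genotypes(spec)
print(f"genome-wide Fst: {genome_fst(g, pops):.4f}")

wins = compute_sweep_stats(g, pops.samples_for("pop1"), pops.samples_for("pop2"))
selected = select_top_intersection(wins, q=0.05)
for r in merge_regions(selected):
    print(f"sweep region {r.chrom}:{r.start+1}-{r.end} "
          f"({r.n_windows} windows, peak Z(Fst) = {r.peak_z_fst:.2f}, "
          f"peak log2 ratio = {r.peak_log2_ratio:.2f})")
```

prints

```
genome-wide Fst: 0.0720
sweep region chr1:890001-1000000 (10 windows, peak Z(Fst) = 5.26, peak log2 ratio = 3.70)
```

Two populations were simulated at background divergence F = 0.05 with a
100-kb sweep injected at 900–1000 kb in the first one (diversity
reduced 10×, local divergence 0.6).  The genome-wide Fst estimate
(0.0720) reflects background divergence plus the sweep's contribution,
and the joint top-5% scan recovers the injected interval as a single
merged region — the extra 10 kb on the left is the half-overlapping
window straddling the sweep edge.

The same workflow is available from the shell:

```sh
beepop simulate --out fixtures --seed 1
beepop popstats --vcf fixtures/genotypes.vcf --popmap fixtures/population_map.tsv --out pop
beepop sweep    --vcf fixtures/genotypes.vcf --popmap fixtures/population_map.tsv \
                --candidate pop1 --reference pop2 --gff fixtures/genes.gff3 --out sw
beepop morpho   --tps fixtures/forewing.tps --metadata fixtures/specimen_metadata.tsv --out mo
beepop report   --run-dir pop --run-dir sw --run-dir mo --out summary.md
```

Every run writes its fully resolved configuration and a log next to its
outputs, so any result can be rerun from the output directory alone.

## Layout

```
src/beepop/
  genotype_io.py      VCF/GFF3 ingestion, filtering, windowing
  popgen_stats.py     pi, W&C Fst, He/Ho/F, LD decay, genotype PCA
  sweep_scan.py       Z(Fst) x log2 theta-pi-ratio outlier scan
  morphometrics.py    TPS, CS, GPA, shape PCA, ANOVA/LSD, stepwise OLS
  synthetic_data.py   Balding-Nichols + landmark simulators, fixtures
  reference_tables.py published pairwise-Fst tables (worked examples)
  cli.py              beepop simulate|popstats|sweep|morpho|report
docs/methods.md       model and design notes
```
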