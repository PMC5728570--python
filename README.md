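# panelpop

Population-structure and diversity analysis of inbred SNP panels.

Breeding programs classify maize inbred lines into *heterotic groups*
(Stiff Stalk, Non-Stiff Stalk, Iodent): pools whose inter-pool hybrids show
heterosis. Genotyping-by-sequencing (GBS) makes it practical to infer these
groups directly from genotype data, but GBS panels arrive as multiple
partially-overlapping marker sets riddled with structured missingness.
`panelpop` implements the full analysis chain a quantitative geneticist runs
on such a panel:

1. **Merge** two marker platforms keyed on (chromosome, position), with full
   accounting of sites, missingness and heterozygosity per input set.
2. **QC** — heterozygous and third-allele calls of expected-homozygous lines
   become missing; sites are dropped on missingness (> 17.2 % by default) and
   minor-allele frequency (< 0.05).
3. **Impute** missing calls with a forward Markov chain: per chromosome, a
   2×2 transition table between adjacent sites is estimated from doubly
   observed lines, and missing calls are filled left-to-right by greedy
   argmax. Accuracy is estimated by the masked-data protocol (hide a
   fraction of known calls, re-impute, score).
4. **LD** — pairwise r² within chromosomes (squared Pearson correlation of
   haploid-coded calls, equal to D²/(p_A p_a p_B p_b)), Gaussian-kernel decay
   curves on log distance, and the crossing distance d* where r̂² = 0.2.
5. **Structure** — PCA; Nei's (1972) standard genetic distance
   D = −ln(J_XY / √(J_X · J_Y)); Ward minimum-variance agglomeration via the
   Lance–Williams recurrence (R's `ward.D` dialect by default, `ward.D2` by
   flag); tree cutting into k groups; Newick export.
6. **Diversity** — per-locus Weir–Cockerham θ in its haploid form
   (θ = (MSP − MSG)/(MSP + (n_c − 1)·MSG)), balanced maximally-unrelated
   subsampling, a 70-SNP moving-average genome scan, top-region extraction
   and ±10 kbp candidate-gene queries against a GFF3/TSV annotation.

A first-class synthetic-panel generator (`panelpop.sim`) provides the test
bed: Balding–Nichols group divergence with known F_ST, pedigree relatedness
and chromosome-scale LD from founder recycling, reference-biased
missingness, and two marker platforms with partial site overlap. Every
statistic above can therefore be validated by parameter recovery without any
external download.

## Worked example

```sh
panelpop run --seed 1 --out demo/
```

simulates the default panel (3 groups × 44 inbred lines, 10 chromosomes ×
1,000 SNPs), merges the two platforms, filters, imputes, and writes LD,
PCA, tree and F_ST artifacts plus a checksummed `manifest.json` under
`demo/`. The same analyses through the Python API:

```python
from panelpop import (SimConfig, simulate_panel, merge, apply_filters,
                      estimate_accuracy, nei_distance, ward_cluster, cut_tree)

gm1, gm2, truth = simulate_panel(SimConfig(seed=1))
merged, report = merge(gm1, gm2)
print(f"{report.n_common_sites} shared sites ({report.pct_common:.1f}%)")
# -> 1720 shared sites (17.2%)

acc, _ = estimate_accuracy(truth.complete, fraction=0.0622, reps=5, seed=1)
print(f"imputation accuracy {acc:.3f}")
# -> imputation accuracy 0.833

groups = cut_tree(ward_cluster(nei_distance(truth.complete)), k=3)
```

17.2 % is the fraction of marker sites shared by the two simulated
platforms; 0.833 is the fraction of deliberately hidden calls the forward
Markov chain restores correctly at a 6.22 % masking rate — on this LD-rich
panel the chain beats the major-allele baseline (≈ 0.76) by exploiting
adjacent-site linkage. The k = 3 tree cut recovers the three simulated
groups exactly.

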