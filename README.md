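# paleoploidy

Detection, characterization and dating of ancestral polyploidization
events from gene collinearity.

Flowering-plant genomes carry layered whole-genome duplications: an
ancient hexaploidy shared across core eudicots, plus younger
lineage-specific tetraploidizations. Each event leaves two signatures in
a genome: collinear blocks of duplicated genes, and a peak in the
distribution of synonymous divergence (Ks) of the duplicate pairs. This
package implements the comparative-genomics workflow that turns those
signatures into an event history, for genomicists studying paleopolyploid
lineages:

1. **Collinearity** — homologous gene pairs are chained into collinear
   blocks on the gene-order dotplot (gaps ≤ 50 genes, blocks ≥ 4 genes),
   with a binomial significance against uniform anchor placement.
2. **Ks estimation** — Nei–Gojobori counting over aligned CDS:
   synonymous site fractions per codon, path-averaged difference counts,
   Jukes–Cantor correction `ks = −(3/4)·ln(1 − (4/3)·ps)`.
3. **Peak decomposition** — an EM Gaussian mixture on the truncated Ks
   distribution (component count by BIC) locates one peak per event.
4. **Rate correction and dating** — lineages evolve at different speeds,
   so the shared hexaploidy peak μ_i differs per genome. With μ_G the
   slowest lineage's peak, `r = (μ_i − μ_G)/μ_G` and `λ_i = 1/(1+r)`
   align all distributions (`X_corrected ~ (λμ, λσ²)`; between-lineage
   distributions use `λ_ij = (λ_i + λ_j)/2`). Absolute ages follow from
   the hexaploidy calibration (~115–130 Mya):
   `age = (ks_event / ks_hexaploidy) × T`.
5. **Event table** — a reference-anchored homology matrix: each
   reference gene, its two hexaploidy paralogs, the outgroup ortholog
   and the 2^d expected target copies per reference column (18 columns
   for one outgroup and d = 2); dots mark gene loss or translocation.
6. **Fractionation** — deletion run lengths with a maximum-likelihood
   geometric fit (p = probability of removing one gene at a time),
   loss-epoch classification by minimum-event parsimony, 100-gene
   sliding-window retention, and subgenome-dominance tests.
7. **Simulator** — a genome-evolution simulator with configurable
   polyploidy schedules, lineage rate multipliers and biased
   geometric-run gene deletion provides ground truth for every stage.

## Worked example

```python
import numpy as np
from paleoploidy import fit_mixture, correction_coefficient, date_event

rng = np.random.default_rng(3)
ks = np.concatenate([rng.normal(0.551, 0.06, 2000),
                     rng.normal(0.944, 0.176, 2000),
                     rng.normal(1.390, 0.099, 2000)])

mix = fit_mixture(ks, seed=3)            # -> 3 components near 0.55/0.94/1.39
rc = correction_coefficient(mix.components[-1].mu, 1.053)
young = date_event(mix.components[0].mu, mix.components[-1].mu, 115, 130)
old = date_event(mix.components[1].mu, mix.components[-1].mu, 115, 130)
print(f"r = {rc.r*100:.2f}%  young: {young.age_low}-{young.age_high} Mya  "
      f"old: {old.age_low}-{old.age_high} Mya")
```

prints

```
r = 32.08%  young: 46-52 Mya  old: 79-89 Mya
```

meaning: this genome accumulated synonymous substitutions ~32% faster
than the slowest reference lineage since the shared hexaploidy, and its
two younger duplication peaks date to roughly 46–52 and 78–88 million
years ago on the 115–130 Mya hexaploidy calibration.

The `examples/` directory holds one short script per capability
(simulation, blocks, Ks, dating, event table, fractionation); each
builds a small input, runs the method and prints what the numbers mean.
A thin CLI mirrors the stages:

```bash
paleoploidy simulate --out sim/ --seed 1
paleoploidy run --config config.yaml --out results/
paleoploidy date --peak 0.551 --ech 1.390 --mu-ref 1.053
```

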