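# tcdyn

Time-course transcriptome dynamics for bulk expression profiling — built for
studies that follow a purified cell population (the motivating case: mouse
hair-follicle skin stem cells sampled at six ages with three replicates each)
and ask which genes move, in which temporal patterns, which pathways co-evolve,
and which genes sit at the core of each pattern's coexpression network.

The pipeline has four analysis stages plus a synthetic-data generator that
plants known structure so every stage is testable without external downloads:

1. **Dynamic-gene filter.** For each gene, per-time-point linear-scale means
   `X̄ᵢ` give a dispersion statistic
   `χ² = Σᵢ (X̄ᵢ − X̄)² / X̄` with `n − 1` degrees of freedom
   (`X̄` = mean of the `X̄ᵢ`). A gene is *dynamic* when its
   Benjamini–Hochberg adjusted `P(χ²) < 0.01` **and** its linear max/min fold
   change across time-point means exceeds 2 (both strict).
2. **Pattern clustering.** Dynamic genes' per-time-point mean profiles are
   z-scored and soft-clustered with fuzzy c-means (fuzzifier `m = 1.25`);
   genes join a pattern only at membership ≥ 0.5. The number of patterns is
   the largest `c` whose centroids stay pairwise non-overlapping
   (Pearson r < 0.9), and each pattern is classified by peak position(s),
   direction, and modality.
3. **Pathway coregulation.** Gene signatures (GMT) are scored per sample with
   single-sample enrichment (rank-weighted ECDF difference, weight `r^0.25`);
   signature tracks are Pearson-correlated and *coregulation clusters* are
   groups in which every pairwise correlation is significant (p < 0.05) and
   positive — maximal cliques in the significance graph, extracted greedily
   and disjointly — with per-time-point Mann–Whitney enrichment tests.
4. **Coexpression hubs.** Per pattern, an unsigned weighted network
   `A = |r|^β` (soft power β from scale-free topology fit, fallback 6) yields
   the topological overlap matrix, intramodular connectivity `kWithin`, and
   the module eigengene with membership `kME`; *hubs* are the top 10% most
   connected genes of each pattern (ceiling rule), and hub overlap with
   reference gene lists is compared against random same-size draws.

## Worked example

```python
from tcdyn import (SimulationConfig, generate_timecourse, classify_dynamic,
                   standardize_profiles, select_cluster_number)

cfg = SimulationConfig(n_static=1700, n_dynamic=300, seed=1)
matrix, truth = generate_timecourse(cfg)          # 2000 genes x 18 samples
result = classify_dynamic(matrix)                 # chi2 + fold-change filter
profiles = standardize_profiles(matrix, result.dynamic_ids)
sel = select_cluster_number(profiles, c_range=range(2, 10), seed=1)
print(len(result.dynamic_ids), sel.optimal_c)
```

Running `python examples/01_filter_dynamic_genes.py` prints:

```
genes: 2000, flagged dynamic: 300 (15.0%)
planted dynamic recovered: 300/300
```

— all 300 planted dynamic genes (and no static ones) pass the joint filter —
and `examples/02_cluster_expression_patterns.py` continues:

```
optimal number of non-overlapping patterns: 6
genes assigned at membership >= 0.5: 300/300
minimum membership among assigned genes: 1.000
```

— the six planted temporal templates are recovered as six non-overlapping
patterns, each with its 50 genes. The remaining examples walk the pathway
coregulation stage (`03`) and hub discovery (`04`).

The whole pipeline can also run from the shell:

```bash
tcdyn all --out run1 --seed 1          # simulate -> filter -> cluster -> pathways -> network
tcdyn filter --matrix expr.tsv --design design.tsv --out run2
```

Outputs are plain TSV/JSON per stage plus a manifest (config hash, seed,
timings); the same config and seed reproduce every output byte for byte.

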