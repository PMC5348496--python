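# pairomics

Paired cecum-vs-feces differential abundance for multi-omic gut
microbiome count data.

When the same mice are sampled at two intestinal sites — cecal contents
(CC) and feces (F) — and profiled by 16S surveys, shotgun metagenomics
and shotgun metaproteomics, the question "which taxa, functions and
pathways differ between sites?" is a *paired*, *overdispersed*,
*depth-confounded* count problem with a tiny sample size. `pairomics`
provides the full analysis stack for it:

* a **paired beta-binomial likelihood-ratio test**: for mouse *i* with
  cecal count c_i, pair total t_i and library sizes C_i, F_i,

      c_i | t_i ~ BetaBin(t_i, π_i(r), φ),   π_i(r) = r·C_i / (r·C_i + F_i)

  tests H₀: r = 1 with φ profiled out, LRT referred to χ²₁;
* **SGoF** (sequential goodness of fit) multiple-testing adjustment with
  exact binomial tails — suited to few samples and many tests;
* signed **paired fold-changes** with a correction factor (CF = 2),
  orientation-consistent SEMs, and the missing-value filter that drops
  features absent from their dominant site;
* **NSAF** protein quantification (spectral counts / length, normalized
  per sample, scaled by the dataset-mean spectrum count);
* **LCA taxonomic assignment** from BLAST-tabular hits with min-score /
  top-percent filtering, function×phylum and pathway×phylum count
  aggregation, and the within-phylum renormalization that separates a
  function's own shift from its phylum's;
* **Shannon alpha diversity** (natural log);
* a **synthetic-data generator** with known planted truth (mass-balanced
  fold planting, gamma-latent pairing and genuine conditional
  overdispersion) so the whole pipeline is testable end to end.

See `docs/methods.md` for the model, the generator's design and its
honest small-sample calibration properties.

## Worked example

```python
import pairomics as pm
from pairomics.pipeline import run_differential

cfg = pm.SimConfig(n_pairs=3, n_features=500, frac_differential=0.1,
                   fold_set=(8.0, 0.125), dispersion=0.05,
                   depth_mean=1e5, seed=7)
matrix, truth = pm.simulate_paired_counts(cfg)

rows = run_differential(matrix)           # test -> SGoF -> FC -> filter
declared = rows[rows["declared"]]
print(len(rows), len(declared))           # 500 64
print(int(truth.differential.reindex(declared["feature"]).sum()))  # 49
print(pm.shannon_index(matrix.counts["M1_CC"]))  # 5.699...
```

The top of the declared table (positive block = higher in cecum,
ascending adjusted p):

```
  feature    raw_p   adjusted_p   mean_fc   sem_fc
feat00125 0.000013 1.183209e-29  9.077152 0.110120
feat00194 0.000021 5.348004e-29  5.861076 0.400237
feat00114 0.000021 2.386390e-28  8.441257 0.532236
```

500 function-level features were simulated with 50 planted at an
eightfold shift (half up in cecum, half down). The pipeline declared 64
features, 49 of the 50 planted among them; `mean_fc ≈ 9` is the signed
CF-corrected mean of the three per-mouse cecum/feces ratios for a
feature planted at r = 8 (the correction factor biases magnitudes
upward slightly at these depths), and `adjusted_p` is the exact SGoF
binomial tail at the feature's rank.

The same analysis is available from the shell:

```
pairomics simulate --outdir sim --seed 7
pairomics diff --matrix sim/counts.tsv --design sim/design.tsv --out diff.tsv
pairomics diff --matrix sim/counts.tsv --design sim/design.tsv \
          --normalize-phylum Firmicutes --out diff_firmicutes.tsv
pairomics nsaf --psm sim/psm.tsv --out quant.tsv
pairomics lca --hits sim/hits.tsv --tax sim/taxonomy.tsv --out annotations.tsv
pairomics diversity --matrix sim/counts.tsv --design sim/design.tsv --out shannon.tsv
```

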