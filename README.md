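# coexsurv

Weighted gene co-expression network analysis (WGCNA) with survival
association, built for tumour transcriptome cohorts such as stage II/III
colon cancer expression studies.

Bulk tumour transcriptomes contain groups of genes — cell cycle, stroma,
immune programs — whose expression rises and falls together across
patients. `coexsurv` extracts these co-expression modules without any prior
gene sets, summarises each module by a single per-patient profile, and asks
whether that profile predicts recurrence-free survival (RFS), both in the
whole cohort and within molecular subtypes defined by MSI, CIMP, BRAF and
KRAS status. It then pinpoints the most connected, most prognostic genes of
each module as candidate biomarkers ("hub genes").

## Method

Starting from a gene-level log2 expression matrix (genes × samples):

1. **Pre-filtering.** Keep the top *n₁* genes by standard deviation
   (default 5000), then the top *n₂* most connected genes (default 3600)
   ranked by whole-network connectivity *k.total*.
2. **Network.** Unsigned soft-thresholded adjacency
   *a₍ᵢⱼ₎ = |cor(xᵢ, xⱼ)|^β*, with β chosen by the scale-free topology
   criterion (R² of the log–log connectivity fit ≥ 0.80; default β = 4).
3. **Topological overlap.** *TOM₍ᵢⱼ₎ = (ℓ₍ᵢⱼ₎ + a₍ᵢⱼ₎) / (min(kᵢ, kⱼ) + 1 −
   a₍ᵢⱼ₎)* with *ℓ₍ᵢⱼ₎ = Σᵤ a₍ᵢᵤ₎a₍ᵤⱼ₎*; modules are cut from the
   average-linkage dendrogram of 1 − TOM by a hybrid procedure (static cut
   at height 0.95, minimum module size 30, then PAM-like adoption of
   leftover genes). Unassigned genes are "grey".
4. **Eigengenes.** Each module eigengene (ME) is the first principal
   component of the module's standardized expression; *kME* is a gene's
   correlation with its module's ME, and *k.in* its within-module
   connectivity.
5. **Survival.** MEs are robustly scaled so their 2.5%/50%/97.5% quantiles
   map to −1/0/+1 and entered as continuous covariates in univariate Cox
   proportional-hazards models of RFS (administratively censored at 5
   years; Efron tie handling). Gene significance is GS = −log10(Cox p);
   Benjamini–Hochberg FDR is applied across each family of tests. Hub
   genes are module members with *k.in* in the module's top 10 and GS > 2.
6. **Subtypes.** Samples are classified into molecular subtypes 1–5 from
   the MSI/CIMP/BRAF/KRAS rule table, and module associations are repeated
   within subtypes that have enough samples (default ≥ 50).

A synthetic-data module generates cohorts with planted modules (latent
factor model), eigengene-driven survival, and rule-consistent subtype
markers, so every stage of the pipeline can be verified against a known
ground truth without any downloads.

## Worked example

```python
import numpy as np
from coexsurv import (simulate_study, pearson_adjacency, tom_dissimilarity,
                      average_linkage, cut_tree_hybrid, module_eigengene,
                      scale_eigengene, associate_modules)

# 500 genes x 200 samples, three planted modules; the first one is
# protective with a true hazard ratio of 0.6 on its scaled eigengene
expr, clin, truth = simulate_study(
    n_genes=500, n_samples=200, module_sizes=(100, 70, 40),
    loading_range=(0.5, 0.9), noise_sd=0.5,
    module_log_hr={"m1": np.log(0.6)}, censor_fraction=0.6, seed=7)

adj = pearson_adjacency(expr, beta=4.0)
diss = tom_dissimilarity(adj)
partition = cut_tree_hybrid(average_linkage(diss), diss,
                            cut_height=0.95, min_size=30)
print(partition.value_counts().to_string())

eig = module_eigengene(expr, partition)
cov = eig.eigengenes.apply(scale_eigengene, axis=1)
table = associate_modules(cov, clin)
print(table[["target", "hr", "ci_low", "ci_high", "p", "fdr"]]
      .round(4).to_string(index=False))
```

Output:

```
module
grey         290
turquoise    100
blue          70
brown         40
   target     hr  ci_low  ci_high      p    fdr
turquoise 0.5822  0.3879   0.8739 0.0090 0.0271
     blue 0.8054  0.5211   1.2448 0.3299 0.3609
    brown 0.8198  0.5354   1.2554 0.3609 0.3609
```

All three planted modules are recovered exactly (the 290 background noise
genes stay grey), and the protective module — relabelled "turquoise" as the
largest module — is estimated at HR 0.58 (95% CI 0.39–0.87), close to the
planted HR of 0.6, while the two null modules are not significant.

The same analysis is available from the shell:

```bash
coexsurv simulate --n-genes 500 --n-samples 200 --modules 3 \
    --protective-module m1 --seed 7 --out-dir sim
coexsurv run --expression sim/expression.tsv --clinical sim/clinical.tsv \
    --out-dir results --beta 4
```

which writes the partition, eigengenes, association tables, hub report,
Newick dendrograms and a JSON summary, each stamped with the config hash
and seed.

## Layout

- `src/coexsurv/expr_io.py` — readers/validators, probe collapsing
  (MaxMean), RFS censoring, variance and connectivity filters
- `src/coexsurv/netbuild.py` — adjacency, soft-threshold scan, TOM,
  connectivity
- `src/coexsurv/moduledetect.py` — UPGMA, hybrid tree cut, eigengenes/kME
- `src/coexsurv/survassoc.py` — Cox fits, scaling, FDR, subtypes, hubs,
  Kaplan–Meier
- `src/coexsurv/enrich.py` — GMT parsing and hypergeometric
  overrepresentation
- `src/coexsurv/synthdata.py` — synthetic cohorts with ground truth
- `src/coexsurv/cli.py` — pipeline orchestration and the `coexsurv`
  console script

See `docs/methods.md` for the statistical details and design choices.
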