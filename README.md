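# modulon

Data-driven regulon discovery from bulk RNA-seq compendia by robust
independent component analysis.

A transcriptional regulatory network (TRN) describes which regulators control
which genes. For most microbes — archaea in particular — only a handful of
regulons are known from binding assays. Given enough public RNA-seq profiles,
the TRN can instead be read off the data: the reference-centered log-TPM
compendium **X** (genes × samples) is factored as

    X ≈ M · A

where the columns of **M** are statistically independent gene-weight
signatures and the rows of **A** are their activities per sample. Each column,
cut at a component-specific threshold, yields an *iModulon*: an independently
modulated gene set that behaves as the data-driven analog of a regulon, with
its **A** row acting as a condition-dependent regulator-activity readout.

The package is for computational biologists assembling expression compendia
for under-characterised organisms: it covers compendium I/O and
reference-condition centering, a restart-robust FastICA decomposition,
exact 1-D k-means thresholding of components, hypergeometric enrichment of
iModulons against curated regulons or GO/KEGG-style gene sets, explained
variance and differential-activity analysis, and a synthetic-compendium
generator with planted ground truth for validating every stage.

## Worked example

```python
from modulon import (
    PipelineConfig, center_to_reference, enrich_against_sets,
    explained_variance, extract_imodulons, flag_single_gene,
    generate_compendium, robust_decompose, score_recovery,
)

# a synthetic 1000-gene compendium: 5 planted modules, 3 projects,
# 10% observation noise, reference structure intact
comp, meta, trn, truth = generate_compendium(
    n_genes=1000, n_modules=5, seed=42, noise_fraction=0.1
)
centered = center_to_reference(comp, meta)

cfg = PipelineConfig(n_runs=10, random_seed=0)
dec = robust_decompose(centered, 5, cfg)
ims = flag_single_gene(extract_imodulons(dec, cfg))

print(f"{dec.n_components} robust components "
      f"({dec.converged_runs}/{dec.n_runs} runs converged)")
print("iModulon sizes:", sorted((im.n_members for im in ims), reverse=True))
print("total explained variance: %.3f" % explained_variance(centered, dec))
print("mean membership F1: %.3f" % score_recovery(ims, truth).attrs["mean_f1"])

enr = enrich_against_sets(ims, trn, list(centered.data.index), cfg)
print(enr.head()[["imodulon_name", "set_name", "overlap",
                  "imodulon_size", "set_size", "q_value", "f1"]])
```

Output:

```
5 robust components (10/10 runs converged)
iModulon sizes: [15, 14, 11, 10, 7]
total explained variance: 0.928
mean membership F1: 0.738
imodulon_name set_name  overlap  imodulon_size  set_size      q_value       f1
        IC_03      R02       15             15        26 2.806896e-25 0.731707
        IC_01      R03       14             14        23 9.757561e-25 0.756757
        IC_02      R05       11             11        19 2.656826e-20 0.733333
        IC_05      R04       10             10        19 2.191881e-18 0.689655
        IC_04      R01        7              7        11 8.492870e-15 0.777778
```

Reading the numbers: all five planted modules come back as robust components
and each is enriched, at vanishing q-values, for exactly its planted regulator
(perfect precision — every iModulon member is a true module gene). The
decomposition explains 92.8% of the centered expression variance. Membership
F1 sits near 0.74 rather than 1.0 because the k = 3 magnitude-threshold rule
deliberately filters out small-weight members — heavy-tailed module weights
always leave some true members just below the cutoff (see
`docs/methods.md`, "iModulon thresholds").

The same pipeline is scriptable from the shell:

```bash
modulon simulate --genes 1000 --modules 5 --seed 42 --out sim/
modulon decompose --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --grid 3,5,8 --seed 0 --out dec/
modulon score --imodulons dec/imodulons.tsv --truth sim/ --out recovery.tsv
modulon activities --activity-matrix dec/A.tsv --metadata sim/metadata.tsv \
    --contrast ref,c1 --project P1 --out contrast.tsv
```

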