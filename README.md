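# paleogen

Synthetic ancient-DNA analysis toolkit: simulates post-mortem deamination
damage in low-coverage sequencing libraries and quantifies how it distorts
downstream population statistics — ancestry proportions (binomial admixture
model), F4 / ABBA-BABA statistics with block-jackknife z-scores, and
projection PCA — and how restricting the analysis to transversion SNPs
mitigates the distortion.

## What it does

- **`paleogen.simulate`** — SNP panels with transition/transversion classes,
  Balding–Nichols population frequencies, admixed diploid genotypes,
  Poisson-depth sequencing observations with fragment-end geometry, and a
  geometric-decay C→T / G→A terminal damage model (double- or single-strand
  chemistry, optional UDG-half terminal retention).
- **`paleogen.genotypes`** — terminal read trimming, random pseudo-haploid
  calling with a base-quality filter, transition masking, sliding-window LD
  pruning, and EIGENSTRAT (`.geno/.snp/.ind`) plus observation-TSV I/O.
- **`paleogen.admixture`** — maximum-likelihood ancestry estimation
  (`n_ij ~ Bin(c, Σ_k q_ik f_kj)`) with monotone EM block updates, multiple
  restarts, hold-out cross-validation, and Hungarian component alignment.
- **`paleogen.fstats`** — F4 (mean of `(a−b)(c−d)`), a paired twin-contrast
  F4, ABBA-BABA D, weighted delete-one block jackknife, and Hudson Fst.
- **`paleogen.pca`** — ±1/0 genotype encoding, reference PCA, and
  least-squares projection of high-missingness samples.
- **`paleogen.pipeline`** — the orchestrated experiment: one cohort sequenced
  under undamaged / damaged / UDG-half protocols, compared on all SNPs vs
  transversions only, reported as JSON/TSV.

## CLI

```sh
paleogen simulate --config cfg.yaml --out sim --seed 1
paleogen call --obs sim.obs.tsv --panel sim --out calls --min-bq 30 --trim-bp 2
paleogen mask --geno calls --out calls_tv
paleogen prune --geno calls_tv --out pruned --window 50 --step 5 --r2 0.2
paleogen admix --geno pruned --K 3 --starts 10 --seed 1 --out fit
paleogen f4 --geno pruned --pops W,Y,X,O --block 100 [--transversions-only]
paleogen pca --ref modern --project ancient --components 10 --out scores.tsv
paleogen experiment --config experiment.yaml --out report_dir --seed 1
```

`experiment` accepts a YAML file whose keys mirror
`paleogen.pipeline.ExperimentConfig` (panel size, population Fst values,
coverage, damage parameters, protocols, fitting options, seeds).

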