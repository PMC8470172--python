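# Example rrgwas pipeline configuration.
#
#   rrgwas simulate examples/config.yaml   # synthetic study population
#   rrgwas run examples/config.yaml        # qc -> pca -> fit -> scan -> report

seed: 17

paths:
  genotypes: rrgwas_out/genotypes       # PLINK prefix (.bed/.bim/.fam)
  pedigree: rrgwas_out/pedigree.csv     # id, sire, dam (0 = unknown)
  phenotypes: rrgwas_out/phenotypes.csv # id, age_months, weight, ...
  out_dir: rrgwas_out

simulate:
  seed: 17
  n_founders: 100
  n_generations: 2
  n_snps: 500
  maf_range: [0.05, 0.5]
  missing_rate: 0.01
  qtns:
    - [0, [16.0, 0.0]]   # SNP index, Legendre coefficients of SNP(t)

qc:
  maf_min: 0.01
  call_rate_min: 0.95
  hwe_p_min: 1.0e-6
  mendel_rate_max: 0.02
  ind_missing_max: 0.10

model:
  order_fixed: 3       # population-mean curve degree
  order_additive: 1    # additive-genetic curve degree
  order_pe: 1          # permanent-environment curve degree
  factors: []          # time-constant fixed factor columns
  covariates: []       # time-constant covariate columns (PCs auto-added)

scan:
  snp_order: null      # default: min(order_fixed, n_distinct_ages - 1)
  method: wald

fdr: 0.05
n_pcs: 2
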