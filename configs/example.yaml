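# Desk-scale end-to-end pipeline configuration.
# Every threshold is config-overridable; the values below are the package
# defaults used throughout the test suite.

seed: 1

stages:
  simulate: true
  match: true
  cis: true
  learn: true
  keyreg: true
  stratify: true

simulate:
  n_genes: 100
  n_samples: 150
  edge_density: 0.04        # P(edge) per upper-triangular gene pair
  cis_fraction: 0.4         # fraction of genes cis-regulated by CNV
  n_cnv_blocks: 10
  beta: 1.0                 # cis CNV effect size
  swap_fraction: 0.05       # CNV-layer sample-label swaps to inject
  n_prognostic: 20
  gamma: 1.0                # log-hazard per SD of prognostic-module score
  censoring_rate: 0.3
  n_signatures: 3
  signature_size: 20
  prognostic_overlap: 0.8
  seed: 1

match:
  fdr: 0.01                 # BH threshold for cis-gene selection
  max_iter: 10

cis:
  fdr: 0.01

learn:
  runs: 50                  # independent structure-search chains
  iters: 2000               # proposals per chain
  threshold: 0.3            # consensus keeps edge frequency strictly above
  exclude_frac: 0.2         # bottom MI fraction dropped from candidates
  max_candidates: 10

keyreg:
  l: 2                      # subnetwork radius for regulator scoring
  alpha: 0.05               # BH-adjusted enrichment cutoff

stratify:
  k: 3
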