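# Demo pipeline configuration: simulate a 100-family cohort, run fine
# mapping against the packaged index-SNP catalog, build both site-specific
# PRSs and fit the full outcome x environment x coding model grid.
#   prs-gxe run --config examples/demo.yaml
outdir: demo_output
seed: 1
simulate: true
sim_overrides:
  n_families: 100
  children_per_family: 3
significance:
  include_nominal: true
outcomes: [TBBMD, LSBMD]
env_terms: [mvpa, calcium, ca_p_ratio]
env_codings: [continuous, binary_median]
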