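id: Q4A
description: Site mean-depth distribution (min/q25/median/q75/max) per transcript,
  weighted by genotype calls
levels:
- raw
- aggr
- aggr_denorm
params: []
render_options:
- name: source
  placeholder: genomic_dim
  default: ensembl
  choices:
    ensembl: dim_genomic_position_ensembl
    refseq: dim_genomic_position_refseq
sort_by: &id001
- gene_symbol
- transcript_id
float_cols:
- dp_min
- dp_q25
- dp_median
- dp_q75
- dp_max
postprocess:
  kind: weighted_quantiles
  group_by: *id001
  value_col: dp
  weight_col: w
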