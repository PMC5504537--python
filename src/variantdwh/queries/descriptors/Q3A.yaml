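id: Q3A
description: Variant-call counts per transcript restricted to one disease population
levels:
- raw
- aggr
- aggr_denorm
params:
- name: omim_id
  type: str
  required: true
render_options:
- name: source
  placeholder: genomic_dim
  default: ensembl
  choices:
    ensembl: dim_genomic_position_ensembl
    refseq: dim_genomic_position_refseq
sort_by:
- gene_symbol
- transcript_id
float_cols: []
postprocess: null
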