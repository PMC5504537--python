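id: Q11
levels:
- raw
postprocess: null
description: Distinct genes containing variants, per sample (exon containment)
params: []
render_options:
- name: source
  placeholder: genomic_dim
  default: ensembl
  choices:
    ensembl: dim_genomic_position_ensembl
    refseq: dim_genomic_position_refseq
sort_by:
- sample_id
float_cols: []
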