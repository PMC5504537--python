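id: Q2B
description: Count and cumulative AF of rare damaging variants per exon
levels:
- raw
- aggr
- aggr_denorm
params:
- name: af_cutoff
  type: float
  default: 0.01
render_options:
- name: source
  placeholder: genomic_dim
  default: ensembl
  choices:
    ensembl: dim_genomic_position_ensembl
    refseq: dim_genomic_position_refseq
- name: damaging_only
  placeholder: damaging_pred
  default: 'yes'
  choices:
    'yes': t.fathmm_damaging = 1
    'no': 1 = 1
sort_by:
- gene_symbol
- transcript_id
- exon_number
float_cols:
- cum_af
postprocess: null
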