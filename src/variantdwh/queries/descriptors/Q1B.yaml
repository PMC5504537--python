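id: Q1B
description: 'Per-variant allele frequency broken down by country (denominator: 2
  x samples in the group, absent variant => AF 0)'
levels:
- raw
- aggr
- aggr_denorm
params: []
render_options: []
sort_by:
- chrom
- pos
- ref
- alt
- country
float_cols:
- af
postprocess: null
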