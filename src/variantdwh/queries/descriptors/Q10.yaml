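id: Q10
levels:
- raw
postprocess: null
description: Variant-call counts per sample for one chromosome
params:
- name: chrom
  type: str
  required: true
render_options: []
sort_by:
- sample_id
float_cols: []
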