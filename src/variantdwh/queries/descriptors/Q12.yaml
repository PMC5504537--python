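id: Q12
levels:
- raw
postprocess: null
description: Variant-call counts per chromosome for one sample
params:
- name: sample_id
  type: int
  required: true
render_options: []
sort_by:
- chrom
float_cols: []
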