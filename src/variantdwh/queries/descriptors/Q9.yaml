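id: Q9
levels:
- raw
postprocess: null
description: Het/hom ratio on chromosome X for one sample
params:
- name: sample_id
  type: int
  required: true
render_options: []
sort_by: []
float_cols:
- het_hom_ratio
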