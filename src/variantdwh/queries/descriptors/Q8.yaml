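id: Q8
levels:
- raw
postprocess: null
description: Calls with alt-read fraction above a cutoff for one sample
params:
- name: sample_id
  type: int
  required: true
- name: ratio_cutoff
  type: float
  default: 0.9
render_options: []
sort_by: []
float_cols: []
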