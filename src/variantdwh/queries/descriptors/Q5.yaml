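id: Q5
levels:
- raw
postprocess: null
description: All variants of one sample in a genomic range
params:
- name: sample_id
  type: int
  required: true
- name: chrom
  type: str
  required: true
- name: start
  type: int
  required: true
- name: end
  type: int
  required: true
render_options: []
sort_by:
- chrom
- pos
- ref
- alt
float_cols: []
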