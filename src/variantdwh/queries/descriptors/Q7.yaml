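id: Q7
levels:
- raw
postprocess: null
description: Distinct variants per chromosome over all samples
params: []
render_options: []
sort_by:
- chrom
float_cols: []
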