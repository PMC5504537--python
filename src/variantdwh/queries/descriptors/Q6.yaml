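id: Q6
levels:
- raw
postprocess: null
description: Genotype-call counts per substitution type over all samples
params: []
render_options:
- name: collapse
  placeholder: subst_expr
  default: 'no'
  choices:
    'no': f.ref || '>' || f.alt
    strand: CASE WHEN f.ref IN ('A','G') THEN (CASE f.ref WHEN 'A' THEN 'T' ELSE 'C'
      END) || '>' || (CASE f.alt WHEN 'A' THEN 'T' WHEN 'C' THEN 'G' WHEN 'G' THEN
      'C' ELSE 'A' END) ELSE f.ref || '>' || f.alt END
sort_by:
- substitution
float_cols: []
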