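SELECT {subst_expr} AS substitution, COUNT(*) AS n
FROM fact f
GROUP BY substitution
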