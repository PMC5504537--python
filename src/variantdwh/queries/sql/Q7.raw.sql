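SELECT chrom, COUNT(*) AS n_variants
FROM (SELECT DISTINCT chrom, pos, ref, alt FROM fact)
GROUP BY chrom
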