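SELECT chrom, COUNT(*) AS n
FROM fact
WHERE sample_id = :sample_id
GROUP BY chrom
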