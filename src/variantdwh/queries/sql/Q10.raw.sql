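SELECT sample_id, COUNT(*) AS n
FROM fact
WHERE chrom = :chrom
GROUP BY sample_id
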