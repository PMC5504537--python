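SELECT COUNT(*) AS n
FROM fact
WHERE sample_id = :sample_id AND dp > 0 AND ad_alt * 1.0 / dp > :ratio_cutoff
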