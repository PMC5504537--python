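SELECT chrom, pos, ref, alt, genotype, dp, ad_alt
FROM fact
WHERE sample_id = :sample_id AND chrom = :chrom AND pos BETWEEN :start AND :end
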