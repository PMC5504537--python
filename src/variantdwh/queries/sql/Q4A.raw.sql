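SELECT e.gene_symbol, e.transcript_id, p.mean_dp AS dp, COUNT(*) AS w
FROM fact f
JOIN dim_variant_predictions p ON p.prediction_fk = f.prediction_fk
JOIN {genomic_dim} e
    ON e.is_canonical = 1 AND e.chrom = f.chrom AND f.pos BETWEEN e.start AND e.end
GROUP BY e.gene_symbol, e.transcript_id, p.mean_dp
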