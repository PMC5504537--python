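SELECT e.gene_symbol, e.transcript_id, a.mean_dp AS dp,
       SUM(a.n_het + a.n_homalt) AS w
FROM fact_agg_counts_dims a
JOIN {genomic_dim} e
    ON e.is_canonical = 1 AND e.chrom = a.chrom AND a.pos BETWEEN e.start AND e.end
GROUP BY e.gene_symbol, e.transcript_id, a.mean_dp
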