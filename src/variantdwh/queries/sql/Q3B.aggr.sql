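SELECT e.gene_symbol, e.transcript_id, e.exon_number,
       SUM(a.n_het + a.n_homalt) AS n_records
FROM fact_agg_counts a
JOIN dim_disease d ON a.disease_fk = d.disease_id
JOIN {genomic_dim} e
    ON e.is_merged = 1 AND e.chrom = a.chrom AND a.pos BETWEEN e.start AND e.end
WHERE d.omim_id = :omim_id
GROUP BY e.gene_symbol, e.transcript_id, e.exon_number
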