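SELECT e.gene_symbol, e.transcript_id, COUNT(*) AS n_records
FROM fact f
JOIN dim_disease d ON f.disease_fk = d.disease_id
JOIN {genomic_dim} e
    ON e.is_canonical = 1 AND e.chrom = f.chrom AND f.pos BETWEEN e.start AND e.end
WHERE d.omim_id = :omim_id
GROUP BY e.gene_symbol, e.transcript_id
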