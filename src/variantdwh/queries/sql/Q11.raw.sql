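SELECT f.sample_id, COUNT(DISTINCT e.gene_symbol) AS n_genes
FROM fact f
JOIN {genomic_dim} e
    ON e.is_merged = 1 AND e.chrom = f.chrom AND f.pos BETWEEN e.start AND e.end
GROUP BY f.sample_id
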