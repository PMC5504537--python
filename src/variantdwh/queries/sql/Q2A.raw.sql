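WITH n_total AS (SELECT SUM(n_samples) AS n_total FROM sample_counts_geo),
totals AS (
    SELECT f.chrom, f.pos, f.ref, f.alt, p.fathmm_damaging AS fathmm_damaging,
           SUM(CASE WHEN f.genotype = 'HET' THEN 1 ELSE 2 END) AS ac
    FROM fact f
    JOIN dim_variant_predictions p ON p.prediction_fk = f.prediction_fk
    GROUP BY f.chrom, f.pos, f.ref, f.alt, p.fathmm_damaging
),
qual AS (
    SELECT t.chrom, t.pos, t.ref, t.alt, t.ac / (2.0 * n.n_total) AS af
    FROM totals t
    CROSS JOIN n_total n
    WHERE {damaging_pred} AND t.ac / (2.0 * n.n_total) < :af_cutoff
)
SELECT e.gene_symbol, e.transcript_id,
       COUNT(*) AS n_variants, SUM(q.af) AS cum_af
FROM qual q
JOIN {genomic_dim} e
    ON e.is_canonical = 1 AND e.chrom = q.chrom AND q.pos BETWEEN e.start AND e.end
GROUP BY e.gene_symbol, e.transcript_id
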