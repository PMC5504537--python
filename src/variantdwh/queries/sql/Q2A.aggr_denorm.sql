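WITH n_total AS (SELECT SUM(n_samples) AS n_total FROM sample_counts_geo),
totals AS (
    SELECT a.chrom, a.pos, a.ref, a.alt,
           MAX(a.fathmm_damaging) AS fathmm_damaging,
           SUM(a.n_het) + 2 * SUM(a.n_homalt) AS ac
    FROM fact_agg_counts_dims a
    GROUP BY a.chrom, a.pos, a.ref, a.alt
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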