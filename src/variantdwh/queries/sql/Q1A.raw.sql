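WITH denom AS (
    SELECT region AS grp, SUM(n_samples) AS n_samples
    FROM sample_counts_geo
    GROUP BY region
),
counts AS (
    SELECT f.chrom, f.pos, f.ref, f.alt, g.region AS grp,
           SUM(CASE WHEN f.genotype = 'HET' THEN 1 ELSE 0 END) AS n_het,
           SUM(CASE WHEN f.genotype = 'HOM_ALT' THEN 1 ELSE 0 END) AS n_homalt
    FROM fact f
    JOIN dim_geography g ON f.geo_fk = g.geo_id
    GROUP BY f.chrom, f.pos, f.ref, f.alt, g.region
),
variants AS (SELECT DISTINCT chrom, pos, ref, alt FROM fact)
SELECT v.chrom, v.pos, v.ref, v.alt, d.grp AS region,
       (COALESCE(c.n_het, 0) + 2.0 * COALESCE(c.n_homalt, 0)) / (2.0 * d.n_samples) AS af
FROM variants v
CROSS JOIN denom d
LEFT JOIN counts c
    ON c.chrom = v.chrom AND c.pos = v.pos
   AND c.ref = v.ref AND c.alt = v.alt AND c.grp = d.grp
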