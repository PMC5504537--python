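SELECT COALESCE(SUM(CASE WHEN genotype = 'HET' THEN 1 ELSE 0 END), 0) AS n_het,
       COALESCE(SUM(CASE WHEN genotype = 'HOM_ALT' THEN 1 ELSE 0 END), 0) AS n_homalt,
       CASE WHEN COALESCE(SUM(CASE WHEN genotype = 'HOM_ALT' THEN 1 ELSE 0 END), 0) > 0
            THEN SUM(CASE WHEN genotype = 'HET' THEN 1 ELSE 0 END) * 1.0
                 / SUM(CASE WHEN genotype = 'HOM_ALT' THEN 1 ELSE 0 END)
       END AS het_hom_ratio
FROM fact
WHERE sample_id = :sample_id AND chrom = 'X'
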