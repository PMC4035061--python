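# Counts-reconstruction plan: rebuilds the 2x2 tables of the published
# D. melanogaster chromosomal-representation survey from its printed list
# sizes and percentages, so the printed odds ratios and exact P-values can
# be recomputed without the original gene lists.
#
# Backgrounds: 15493 annotated genes (whole genome) and the 12150-gene
# expression-chip universe. Comparisons whose reconstruction is fragile to
# percentage rounding carry the printed OR so discrepancies > 0.02 are
# flagged as warnings in the report.

bootstrap:
  R: 10000
  level: 0.95
  seed: 0

counts_comparisons:
  - name: mito_sensitive_x
    focal_label: mito_sensitive
    property_label: X-linked
    n_focal: 1211
    pct_focal: 13.7
    n_background: 12150
    pct_background: 16
    printed_or: 0.82

  - name: core_proteome_x
    focal_label: core_proteome
    property_label: X-linked
    n_focal: 419
    pct_focal: 18.7
    n_background: 15493
    pct_background: 15.5
    printed_or: 1.26

  - name: mito_annotated_x
    focal_label: mito_annotated
    property_label: X-linked
    n_focal: 524
    pct_focal: 15.2
    n_background: 15493
    pct_background: 15.5
    printed_or: 1.01

  - name: mito_sensitive_y_sensitive
    focal_label: mito_sensitive
    property_label: y_sensitive
    n_focal: 1211
    pct_focal: 7.5
    n_background: 12150
    pct_background: 5.8
    printed_or: 1.38

  - name: mito_sensitive_female_fitness
    focal_label: mito_sensitive
    property_label: female_fitness
    n_focal: 1211
    pct_focal: 2.8
    n_background: 12150
    pct_background: 4.1
    printed_or: 0.67

  - name: mito_sensitive_combined_fitness
    focal_label: mito_sensitive
    property_label: combined_fitness
    n_focal: 1211
    pct_focal: 2.6
    n_background: 12150
    pct_background: 3.9
    printed_or: 0.64

  - name: mito_sensitive_antagonistic_fitness
    focal_label: mito_sensitive
    property_label: antagonistic_fitness
    n_focal: 1211
    pct_focal: 8.1
    n_background: 12150
    pct_background: 9.7
    printed_or: 0.83

  - name: mito_sensitive_male_fitness
    focal_label: mito_sensitive
    property_label: male_fitness
    n_focal: 1211
    pct_focal: 8.3
    n_background: 12150
    pct_background: 5.9
    printed_or: 1.52

  - name: testis_in_core_proteome
    focal_label: core_proteome
    property_label: testis_biased
    n_focal: 419
    pct_focal: 7
    n_background: 15493
    pct_background: 16.1
    printed_or: 0.39
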