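seed: 1
n_samples: 379
chrom: chr10
region_start: 12280000
variant_spacing: 2000
index_id: rs12779790
index_maf: 0.2
proxies:
- id: rs11257655
  maf: 0.2
  r2: 0.74
  sign: 1
  ref: C
  alt: T
- id: rs34428576
  maf: 0.2
  r2: 0.71
  sign: 1
  ref: A
  alt: G
- id: proxy_03
  maf: 0.2
  r2: 0.95
  sign: 1
  ref: A
  alt: G
- id: proxy_04
  maf: 0.2
  r2: 0.9
  sign: 1
  ref: A
  alt: G
- id: proxy_05
  maf: 0.2
  r2: 0.87
  sign: 1
  ref: A
  alt: G
- id: proxy_06
  maf: 0.2
  r2: 0.85
  sign: 1
  ref: A
  alt: G
- id: proxy_07
  maf: 0.2
  r2: 0.82
  sign: 1
  ref: A
  alt: G
- id: proxy_08
  maf: 0.2
  r2: 0.8
  sign: 1
  ref: A
  alt: G
- id: proxy_09
  maf: 0.2
  r2: 0.78
  sign: 1
  ref: A
  alt: G
- id: proxy_10
  maf: 0.2
  r2: 0.76
  sign: 1
  ref: A
  alt: G
- id: rs36062557
  maf: 0.2
  r2: 0.38
  sign: 1
  ref: A
  alt: G
- id: low_ld_01
  maf: 0.2
  r2: 0.5
  sign: 1
  ref: A
  alt: G
n_background_variants: 5
background_maf: 0.2
use_exact_counts: true
peak_plan:
- track_id: islet_DNase
  cell_type: islet
  assay_name: DNase
  cover_variants:
  - rs11257655
  - rs34428576
  width: 400
  fmt: narrowPeak
- track_id: islet_FAIRE
  cell_type: islet
  assay_name: FAIRE
  cover_variants:
  - rs11257655
  width: 400
  fmt: bed
- track_id: liver_DNase
  cell_type: liver
  assay_name: DNase
  cover_variants:
  - rs11257655
  width: 400
  fmt: bed
- track_id: islet_H3K4me1
  cell_type: islet
  assay_name: H3K4me1
  cover_variants:
  - rs11257655
  width: 400
  fmt: bed
- track_id: islet_H3K9ac
  cell_type: islet
  assay_name: H3K9ac
  cover_variants:
  - rs11257655
  width: 400
  fmt: bed
- track_id: HepG2_FOXA1
  cell_type: HepG2
  assay_name: FOXA1
  cover_variants:
  - rs11257655
  width: 400
  fmt: bed
- track_id: HepG2_FOXA2
  cell_type: HepG2
  assay_name: FOXA2
  cover_variants:
  - rs11257655
  width: 400
  fmt: bed
- track_id: muscle_DNase
  cell_type: skeletal muscle myotube
  assay_name: DNase
  cover_variants: []
  width: 400
  fmt: bed
motif_variant: rs11257655
luciferase:
  832/13:
    true_ratio: 2.1
    baseline_fold: 4.0
    n_clones: 5
    n_replicates: 2
    well_cv: 0.2
    clone_cv: 0.1
    risk_label: T
    nonrisk_label: C
    orientation: forward
    n_empty_clones: 3
    base_firefly: 1000.0
    base_renilla: 500.0
    haplotype_activities: null
  MIN6:
    true_ratio: 1.4
    baseline_fold: 4.0
    n_clones: 5
    n_replicates: 2
    well_cv: 0.2
    clone_cv: 0.1
    risk_label: T
    nonrisk_label: C
    orientation: forward
    n_empty_clones: 3
    base_firefly: 1000.0
    base_renilla: 500.0
    haplotype_activities: null
  HepG2:
    true_ratio: 1.4
    baseline_fold: 4.0
    n_clones: 5
    n_replicates: 2
    well_cv: 0.2
    clone_cv: 0.1
    risk_label: T
    nonrisk_label: C
    orientation: forward
    n_empty_clones: 3
    base_firefly: 1000.0
    base_renilla: 500.0
    haplotype_activities: null
chip:
  n_per_genotype:
    CT: 3
    CC: 2
  antibodies:
  - FOXA1
  - FOXA2
  site_region: rs11257655_site
  control_region: chr10_control
  site_enrichment:
    FOXA1:
      CT: 7.2
      CC: 1.0
    FOXA2:
      CT: 4.2
      CC: 1.0
  ct_noise_sd: 0.2
  base_ct: 30.0
  sample_base_sd: 0.5
  replicates: 3
  include_input: false
  input_fraction: 0.05
expression:
  gene: CAMK1D
  housekeeping: B2M
  induction: 1.8
  low_label: glucose_3mM
  high_label: glucose_20mM
  n_per_condition: 5
  ct_noise_sd: 0.15
  replicates: 3
  efficiency: 2.0
  gene_intercept: 28.0
  housekeeping_intercept: 22.0
  n_dilution_points: 5
  dilution_factor: 3.0
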