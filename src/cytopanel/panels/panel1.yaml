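panel_id: 1
name: Lymphocyte panel
channels:
- marker: CD8a
  fluorophore: FITC
  detector: CD8a-FITC
- marker: CD4
  fluorophore: PE
  detector: CD4-PE
- marker: CD19
  fluorophore: PE-Cy7
  detector: CD19-PE-Cy7
- marker: CCR4
  fluorophore: APC
  detector: CCR4-APC
- marker: CD45RA
  fluorophore: AF700
  detector: CD45RA-AF700
- marker: TCRgd
  fluorophore: APC-Fire750
  detector: TCRgd-APC-Fire750
- marker: CD45
  fluorophore: PacBlue
  detector: CD45-PacBlue
- marker: Viability
  fluorophore: ZombieAqua
  detector: Viability-ZombieAqua
- marker: CD3
  fluorophore: BV570
  detector: CD3-BV570
- marker: CD25
  fluorophore: BV650
  detector: CD25-BV650
- marker: CD154
  fluorophore: BV711
  detector: CD154-BV711
- marker: CD127
  fluorophore: BV785
  detector: CD127-BV785
gates:
- id: main_cells
  parent: null
  kind: scatter-region
  channels:
  - FSC-A
  - SSC-A
  threshold_source: fixed-value
  polarity: inclusive
  region: main-cells
- id: singlets
  parent: main_cells
  kind: singlet
  channels:
  - FSC-A
  - FSC-H
  threshold_source: fixed-value
  polarity: inclusive
- id: dead
  parent: singlets
  kind: viability-exclusion
  channels:
  - Viability-ZombieAqua
  threshold_source: fixed-value
  polarity: exclusive
- id: cd45_pos
  parent: dead
  kind: threshold-positive
  channels:
  - CD45-PacBlue
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd19_pos
  parent: cd45_pos
  kind: threshold-positive
  channels:
  - CD19-PE-Cy7
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd3_pos
  parent: cd45_pos
  kind: threshold-positive
  channels:
  - CD3-BV570
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd8_pos
  parent: cd3_pos
  kind: threshold-positive
  channels:
  - CD8a-FITC
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd8pos_cd4_neg
  parent: cd8_pos
  kind: threshold-negative
  channels:
  - CD4-PE
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd45ra_pos
  parent: cd8pos_cd4_neg
  kind: threshold-positive
  channels:
  - CD45RA-AF700
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd4_pos
  parent: cd3_pos
  kind: threshold-positive
  channels:
  - CD4-PE
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd4pos_cd8_neg
  parent: cd4_pos
  kind: threshold-negative
  channels:
  - CD8a-FITC
  threshold_source: isotype-quantile
  polarity: inclusive
- id: ccr4_pos
  parent: cd4pos_cd8_neg
  kind: threshold-positive
  channels:
  - CCR4-APC
  threshold_source: isotype-quantile
  polarity: inclusive
- id: treg_cd25_pos
  parent: ccr4_pos
  kind: threshold-positive
  channels:
  - CD25-BV650
  threshold_source: isotype-quantile
  polarity: inclusive
- id: treg_cd127_low
  parent: treg_cd25_pos
  kind: threshold-low
  channels:
  - CD127-BV785
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd8_neg
  parent: cd3_pos
  kind: threshold-negative
  channels:
  - CD8a-FITC
  threshold_source: isotype-quantile
  polarity: inclusive
- id: dn_cd4_neg
  parent: cd8_neg
  kind: threshold-negative
  channels:
  - CD4-PE
  threshold_source: isotype-quantile
  polarity: inclusive
- id: tcrgd_pos
  parent: dn_cd4_neg
  kind: threshold-positive
  channels:
  - TCRgd-APC-Fire750
  threshold_source: isotype-quantile
  polarity: inclusive
populations:
- name: B cells
  path:
  - main_cells
  - singlets
  - dead
  - cd45_pos
  - cd19_pos
  activation_markers:
  - CD25
  - CD154
- name: T cells
  path:
  - main_cells
  - singlets
  - dead
  - cd45_pos
  - cd3_pos
  activation_markers: []
- name: Cytotoxic T cells
  path:
  - main_cells
  - singlets
  - dead
  - cd45_pos
  - cd3_pos
  - cd8_pos
  - cd8pos_cd4_neg
  activation_markers:
  - CD25
  - CD154
- name: Naive cytotoxic T cells
  path:
  - main_cells
  - singlets
  - dead
  - cd45_pos
  - cd3_pos
  - cd8_pos
  - cd8pos_cd4_neg
  - cd45ra_pos
  activation_markers: []
- name: CD4 T cells
  path:
  - main_cells
  - singlets
  - dead
  - cd45_pos
  - cd3_pos
  - cd4_pos
  - cd4pos_cd8_neg
  activation_markers:
  - CD25
  - CD154
- name: Regulatory T cells
  path:
  - main_cells
  - singlets
  - dead
  - cd45_pos
  - cd3_pos
  - cd4_pos
  - cd4pos_cd8_neg
  - ccr4_pos
  - treg_cd25_pos
  - treg_cd127_low
  activation_markers: []
- name: Gamma-delta T cells
  path:
  - main_cells
  - singlets
  - dead
  - cd45_pos
  - cd3_pos
  - cd8_neg
  - dn_cd4_neg
  - tcrgd_pos
  activation_markers: []
activation_markers:
- CD25
- CD154
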