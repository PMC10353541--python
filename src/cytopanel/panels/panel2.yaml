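panel_id: 2
name: Monocyte/DC/NK panel
channels:
- marker: CD56
  fluorophore: FITC
  detector: CD56-FITC
- marker: CD14
  fluorophore: PE
  detector: CD14-PE
- marker: CD19
  fluorophore: PE-Cy7
  detector: CD19-PE-Cy7
- marker: CD123
  fluorophore: APC
  detector: CD123-APC
- marker: CD54
  fluorophore: AF700
  detector: CD54-AF700
- marker: CD20
  fluorophore: APC-Fire750
  detector: CD20-APC-Fire750
- marker: CD45
  fluorophore: PacBlue
  detector: CD45-PacBlue
- marker: Viability
  fluorophore: ZombieAqua
  detector: Viability-ZombieAqua
- marker: CD3
  fluorophore: BV570
  detector: CD3-BV570
- marker: CD69
  fluorophore: BV650
  detector: CD69-BV650
- marker: CD11c
  fluorophore: BV785
  detector: CD11c-BV785
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
- id: mono_scatter
  parent: dead
  kind: scatter-region
  channels:
  - FSC-A
  - SSC-A
  threshold_source: fixed-value
  polarity: inclusive
  region: monocyte
- id: lymph_scatter
  parent: dead
  kind: scatter-region
  channels:
  - FSC-A
  - SSC-A
  threshold_source: fixed-value
  polarity: inclusive
  region: lymphocyte
- id: m_cd45_pos
  parent: mono_scatter
  kind: threshold-positive
  channels:
  - CD45-PacBlue
  threshold_source: isotype-quantile
  polarity: inclusive
- id: m_cd3_neg
  parent: m_cd45_pos
  kind: threshold-negative
  channels:
  - CD3-BV570
  threshold_source: isotype-quantile
  polarity: inclusive
- id: m_cd19_neg
  parent: m_cd3_neg
  kind: threshold-negative
  channels:
  - CD19-PE-Cy7
  threshold_source: isotype-quantile
  polarity: inclusive
- id: m_cd14_pos
  parent: m_cd19_neg
  kind: threshold-positive
  channels:
  - CD14-PE
  threshold_source: isotype-quantile
  polarity: inclusive
- id: l_cd45_pos
  parent: lymph_scatter
  kind: threshold-positive
  channels:
  - CD45-PacBlue
  threshold_source: isotype-quantile
  polarity: inclusive
- id: l_cd3_neg
  parent: l_cd45_pos
  kind: threshold-negative
  channels:
  - CD3-BV570
  threshold_source: isotype-quantile
  polarity: inclusive
- id: l_cd19_neg
  parent: l_cd3_neg
  kind: threshold-negative
  channels:
  - CD19-PE-Cy7
  threshold_source: isotype-quantile
  polarity: inclusive
- id: l_cd14_neg
  parent: l_cd19_neg
  kind: threshold-negative
  channels:
  - CD14-PE
  threshold_source: isotype-quantile
  polarity: inclusive
- id: l_cd20_neg
  parent: l_cd14_neg
  kind: threshold-negative
  channels:
  - CD20-APC-Fire750
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd123_pos
  parent: l_cd20_neg
  kind: threshold-positive
  channels:
  - CD123-APC
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd11c_pos
  parent: l_cd20_neg
  kind: threshold-positive
  channels:
  - CD11c-BV785
  threshold_source: isotype-quantile
  polarity: inclusive
- id: cd56_pos
  parent: l_cd20_neg
  kind: threshold-positive
  channels:
  - CD56-FITC
  threshold_source: isotype-quantile
  polarity: inclusive
- id: l_cd3_pos
  parent: l_cd45_pos
  kind: threshold-positive
  channels:
  - CD3-BV570
  threshold_source: isotype-quantile
  polarity: inclusive
- id: nkt_cd56_pos
  parent: l_cd3_pos
  kind: threshold-positive
  channels:
  - CD56-FITC
  threshold_source: isotype-quantile
  polarity: inclusive
populations:
- name: Monocytes
  path:
  - main_cells
  - singlets
  - dead
  - mono_scatter
  - m_cd45_pos
  - m_cd3_neg
  - m_cd19_neg
  - m_cd14_pos
  activation_markers:
  - CD54
  - CD69
- name: pDCs
  path:
  - main_cells
  - singlets
  - dead
  - lymph_scatter
  - l_cd45_pos
  - l_cd3_neg
  - l_cd19_neg
  - l_cd14_neg
  - l_cd20_neg
  - cd123_pos
  activation_markers:
  - CD54
  - CD69
- name: mDCs
  path:
  - main_cells
  - singlets
  - dead
  - lymph_scatter
  - l_cd45_pos
  - l_cd3_neg
  - l_cd19_neg
  - l_cd14_neg
  - l_cd20_neg
  - cd11c_pos
  activation_markers:
  - CD54
  - CD69
- name: NK cells
  path:
  - main_cells
  - singlets
  - dead
  - lymph_scatter
  - l_cd45_pos
  - l_cd3_neg
  - l_cd19_neg
  - l_cd14_neg
  - l_cd20_neg
  - cd56_pos
  activation_markers:
  - CD54
  - CD69
- name: NK T cells
  path:
  - main_cells
  - singlets
  - dead
  - lymph_scatter
  - l_cd45_pos
  - l_cd3_pos
  - nkt_cd56_pos
  activation_markers: []
activation_markers:
- CD54
- CD69
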