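schema_version: 1
name: wprt_phase2
phase: 2
description: >
  Sequential boost phase: 13 Gy to PTV-P in 5 fractions, planned
  independently of phase 1 with the isocentre at the PTV-P centre.
auxiliary:
  shell_target: PTV-P
  shell_distances_mm: [5, 15, 25, 50]
  shell_thickness_mm: 5.0
  shell_mode: band
  skin_ring_depth_mm: 20.0
  transition_margin_mm: 5.0
constraints:
  - {structure: PTV-P, type: MAX, limit: {percent: 105, of: D_p}}
  - {structure: PTV-P, type: MEAN, limit: {percent: 101, of: D_p}}
  - {structure: Left+right femoral head, type: MAX, limit: {percent: 70, of: D_p}}
  - {structure: PTV-P shell 50 mm, type: MAX, limit: {percent: 50, of: D_p}}
  - {structure: Unspecified tissue, type: MAX, limit: {percent: 105, of: D_p}}
objectives:
  - priority: 1
    structure: PTV-P
    cost: {kind: LTCP, d_p: {percent: 100, of: D_p}, alpha: 0.95}
    goal: {value: 0.5}
  - priority: 2
    structure: PTV-P shell 5 mm
    cost: {kind: MAX}
    goal: {percent: 90, of: D_p}
  - priority: 3
    structure: rectum
    cost: {kind: EUD, k: 16}
    goal: {percent: 70, of: D_p}
  - priority: 4
    structure: bladder
    cost: {kind: EUD, k: 12}
    goal: {percent: 60, of: D_p}
  - priority: 5
    structure: PTV-P shell 15 mm
    cost: {kind: MAX}
    goal: {percent: 50, of: D_p}
  - priority: 5
    structure: PTV-P shell 25 mm
    cost: {kind: MAX}
    goal: {percent: 30, of: D_p}
  - priority: 5
    structure: Skin ring 20 mm
    cost: {kind: MAX}
    goal: {percent: 30, of: D_p}
  - priority: 6
    structure: rectum
    cost: {kind: MEAN}
    goal: {percent: 10, of: D_p}
  - priority: 7
    structure: bladder
    cost: {kind: MEAN}
    goal: {percent: 10, of: D_p}
  - priority: 8
    structure: Left+right femoral head
    cost: {kind: EUD, k: 5}
    goal: {percent: 10, of: D_p}
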