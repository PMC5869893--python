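schema_version: 1
name: wprt_phase1
phase: 1
description: >
  Whole-pelvis phase (simultaneous integrated boost): 60 Gy to PTV-P and
  50 Gy to PTV-LN in 25 fractions.  Hard constraints cap target and
  normal-tissue maxima; prioritized objectives drive target coverage
  (LTCP), then OAR sparing (EUD/mean) and conformity (shell maxima).
auxiliary:
  shell_target: PTV-LN
  shell_distances_mm: [5, 15, 25, 50]
  shell_thickness_mm: 5.0
  shell_mode: band
  skin_ring_depth_mm: 20.0
  transition_margin_mm: 5.0
constraints:
  - {structure: PTV-P, type: MAX, limit: {percent: 105, of: D_high}}
  - {structure: PTV-P, type: MEAN, limit: {percent: 101, of: D_high}}
  - {structure: PTV-LN - PTV-P+5mm, type: MAX, limit: {percent: 105, of: D_low}}
  - {structure: PTV-LN - PTV-P+5mm, type: MEAN, limit: {percent: 101, of: D_low}}
  - {structure: Left+right femoral head, type: MAX, limit: {percent: 70, of: D_high}}
  - {structure: PTV-LN shell 50 mm, type: MAX, limit: {percent: 50, of: D_high}}
  - {structure: Unspecified tissue, type: MAX, limit: {percent: 105, of: D_high}}
objectives:
  - priority: 1
    structure: PTV-P
    cost: {kind: LTCP, d_p: {percent: 100, of: D_high}, alpha: 0.7}
    goal: {value: 0.65}
  - priority: 2
    structure: PTV-LN
    cost: {kind: LTCP, d_p: {percent: 100, of: D_low}, alpha: 0.9}
    goal: {value: 0.5}
  - priority: 3
    structure: PTV-LN shell 5 mm
    cost: {kind: MAX}
    goal: {percent: 90, of: D_low}
  - priority: 4
    structure: rectum
    cost: {kind: EUD, k: 12}
    goal: {percent: 70, of: D_high}
  - priority: 4
    structure: rectum
    cost: {kind: EUD, k: 4}
    goal: {percent: 30, of: D_high}
  - priority: 5
    structure: bladder
    cost: {kind: EUD, k: 4}
    goal: {percent: 30, of: D_high}
  - priority: 6
    structure: PTV-LN shell 15 mm
    cost: {kind: MAX}
    goal: {percent: 60, of: D_low}
  - priority: 6
    structure: PTV-LN shell 25 mm
    cost: {kind: MAX}
    goal: {percent: 40, of: D_low}
  - priority: 7
    structure: bowel_bag
    cost: {kind: EUD, k: 8}
    goal: {percent: 30, of: D_high}
  - priority: 8
    structure: Skin ring 20 mm
    cost: {kind: MAX}
    goal: {percent: 30, of: D_high}
  - priority: 9
    structure: rectum
    cost: {kind: MEAN}
    goal: {percent: 20, of: D_low}
  - priority: 10
    structure: bladder
    cost: {kind: MEAN}
    goal: {percent: 20, of: D_low}
  - priority: 11
    structure: bowel_bag
    cost: {kind: MEAN}
    goal: {percent: 20, of: D_low}
  - priority: 12
    structure: Left+right femoral head
    cost: {kind: EUD, k: 5}
    goal: {percent: 10, of: D_high}
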