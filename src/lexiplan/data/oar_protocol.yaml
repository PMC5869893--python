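schema_version: 1
name: wprt_oar_protocol
description: >
  Clinical organ-at-risk dose constraints for the total summed dose
  (phase 1 plus boost).  D_max is the voxel maximum; V_xGy is the
  relative volume (%) of the organ receiving at least x Gy.
constraints:
  - {structure: rectum, metric: D_max, limit_gy: 78}
  - {structure: rectum, metric: V_gy, dose_gy: 65, limit_pct: 20}
  - {structure: rectum, metric: V_gy, dose_gy: 60, limit_pct: 40}
  - {structure: rectum, metric: V_gy, dose_gy: 55, limit_pct: 45}
  - {structure: rectum, metric: V_gy, dose_gy: 50, limit_pct: 50}
  - {structure: bowel_bag, metric: D_max, limit_gy: 56}
  - {structure: bowel_bag, metric: V_gy, dose_gy: 50, limit_pct: 10}
  - {structure: bowel_bag, metric: V_gy, dose_gy: 45, limit_pct: 15}
  - {structure: bowel_bag, metric: V_gy, dose_gy: 40, limit_pct: 20}
  - {structure: bladder, metric: D_max, limit_gy: 78}
  - {structure: bladder, metric: V_gy, dose_gy: 65, limit_pct: 20}
  - {structure: bladder, metric: V_gy, dose_gy: 55, limit_pct: 40}
  - {structure: bladder, metric: V_gy, dose_gy: 50, limit_pct: 50}
  - {structure: bladder, metric: V_gy, dose_gy: 35, limit_pct: 80}
  - {structure: femoral_heads, metric: D_max, limit_gy: 55}
  - {structure: femoral_heads, metric: V_gy, dose_gy: 45, limit_pct: 5}
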