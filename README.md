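# lexiplan

Automated, wishlist-driven treatment planning for two-phase whole-pelvis
prostate radiotherapy (WPRT), with the dosimetric evaluation and
gamma-QA machinery needed to judge the plans — all runnable end to end
on a packaged synthetic pelvis phantom, no patient data required.

**Who it is for:** medical-physics researchers studying prioritized
(a priori) multi-criteria optimization — the paradigm in which a
planning protocol is written once as a *wishlist* and every plan is
then generated automatically, instead of per-patient objective tweaking.

## The method

A wishlist is an ordered protocol: hard constraints that may never be
violated, plus objectives with strict priorities. The solver applies
the lexicographic ε-constraint method: for priority *k* it solves

    minimize   f_k(D x)
    subject to D x respecting every hard limit,
               f_j(D x) ≤ b_j   for all j < k,
               x ≥ 0

where `x` are beamlet fluence weights, `D` the dose-influence matrix
(20 equi-angular beams of 10 mm beamlets through a water-equivalent
body), and each finished stage is frozen at `b_k` = goal (if reached)
or attained × 1.03 (if missed). A second pass tightens every bound to
its attainable value, making the plan Pareto-consistent with the
priorities. All cost functions are convex:

* `LTCP = (1/m) Σ exp(−α (d_j − D_p))` — target-coverage surrogate,
* `EUD(k) = ((1/m) Σ d_j^k)^(1/k)` — organ sparing with volume effect,
* max and mean dose.

The packaged phase-1 wishlist (60/50 Gy simultaneous integrated boost)
carries 7 hard constraints and priorities 1–12; the boost wishlist
(13 Gy to the prostate PTV) carries 5 and priorities 1–8. Plans are
evaluated with DVH statistics (D2%, D98%, V95%, …), homogeneity index
`HI = (D2% − D98%)/D50%`, conformity indices `CI = V95%/V_PTV` and
`CI50% = V50%/V_PTV`, a 16-row clinical organ-at-risk protocol on the
summed dose (with EQD2-adjusted rectal V70/V55, α/β = 3), and a
3%/3 mm local-dose gamma comparison. See `docs/methods.md` for the
full model description.

## Worked example

```python
import numpy as np
import lexiplan as lp

plan = lp.plan_two_phase(spec=lp.PhantomSpec(seed=0))   # ~20 min, 1 core

ss, summed = plan.structures, plan.summed_dose
for target, rx in (("PTV-P", 73.0), ("PTV-LN", 50.0)):
    v95 = 100 * np.mean(summed[ss[target]] >= 0.95 * rx)
    print(f"{target}: V95% = {v95:.1f}% of {rx:g} Gy")
print("protocol pass:", plan.metrics.protocol_pass)
print(plan.phase1.result.constraint_report[4])
```

prints (phantom seed 0, 4 mm grid, 20 beams):

```
PTV-P: V95% = 100.0% of 73 Gy
PTV-LN: V95% = 98.6% of 50 Gy
protocol pass: True
{'label': 'Left+right femoral head MAX <= 42 Gy', ..., 'value_gy': 42.01, 'ok': True}
```

i.e. the summed plan covers both targets beyond the clinical
V95% ≥ 96% criterion, every organ-at-risk row of the clinical table
passes on the summed dose, and the femoral-head hard limit (70% of
60 Gy) is respected — the prioritized sweep pushed organ sparing until
that bound became active.

The same pipeline is scriptable from the shell:

```bash
lexiplan phantom  --run-dir run0 --seed 0
lexiplan plan     --run-dir run0 --phase 1
lexiplan plan     --run-dir run0 --phase 2
lexiplan evaluate --run-dir run0
lexiplan gamma    --reference run0/phase1/dose.nii.gz \
                  --evaluated run0/phase1/dose.nii.gz --out run0/qa
```

Short narrative scripts in `examples/` cover each capability one at a
time (phantom anatomy, dose-influence matrix, a boost-phase plan, plan
evaluation, gamma QA).

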