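"""Generate the synthetic pelvis phantom and inspect its anatomy.

The phantom is the package's stand-in for a planning CT plus contours:
a concave nodal target (CTV-LN) wrapping around bowel and bladder, the
prostate (CTV-P) abutting the rectum, lateral femoral heads, and PTVs
from a 5 mm setup margin.  The same spec + seed always reproduces the
identical structure set; different seeds jitter the anatomy to emulate
different patients.
"""

from lexiplan import PhantomSpec, default_grid, generate_phantom

spec = PhantomSpec(seed=0)
grid = default_grid(spec, spacing_mm=4.0)
structures = generate_phantom(spec, grid)

print(f"grid: {grid.dims} voxels at {grid.spacing[0]:g} mm")
print(f"{'structure':22s} {'voxels':>8s} {'volume (ml)':>12s}")
for name in structures.names:
    print(f"{name:22s} {int(structures[name].sum()):8d} "
          f"{structures.volume_ml(name):12.1f}")

# the nodal CTV must contain the prostate CTV, PTVs nest the same way
assert not (structures["CTV-P"] & ~structures["CTV-LN"]).any()
assert not (structures["PTV-P"] & ~structures["PTV-LN"]).any()
print("\nnesting invariants hold: CTV-P within CTV-LN, PTV-P within PTV-LN")

out = "scratch_phantom"
structures.save(out)
print(f"wrote one NIfTI mask per structure plus structures.json to ./{out}/")
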