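"""Simulate a VBM cohort with planted disease factors and write it to disk.

The generator produces healthy controls whose gray matter volume declines
smoothly with age (plus a sex offset), and patients who additionally carry a
nonnegative mixture of spatial disease factors: two that add volume and two
that remove it.
"""

from pathlib import Path

import numpy as np

from normfactor import CohortSpec, generate_cohort, write_fixture

spec = CohortSpec(n_controls=60, n_patients=40, grid_shape=(12, 12, 12),
                  mask_fraction=0.5, seed=1)
bundle = generate_cohort(spec)

print(f"masked voxels:       {bundle.space.n_voxels}")
print(f"controls / patients: {spec.n_controls} / {spec.n_patients}")
print(f"planted factors:     {spec.k_pos} positive, {spec.k_neg} negative")
print(f"mean planted loading: {bundle.truth.true_W_pos.mean():.3f} "
      f"(scale {spec.loading_scale})")
print(f"GMV clipped at zero: {100 * bundle.truth.clip_fraction:.4f}% of voxels")

out = Path("scratch_example_cohort")
paths = write_fixture(bundle, out, force=True)
print(f"wrote {len(paths['images'])} NIfTI images, mask and tables to {out}/")
# Each patient's image = normative GMV + W_pos @ H_pos - W_neg @ H_neg + noise.
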