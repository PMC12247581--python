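"""Preprocess a phantom volume and select the five percentile slices.

Mirrors the real-MRI pipeline: isotropic rescale, Otsu background removal +
median filtering + [0,1] scaling, valid-slice detection (>= 1% non-zero
voxels), then the 25/37.5/50/62.5/75th percentile slices of the valid range.
"""

from diffage import (PhantomSpec, VolumeImage, find_valid_slices,
                     generate_phantom, normalize_intensities,
                     select_percentile_slices)

vol = VolumeImage(generate_phantom(12.0, PhantomSpec(), rng_seed=1))
norm = normalize_intensities(vol)
valid = find_valid_slices(norm, min_nonzero_fraction=0.01)
plan = select_percentile_slices(valid)

print(f"valid axial slices: {valid[0]}..{valid[-1]} ({len(valid)} of "
      f"{vol.data.shape[2]})")
for p, idx in zip(plan.percentiles, plan.selected_indices):
    print(f"  {p:5.1f}th percentile -> slice {idx}")

# The five indices spread evenly over the brain's axial extent; each feeds
# one slice-specific regression model.
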