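"""Estimate a resection cavity from pre/post binary volumes.

The estimator closes both binary brain volumes, subtracts post from pre and
opens the difference; with a 1-voxel co-registration jitter rind planted at
the brain surface, the opening strips the rind and recovers the cavity.
"""

from perifocal import (
    PhantomSpec, ResectionSpec, binarize_labels, estimate_resection,
    make_phantom_labels, make_post_volume, volume_mm3,
)

labels = make_phantom_labels(PhantomSpec(seed=0))
pre_bin = binarize_labels(labels)

for jitter in (0, 1):
    post, truth = make_post_volume(labels, ResectionSpec(
        side="left", posterior_extent_mm=40.0, jitter_voxels=jitter,
    ))
    radii = (0, 0) if jitter == 0 else (1, 1)
    est = estimate_resection(pre_bin, binarize_labels(post),
                             close_radius=radii[0], open_radius=radii[1])
    dice = 2 * (est & truth).count / (est.count + truth.count)
    print(f"jitter {jitter} voxel(s), close/open radii {radii}: "
          f"truth {volume_mm3(truth):.0f} mm^3, estimated {volume_mm3(est):.0f} mm^3, "
          f"Dice {dice:.4f}")

print("\nwith no jitter the subtraction recovers the cavity exactly (Dice 1);")
print("the jitter rind inflates the raw difference and the morphological")
print("opening removes it at a small cost in boundary voxels.")
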