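"""Pose-normalize a small set of fundus patches from OD/macula landmarks.

Renders three synthetic OD-region images with different landmark geometry,
mirrors any right eye into a left eye, computes each image's pose (the
angle between the horizontal and the macula-OD axis, and the macula-OD
distance), and maps every image into the population-mean pose.
"""

import numpy as np

import odatlas as od

phantoms = [od.render_phantom(od.PhantomSpec(patch_size=192, seed=s))
            for s in range(3)]
images = [p.patch for p in phantoms]
landmarks = [p.landmarks for p in phantoms]

# perturb one subject's landmarks so the normalization has work to do
landmarks[1] = od.Landmarks(od_center=(92.0, 99.0), macula_center=(186.0, 120.0),
                            image_size=landmarks[1].image_size)

flipped = [od.flip_to_left_eye(i, l) for i, l in zip(images, landmarks)]
poses = [od.compute_pose(l) for _, l, _ in flipped]
stats = od.population_pose_stats(poses, [l.od_center for _, l, _ in flipped])

print(f"population mean pose: distance {stats.mean_distance:.1f} px, "
      f"angle {np.degrees(stats.mean_angle):.2f} deg")
for k, ((img, lm, was_flipped), pose) in enumerate(zip(flipped, poses)):
    patch = od.affine_normalize(img, lm, stats, m=128)
    p = patch.source_affine
    print(f"subject {k}: flipped={was_flipped} scale={p.scale:.3f} "
          f"rotation={np.degrees(p.rotation):+.2f} deg "
          f"padded={patch.pad_mask.mean():.1%} of patch")
# scale 1 / rotation 0 means the subject already sat at the mean pose;
# every patch now has its OD at the same position, size and orientation.
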