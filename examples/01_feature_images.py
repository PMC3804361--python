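"""Feature images of a closed surface.

A closed contour is turned into the pair of images the registration
functional actually matches: the signed distance image (negative inside,
bounded above so far-away structure cannot dominate) and the curvature
image, the Laplacian of the distance image, which on the zero level set
equals the sum of the principal curvatures.  For a circle of radius r the
curvature image near the contour should read 1/r.
"""

import numpy as np

import fealign as fa

# a star-shaped contour in the unit square
spec = fa.ShapeSpec(family="star", radius=0.22, spikes=5, spike_length=0.08,
                    resolution=512)
star = fa.make_shape(spec)
print(f"surface: {len(star.vertices)} vertices, closed={star.is_closed()}")

grid = fa.GridGeometry.unit(2, 129)
dist = fa.signed_distance(star, grid)
print(f"signed distance range: [{dist.values.min():+.4f}, "
      f"{dist.values.max():+.4f}]")

# bounding clips the positive tail only; the inside is untouched
bounded = fa.bound_distance(dist, 0.1)
print(f"bounded at b=0.1:      [{bounded.values.min():+.4f}, "
      f"{bounded.values.max():+.4f}]")

# the gradient of a distance image has unit length away from the skeleton
gx, gy = dist.gradient()
norm = np.hypot(gx.values, gy.values)
band = fa.images.band_mask(dist, 0.05)
print(f"|grad I| in the band:  {norm[band].mean():.4f} (should be ~1)")

# curvature image of a circle: 1/r on the contour
circle = fa.make_shape(fa.ShapeSpec(family="circle", radius=0.3,
                                    resolution=2048))
dist_c = fa.signed_distance(circle, grid)
curv = fa.mean_curvature_image(dist_c)
near = np.abs(dist_c.values) < grid.spacing[0]
print(f"curvature near circle: {curv.values[near].mean():.3f} "
      f"(analytic 1/r = {1 / 0.3:.3f})")
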