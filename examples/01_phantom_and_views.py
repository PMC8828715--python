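"""Generate a textured tumour phantom and build its 2.5D representation.

The phantom is an ellipsoid with smooth sinusoidal intra-tumour texture in
a noisy volume; the 2.5D representation is three orthogonal 224x224 views
through the tumour centroid, normalised from [0, 4096] to [0, 255].
"""

from radiofuse import PhantomSpec, extract_views, generate_phantom, roi_centroid

spec = PhantomSpec(grid_shape=(40, 40, 40), semi_axes=(12, 9, 10),
                   texture_scale=80.0)
phantom = generate_phantom(spec, seed=7)

print(f"tumour voxels: {int(phantom.mask.sum())}")
print(f"physical centroid (mm): "
      f"{tuple(round(c, 2) for c in roi_centroid(phantom))}")

views = extract_views(phantom)
for name, v in zip(("axial", "sagittal", "coronal"), views.as_tuple()):
    print(f"{name:9s} view {v.shape}, intensity range "
          f"[{v.min():.1f}, {v.max():.1f}]")
# Each view is a 224x224 grayscale image of the tumour cross-section;
# values are the CT-like intensities linearly rescaled to [0, 255].
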