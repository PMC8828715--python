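"""Extract a deep feature block from the 2.5D views.

A ViewExtractor maps each 224x224 view to a fixed-width vector (default
2048); concatenating the axial, sagittal and coronal outputs gives the
6144-dimensional per-patient block.  The built-in extractor is a seeded
convolutional filter bank (edge/blob kernels plus random projections with
rectification and global average pooling); a pretrained CNN can be
plugged in behind the same contract.
"""

from radiofuse import (PhantomSpec, extract_deep, extract_views,
                       filterbank_standin, generate_phantom)

spec = PhantomSpec(grid_shape=(40, 40, 40), semi_axes=(12, 9, 10),
                   texture_scale=80.0)
phantom = generate_phantom(spec, seed=7)
views = extract_views(phantom)

tl = extract_deep(views, filterbank_standin(seed=1), block="TL")
ft = extract_deep(views, filterbank_standin(seed=2), block="FT")
print(f"TL block: {len(tl)} features, e.g. {tl.names[0]} = {tl.values[0]:.4f}")
print(f"FT block: {len(ft)} features (independent filter bank)")
# The two blocks play the roles of transfer-learned and fine-tuned CNN
# features: same contract, different seeded banks, distinct responses.
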