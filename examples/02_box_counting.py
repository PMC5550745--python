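"""Box-counting fractal dimension and lacunarity on reference patterns.

A straight line is one-dimensional, a filled plane two-dimensional; a
ramified cell outline falls in between (microglia outlines are typically
1.2-1.45).  Lacunarity measures gappiness: a solid disk is more
homogeneous than sparsely scattered dots of equal total mass.
"""

import numpy as np
from skimage import draw

from gliamorph import fractal_dimension, lacunarity, load_presets, render_cell
from gliamorph.synthetic import cell_rng

line = np.zeros((512, 512), bool)
line[256, :] = True
plane = np.ones((512, 512), bool)
cell = render_cell(load_presets()["ramified"], cell_rng(2, 0))

print(f"D(straight line)   = {fractal_dimension(line).value:.3f}   (expected 1)")
print(f"D(filled plane)    = {fractal_dimension(plane).value:.3f}   (expected 2)")
print(f"D(ramified outline)= {fractal_dimension(cell.outline_mask).value:.3f}   (in between)")

rr, cc = np.ogrid[:512, :512]
disk = (rr - 256) ** 2 + (cc - 256) ** 2 <= 80**2
rng = np.random.default_rng(5)
dots = np.zeros((512, 512), bool)
while dots.sum() < disk.sum():
    r, c = rng.integers(20, 492, 2)
    dd, cc2 = draw.disk((r, c), 6, shape=dots.shape)
    dots[dd, cc2] = True
print(f"lacunarity(solid disk)  = {lacunarity(disk):.3f}")
print(f"lacunarity(sparse dots) = {lacunarity(dots):.3f}   (gaps raise heterogeneity)")
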