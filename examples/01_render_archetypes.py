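"""Render one cell per morphological archetype and measure its shape.

The four archetypes emulate the canonical microglial forms: ramified
(surveillant), hypertrophied, bushy and amoeboid (reactive).  The printed
descriptors show the activation gradient: branching complexity (fractal
dimension D), cell perimeter and lacunarity fall from ramified to
amoeboid, while density (solidity) and circularity rise.
"""

from gliamorph import compute_vector, load_presets, render_cell
from gliamorph.synthetic import cell_rng

presets = load_presets()
print(f"{'archetype':14s} {'D':>6s} {'lacun':>6s} {'perim(um)':>10s} {'density':>8s} {'CC':>6s} {'CHSR':>6s}")
for i, (name, spec) in enumerate(presets.items()):
    cell = render_cell(spec, cell_rng(7, i))
    v = compute_vector(cell)
    print(
        f"{name:14s} {v.fractal_dimension:6.3f} {v.lacunarity:6.3f} "
        f"{v.cell_perimeter_um:10.1f} {v.density:8.3f} "
        f"{v.cell_circularity:6.3f} {v.convex_hull_span_ratio:6.2f}"
    )
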