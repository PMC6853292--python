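"""Cast a cycloid grid on one section and count intersections and points.

Reproduces the manual procedure: pick a random section where the nerve is
visible, orient the grid from the basal-lamina trace, count line
intersections (I) with the bundle boundary and test points (P) inside it,
honouring the restriction line across the lamina pore, and form
Ŝ_V = 2I/((l/p)·P).  Writes an audit overlay PNG.
"""

import math

import numpy as np

from nervestereo import Phenotype, build_bundle_scene, voxelize
from nervestereo.estimators import make_section_plane, select_section
from nervestereo.grid import build_grid, count, lamina_orientation
from nervestereo.overlay import save_overlay

scene = build_bundle_scene(Phenotype.PENETRATING, radius=0.64, pore_diameter=1.8, seed=0)
stack = voxelize(scene, (0.01, 0.01, 0.1), lazy=True)

rng = np.random.default_rng(3)
k = select_section(stack, 1, rng)
sp = make_section_plane(stack, k)

vertical = (lamina_orientation(sp) + math.pi / 2) % math.pi
lp = 0.7
phase = (rng.uniform(0, 2 * math.pi * lp / 8), rng.uniform(0, lp / 2))
grid = build_grid(lp, vertical, phase, sp.extent)

tally = count(grid, 1, sp, restricted=sp.pore_endpoints is not None)
sv = 2 * tally.I / (lp * tally.P)
print(f"section {k}: lamina angle {math.degrees(lamina_orientation(sp)):.1f}°, "
      f"grid minor axis at {math.degrees(vertical):.1f}°")
print(f"I = {tally.I} boundary intersections, P = {tally.P} points inside "
      f"({tally.n_arcs_cast} arcs cast, restricted={tally.restricted})")
print(f"single-cast Ŝ_V = {sv:.2f} μm⁻¹ (analytic {scene.phantoms[0].phantom.sv:.2f}; "
      "single casts are noisy — pool several)")

path = save_overlay(sp, grid, 1, "overlay_example.png", tally=tally)
print(f"audit overlay written to {path}")
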