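"""Serial-stack depth topology: recover a V-shaped depth profile.

Generates a 16-section stack (100 um interval) whose nodal minimal
depth dips to 150 um at section 8 — the shape seen where a node comes
closest to the surface mid-series — measures every section, and prints
measured vs. generated depth per section.
"""

from nodalmorph import (
    FlatSurface,
    SectionPhantomSpec,
    make_heart_series,
    measure_section_depth,
)

base = SectionPhantomSpec(
    image_height_px=280,
    image_width_px=220,
    pixel_size_um=4.0,
    surface_shape=FlatSurface(row_um=16.0),
    node_center_depth_um=100.0,
    node_radius_um=60.0,
    seed=5,
)
depth_curve = lambda i: 150.0 + 50.0 * abs(i - 8)
series = make_heart_series(16, 100.0, depth_curve, ["none"] * 16, base)

print("section  axial_um  generated_um  measured_um")
for i, (img, masks, truth) in enumerate(series):
    profile, _ = measure_section_depth(masks, img.pixel_size_um)
    print(
        f"{i:7d}  {img.axial_position_um:8.0f}  {depth_curve(i):12.1f}"
        f"  {profile.min_depth_um:11.1f}"
    )
# Measured minima track the generated V within one pixel per section.
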