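"""Simulate the focused pressure field of the lens in water.

Propagates the six-annulus aperture by the axisymmetric angular-spectrum
method and reports the focal metrics: where the focus forms, how wide and
how long the focal spot is.
"""

from fuskit.field import GridSpec, beam_metrics, propagate_homogeneous
from fuskit.lens import design_lens
from fuskit.media import Medium

lens = design_lens()
water = Medium("water", 1000.0, 1480.0, 0.0)
grid = GridSpec(r_max_mm=0.35, dr_mm=0.003, z_min_mm=2.5, z_max_mm=7.5,
                dz_mm=0.01)

field = propagate_homogeneous(lens.transmit_annuli_mm, water, grid, 20.7e6)
metrics = beam_metrics(field)

print(f"focal length:   {metrics.focal_length_mm:6.2f} mm")
print(f"focal diameter: {metrics.focal_diameter_um:6.0f} um  (lateral -3 dB width)")
print(f"focal depth:    {metrics.focal_depth_um:6.0f} um  (axial -3 dB width)")
print()
print("The masked aperture focuses ~5 mm above the source into a spot about")
print("0.1 mm wide and 0.8 mm long — a needle of high pressure that a scan")
print("plan must sweep through the target volume.")
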