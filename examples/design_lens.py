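"""Design the Fresnel air-cavity lens of the 20.7 MHz treatment transducer.

Builds the half-wavelength-band boundary radii for a 5 mm focus in water,
pairs them into transmitting annuli, and prints the resonance parameters.
"""

from fuskit.lens import design_lens, harmonic_frequency

lens = design_lens(
    focal_length_mm=5.0,
    frequency_hz=20.7e6,
    design_sound_speed_m_s=1465.0,
    n_boundaries=11,
    matching_layer_sound_speed_m_s=2153.0,
)

print(f"design wavelength: {lens.wavelength_mm * 1e3:.2f} um")
print("transmitting regions (inner, outer) in um — the central circle and")
print("every other ring; the gaps are the blocked air-cavity zones:")
for i, (inner, outer) in enumerate(lens.transmit_annuli_um, start=1):
    print(f"  region {i}: {inner:7.1f}  {outer:7.1f}")
print(f"quarter-wave matching layer: {lens.matching_layer_thickness_um:.1f} um")
print(f"9th-harmonic frequency of a 1 mm plate (c = 4600 m/s): "
      f"{harmonic_frequency(1e-3, 9, 4600.0) / 1e6:.1f} MHz")
print()
print("Each boundary sits n half-wavelengths farther from the focus than the")
print("lens centre, so all transmitted zones interfere constructively there.")
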