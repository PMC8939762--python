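"""Estimate tissue acoustic properties from substitution measurements.

Synthesizes the two hydrophone records of a substitution experiment — a
reference path and the same path with a tissue sample inserted — then
recovers the sample's attenuation from the amplitude ratio and its sound
speed from the cross-correlation time-of-flight shift.
"""

import numpy as np

from fuskit.dosimetry import (
    attenuation_from_insertion_loss,
    estimate_delay,
    sound_speed_from_tof,
)

# Ground truth used to synthesize the records (tumor-like tissue).
alpha_true, c_true, d_mm = 0.321, 1521.0, 5.0
alpha_ref, c_ref = 0.110, 1480.0

fs = 400e6
t = np.arange(0, 4e-6, 1 / fs)
reference = np.exp(-((t - 1.5e-6) ** 2) / (2 * (60e-9) ** 2)) * np.sin(
    2 * np.pi * 20.7e6 * t
)
loss = np.exp(-(alpha_true - alpha_ref) * d_mm)
advance_s = d_mm * 1e-3 * (1 / c_ref - 1 / c_true)
shift = int(round(advance_s * fs))
through_sample = loss * np.roll(reference, -shift)

amp_ratio_ref = np.max(np.abs(reference))
amp_ratio_smp = np.max(np.abs(through_sample))
alpha_est = attenuation_from_insertion_loss(
    amp_ratio_ref, amp_ratio_smp, d_mm, alpha_ref
)
dt_est = -estimate_delay(reference, through_sample, fs)
c_est = sound_speed_from_tof(dt_est, d_mm, c_ref)

print(f"attenuation: estimated {alpha_est:.3f} Np/mm (true {alpha_true})")
print(f"sound speed: estimated {c_est:.0f} m/s (true {c_true:.0f})")
print()
print("The sample's extra amplitude loss gives its attenuation; its earlier")
print("arrival (it is faster than the reference medium) gives its sound")
print("speed — the two numbers the layered-tissue simulation needs.")
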