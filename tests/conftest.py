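import numpy as np
import pytest

from fuskit.field import GridSpec, propagate_homogeneous
from fuskit.lens import design_lens
from fuskit.media import Medium

# Boundary radii of the treatment lens as printed on the device datasheet
# (inner, outer of each transmitting region, um).
TABLE_RADII_UM = [595, 843, 1035, 1197, 1340, 1471, 1591, 1704, 1811, 1912, 2009]

FREQ_HZ = 20.7e6


@pytest.fixture(scope="session")
def lens_design():
    return design_lens()


@pytest.fixture(scope="session")
def lossless_water():
    return Medium("water_lossless", 1000.0, 1480.0, 0.0)


@pytest.fixture(scope="session")
def water_field(lens_design, lossless_water):
    """Simulated field of the treatment lens in lossless water."""
    grid = GridSpec(r_max_mm=0.35, dr_mm=0.003, z_min_mm=2.5, z_max_mm=7.5,
                    dz_mm=0.01)
    return propagate_homogeneous(
        lens_design.transmit_annuli_mm, lossless_water, grid, FREQ_HZ
    )


@pytest.fixture(scope="session")
def disc_vs_closed_form(lossless_water):
    """Single-disc ASM field and the matching closed-form on-axis curve."""
    from fuskit.field import on_axis_piston_closed_form

    a_mm = 1.0
    grid = GridSpec(r_max_mm=0.1, dr_mm=0.01, z_min_mm=a_mm, z_max_mm=15.0,
                    dz_mm=0.02)
    fld = propagate_homogeneous([(0.0, a_mm)], lossless_water, grid, FREQ_HZ)
    k = lossless_water.wavenumber_per_mm(FREQ_HZ).real
    closed = on_axis_piston_closed_form(a_mm, k, fld.z_mm)
    return fld, closed, a_mm, k
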