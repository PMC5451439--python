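"""Unit conventions shared across the package.

All lengths are handled internally in millimetres and all times in hours.
Diffusion coefficients are accepted in um^2/h at every public interface
(the unit in which murine glioma estimates are usually quoted) and
converted once, here, to mm^2/h for the solvers.
"""

from __future__ import annotations

#: 1 um^2/h expressed in mm^2/h.
UM2H_TO_MM2H = 1e-6

#: Hours per imaging day.
HOURS_PER_DAY = 24.0

#: Conversion factor from um/h to cm/yr (8760 h/yr divided by 1e4 um/cm).
UMH_TO_CMYR = 8760.0 / 1e4


def day_to_hours(day: float) -> float:
    """Convert days post-implantation to hours post-implantation."""
    return HOURS_PER_DAY * float(day)


def hours_to_day(hours: float) -> float:
    """Inverse of :func:`day_to_hours`."""
    return float(hours) / HOURS_PER_DAY


def um2h_to_mm2h(d_um2_per_h: float) -> float:
    """Convert a diffusion coefficient from um^2/h to mm^2/h."""
    return float(d_um2_per_h) * UM2H_TO_MM2H


def umh_to_cmyr(speed_um_per_h: float) -> float:
    """Convert a front speed from um/h to cm/yr.

    8760 hours per (non-leap) year, 1e4 um per cm: the net factor is 0.876.
    """
    if speed_um_per_h < 0:
        raise ValueError("speed must be non-negative")
    return float(speed_um_per_h) * UMH_TO_CMYR


def cmyr_to_umh(speed_cm_per_yr: float) -> float:
    """Inverse of :func:`umh_to_cmyr`."""
    return float(speed_cm_per_yr) / UMH_TO_CMYR
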