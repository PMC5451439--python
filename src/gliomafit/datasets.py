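"""Published reference estimates for GL261-bearing mice.

Whole-series and per-interval Fisher-KPP parameter estimates (D in um^2/h,
rho in 1/h), the implied front velocities, and the Jaccard-distance fit
errors reported for three GL261 glioma-bearing mice imaged on days 11,
15, 18, 22, and 25 post-implantation, together with the measured
visible-tumour volumes. These serve as reference inputs for report
generation, unit-conversion checks, and plausible parameter ranges for
synthetic phantoms; they are data, not package output.

Each 3D-fit record is (mouse, hypothesis, time_point, D, rho, velocity,
error): ``time_point`` is None for whole-series (Hypothesis 1) fits and
2..5 for the interval ending at imaging session 2..5 (days 15, 18, 22,
25). Hypothesis 1 errors are the time-averaged (mean-mode) Jaccard error;
interval errors are single-day Jaccard distances.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReferenceFit",
    "REFERENCE_FITS_3D",
    "SENSITIVITY_REFERENCE",
    "REFERENCE_VOLUMES_MM3",
    "IMAGING_DAYS",
    "ANISOTROPIC_ETA_UM2H",
]

IMAGING_DAYS = (11, 15, 18, 22, 25)

#: Base diffusivity of the published anisotropic 2D simulation (um^2/h).
ANISOTROPIC_ETA_UM2H = 11120.0


@dataclass(frozen=True)
class ReferenceFit:
    mouse: int
    hypothesis: int
    time_point: int | None  # None: whole series; k: interval ending at session k
    D: float  # um^2/h
    rho: float  # 1/h
    velocity: float  # um/h, as printed
    error: float  # Jaccard-based fit error, as printed


REFERENCE_FITS_3D: tuple[ReferenceFit, ...] = (
    # Mouse 1
    ReferenceFit(1, 1, None, 413.77, 0.0188, 5.5781, 0.4524),
    ReferenceFit(1, 2, 2, 139.24, 0.0182, 3.1838, 0.1196),
    ReferenceFit(1, 2, 3, 839.93, 0.0248, 9.1280, 0.1191),
    ReferenceFit(1, 2, 4, 1047.6, 0.0192, 8.9697, 0.1029),
    ReferenceFit(1, 2, 5, 968.75, 0.0082, 5.6369, 0.0949),
    ReferenceFit(1, 3, 2, 139.24, 0.0182, 3.1838, 0.1196),
    ReferenceFit(1, 3, 3, 233.97, 0.0499, 6.8338, 0.1145),
    ReferenceFit(1, 3, 4, 1156.2, 0.0178, 9.0731, 0.0688),
    ReferenceFit(1, 3, 5, 1305.6, 0.0105, 7.4051, 0.0644),
    # Mouse 2
    ReferenceFit(2, 1, None, 319.22, 0.0167, 4.6178, 0.4528),
    ReferenceFit(2, 2, 2, 558.74, 0.0235, 7.2472, 0.1151),
    ReferenceFit(2, 2, 3, 206.21, 0.0100, 2.8720, 0.1067),
    ReferenceFit(2, 2, 4, 346.35, 0.0055, 2.7604, 0.1042),
    ReferenceFit(2, 2, 5, 886.07, 0.0104, 6.0713, 0.0979),
    ReferenceFit(2, 3, 2, 558.74, 0.0235, 7.2472, 0.1151),
    ReferenceFit(2, 3, 3, 950.79, 0.0051, 4.4041, 0.0846),
    ReferenceFit(2, 3, 4, 77.734, 0.0369, 3.3873, 0.0621),
    ReferenceFit(2, 3, 5, 94.161, 0.0520, 4.4255, 0.0643),
    # Mouse 3 (ventricles unresolvable before day 18: truncated series)
    ReferenceFit(3, 1, None, 651.17, 0.0177, 6.7899, 0.2833),
    ReferenceFit(3, 2, 4, 859.70, 0.0127, 6.6085, 0.1408),
    ReferenceFit(3, 2, 5, 454.29, 0.0236, 6.5487, 0.1364),
    ReferenceFit(3, 3, 4, 859.70, 0.0127, 6.6085, 0.1408),
    ReferenceFit(3, 3, 5, 1552.1, 0.0200, 11.1431, 0.1027),
)

#: Initial-density sensitivity reference (Mouse 1, whole-series fits at
#: assumed starting densities 30/50/70 percent of carrying capacity).
SENSITIVITY_REFERENCE: tuple[tuple[float, ReferenceFit], ...] = (
    (0.3, ReferenceFit(1, 1, None, 316.43, 0.0226, 5.3484, 0.4510)),
    (0.5, ReferenceFit(1, 1, None, 413.77, 0.0188, 5.5781, 0.4524)),
    (0.7, ReferenceFit(1, 1, None, 441.52, 0.0168, 5.4476, 0.4592)),
)

#: Measured visible-tumour volumes (mm^3) per mouse and imaging day.
REFERENCE_VOLUMES_MM3: dict[int, tuple[float, ...]] = {
    1: (0.715, 1.155, 4.980, 15.570, 25.460),
    2: (0.595, 3.025, 4.320, 8.095, 12.340),
    3: (0.970, 3.855, 16.485, 30.675, 61.490),
}
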