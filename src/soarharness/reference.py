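"""Published reference values from the original harness-comparison field study.

The coefficient tables printed in the original study of backpack- vs
leg-loop-tagged soaring raptors serve as inputs for the derived headline
quantities (net species-specific climb-rate effect, percent height change,
glide-ratio gain) and as cross-checks for a re-analysis of the deposited
data. Reference level of the contrasts: backpack harness, black kite.
"""

from __future__ import annotations

#: soaring vertical-speed model, fixed-effect estimates (m/s)
SOARING_VSPEED_ESTIMATES = {
    "intercept": 0.39,
    "leg_loop": -0.29,
    "leg_loop_x_tawny_eagle": 0.02,
    "leg_loop_x_griffon_vulture": 0.51,
    "leg_loop_x_himalayan_vulture": 0.39,
    "leg_loop_x_ruppells_vulture": 0.65,
}

#: gliding vertical-speed model (interaction excluded), m/s
GLIDING_VSPEED_ESTIMATES = {"intercept": -0.99, "leg_loop": 0.15}

#: square-root glide-ratio model (interaction excluded)
GLIDE_RATIO_SQRT_ESTIMATES = {"intercept": 3.35, "leg_loop": 0.16}

#: log maximum-height model (interaction excluded)
LOG_MAX_HEIGHT_ESTIMATES = {"intercept": 5.28, "leg_loop": 0.23}

#: log mean-VeDBA model (interaction excluded)
LOG_VEDBA_ESTIMATES = {"intercept": -1.78, "leg_loop": -0.09}

#: device cases: front width x case height (cm); both cases sit on a plate
DEVICE_CASES_CM = {
    "gps_acc_combo": {"width": 4.0, "height": 2.2},   # separate GPS + ACC units, shared case
    "integrated": {"width": 2.6, "height": 1.3},      # single-unit logger
}
PLATE_HEIGHT_CM = 0.3


def frontal_area_cm2(width_cm: float, case_height_cm: float,
                     plate_height_cm: float = PLATE_HEIGHT_CM) -> float:
    """Front cross-sectional area of a device case mounted on its plate.

    The case presents a rectangle of ``width x (case height + plate
    height)`` to the airflow; this area, relative to the bird's body
    cross-section, indexes the drag burden of the tag.
    """
    return float(width_cm * (case_height_cm + plate_height_cm))
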