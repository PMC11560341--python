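"""Published reference values for the adult rat sciatic nerve cohort.

Per-nerve Raghavan–Vorp material parameters (MPa) estimated from ex vivo
uniaxial stretch tests on seven Sprague–Dawley sciatic nerves, together
with the cohort geometry and dose–response summaries. These serve as
inputs for regenerating realistic synthetic cohorts and as anchors for
validation.
"""

from __future__ import annotations

#: (label, sex, alpha MPa, beta MPa) per nerve; cohort averages 0.183 / 1.88.
REFERENCE_FITS: tuple[tuple[str, str, float, float], ...] = (
    ("Female 1", "female", 0.202, 2.04),
    ("Female 2", "female", 0.305, 3.40),
    ("Female 3", "female", 0.060, 0.78),
    ("Female 4", "female", 0.203, 1.09),
    ("Male 1", "male", 0.310, 1.54),
    ("Male 2", "male", 0.037, 2.59),
    ("Male 4", "male", 0.161, 1.74),
)

#: Cohort geometry: mean (range) of diameter and suture-to-suture length, mm.
DIAMETER_MM = 1.42
DIAMETER_RANGE_MM = (1.30, 1.53)
LENGTH_MM = 28.8
LENGTH_RANGE_MM = (24.7, 35.2)

#: Stretch at 50% CAP amplitude reduction: cohort 95% CI mean +/- half width.
LAMBDA50_MEAN = 1.108
LAMBDA50_CI_HALF_WIDTH = 0.026
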