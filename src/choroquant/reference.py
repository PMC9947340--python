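"""Published summary statistics of the reference clinical cohort.

Twenty-four healthy adults imaged with swept-source OCT under paired
dark/light adaptation in control and acute-hyperglycemia (75 g oral glucose)
sessions.  Values are cohort means ± standard errors over the 0–6 mm macular
region, used here as fixed inputs for internal-consistency checks and for
calibrating the cohort-level simulator; they are not outputs of this package.
"""

from types import MappingProxyType

N_SUBJECTS = 24

# baseline choroidal parameters, control vs hyperglycemia session (mean, SE)
BASELINE = MappingProxyType({
    "control": MappingProxyType({
        "LV_mm3": (15.34, 0.72),
        "SV_mm3": (10.74, 0.50),
        "TCV_mm3": (26.08, 1.21),
        "CVI_pct": (58.77, 0.27),
    }),
    "hyperglycemia": MappingProxyType({
        "LV_mm3": (15.32, 0.66),
        "SV_mm3": (10.72, 0.46),
        "TCV_mm3": (26.04, 1.11),
        "CVI_pct": (58.81, 0.28),
    }),
})

# cohort covariates (mean, sd-like spread as printed)
AGE_YEARS = (25.29, 1.91)
AXIAL_LENGTH_MM = (25.47, 1.16)

# blood glucose around the oral glucose tolerance test, mmol/L (mean, spread)
GLUCOSE_PRE_MMOL_L = (5.03, 0.34)
GLUCOSE_POST_MMOL_L = (7.70, 1.48)
GLUCOSE_CHANGE_MMOL_L = (2.67, 1.49)

# condition contrasts (glucose − control) of parameter change from baseline,
# 0–6 mm region: (timepoint, parameter) -> (mean difference, SE)
CONTRAST_TABLE = MappingProxyType({
    ("dark", "TCV"): (-0.07, 0.15),
    ("light_30s", "TCV"): (0.18, 0.14),
    ("light_2min", "TCV"): (0.25, 0.17),
    ("light_5min", "TCV"): (0.38, 0.17),
    ("dark", "LV"): (-0.13, 0.08),
    ("light_30s", "LV"): (0.12, 0.08),
    ("light_2min", "LV"): (0.20, 0.10),
    ("light_5min", "LV"): (0.27, 0.10),
    ("dark", "SV"): (0.06, 0.08),
    ("light_30s", "SV"): (0.06, 0.08),
    ("light_2min", "SV"): (0.05, 0.08),
    ("light_5min", "SV"): (0.11, 0.08),
    ("dark", "CVI"): (-0.36, 0.09),
    ("light_30s", "CVI"): (-0.09, 0.33),
    ("light_2min", "CVI"): (-0.14, 0.33),
    ("light_5min", "CVI"): (-0.11, 0.33),
})

DARK_CVI_EFFECT_PCT = CONTRAST_TABLE[("dark", "CVI")][0]
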