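"""Published factor tables for six Tibetan–Himalayan alpine endemics.

These are the per-variable sensitivity, exposure and vulnerability
factors, the total indicators, and the vulnerability-class area shares
from a published climate-niche vulnerability assessment of six alpine
endemic herbaceous plants of the Tibetan–Himalayan region, under the
moderate (SSP2-4.5) and high (SSP5-8.5) emission pathways.  They serve
as validation inputs: the package's aggregation operations must
reproduce the printed totals from the printed per-variable factors.

Values are printed to 2–3 decimals; tolerances in validation must allow
for that input rounding.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = [
    "VARIABLES",
    "SCENARIOS",
    "RED_LIST",
    "load_factors",
    "load_totals",
    "load_class_shares",
]

VARIABLES = ["MDR", "ISO", "MTWQ", "PS", "PWQ", "PCQ"]
SCENARIOS = ["SSP2-4.5", "SSP5-8.5"]

RED_LIST = {
    "S. kawaguchii": "NT",
    "A. erecta": "NT",
    "C. microphyllus": "NT",
    "S. purpurea": "LC",
    "I. younghusbandii": "LC",
    "A. xylorhiza": "LC",
}

# species, variable, sensitivity, exposure and vulnerability factors per scenario
_FACTORS = """\
species,variable,s,d_ssp245,d_ssp585,v_ssp245,v_ssp585
S. kawaguchii,MDR,13.58,0.22,0.31,4.07,4.22
S. kawaguchii,ISO,11.19,0.14,0.17,3.57,3.62
S. kawaguchii,MTWQ,6.08,0.30,0.44,2.81,2.96
S. kawaguchii,PS,4.44,0.05,0.08,2.16,2.19
S. kawaguchii,PWQ,30.62,0.09,0.16,5.78,5.96
S. kawaguchii,PCQ,7.13,0.01,0.01,2.68,2.69
A. erecta,MDR,4.35,0.13,0.19,2.22,2.28
A. erecta,ISO,3.06,0.09,0.14,1.83,1.87
A. erecta,MTWQ,11.89,0.30,0.44,3.93,4.14
A. erecta,PS,8.88,0.06,0.09,3.07,3.11
A. erecta,PWQ,14.50,0.07,0.10,3.93,3.99
A. erecta,PCQ,7.23,0.02,0.03,2.71,2.72
C. microphyllus,MDR,4.13,0.20,0.28,2.23,2.30
C. microphyllus,ISO,3.50,0.19,0.27,2.04,2.11
C. microphyllus,MTWQ,4.24,0.28,0.42,2.33,2.45
C. microphyllus,PS,6.54,0.14,0.21,2.74,2.81
C. microphyllus,PWQ,9.22,0.13,0.19,3.23,3.32
C. microphyllus,PCQ,2.66,0.04,0.04,1.67,1.66
S. purpurea,MDR,5.41,0.23,0.33,2.58,2.68
S. purpurea,ISO,4.82,0.24,0.33,2.44,2.53
S. purpurea,MTWQ,5.15,0.33,0.48,2.62,2.76
S. purpurea,PS,3.97,0.12,0.17,2.11,2.16
S. purpurea,PWQ,8.70,0.09,0.14,3.09,3.15
S. purpurea,PCQ,6.55,0.01,0.02,2.58,2.58
I. younghusbandii,MDR,3.17,0.26,0.37,2.00,2.09
I. younghusbandii,ISO,5.32,0.26,0.34,2.59,2.67
I. younghusbandii,MTWQ,6.15,0.32,0.47,2.85,3.00
I. younghusbandii,PS,4.94,0.14,0.21,2.37,2.45
I. younghusbandii,PWQ,14.75,0.12,0.18,4.06,4.17
I. younghusbandii,PCQ,2.30,0.02,0.02,1.53,1.53
A. xylorhiza,MDR,3.30,0.21,0.30,2.00,2.07
A. xylorhiza,ISO,2.74,0.19,0.25,1.81,1.85
A. xylorhiza,MTWQ,3.78,0.29,0.43,2.21,2.32
A. xylorhiza,PS,2.28,0.10,0.15,1.58,1.62
A. xylorhiza,PWQ,3.91,0.12,0.18,2.09,2.15
A. xylorhiza,PCQ,1.93,0.02,0.03,1.41,1.41
"""

# total indicators; vulnerability totals are the study's normalized values
_TOTALS = """\
species,marginality,sensitivity,exposure_ssp245,exposure_ssp585,vulnerability_ssp245,vulnerability_ssp585
S. kawaguchii,1.241,3.489,0.409,0.593,0.787,0.806
A. erecta,0.667,2.884,0.350,0.520,0.700,0.716
C. microphyllus,3.148,2.247,0.441,0.638,0.598,0.614
S. purpurea,1.033,2.402,0.492,0.707,0.642,0.659
I. younghusbandii,1.810,2.470,0.523,0.741,0.632,0.651
A. xylorhiza,1.919,1.730,0.437,0.626,0.446,0.459
"""

# vulnerability-class area shares (% of range) with protected shares in _pa
_CLASS_SHARES = """\
species,scenario,low,low_pa,medium,medium_pa,high,high_pa,pa_total
S. kawaguchii,SSP2-4.5,17.6,0.89,54.3,4.41,28.1,3.25,8.55
S. kawaguchii,SSP5-8.5,14.8,0.81,56.9,4.54,28.3,3.20,8.55
A. erecta,SSP2-4.5,48.7,4.70,48.2,7.11,3.1,0.67,12.48
A. erecta,SSP5-8.5,38.6,3.57,57.8,8.16,3.6,0.75,12.48
C. microphyllus,SSP2-4.5,26.6,8.59,43.5,10.71,29.9,5.72,25.02
C. microphyllus,SSP5-8.5,22.1,8.11,48.1,11.26,29.8,5.65,25.02
S. purpurea,SSP2-4.5,40.9,4.42,33.8,6.08,25.3,5.02,15.52
S. purpurea,SSP5-8.5,38.7,4.28,36.1,6.11,25.2,5.13,15.52
I. younghusbandii,SSP2-4.5,7.5,1.10,48.9,8.24,43.6,6.95,16.29
I. younghusbandii,SSP5-8.5,8.3,0.90,48.9,8.82,42.8,6.57,16.29
A. xylorhiza,SSP2-4.5,91.5,17.80,8.1,1.42,0.4,0.01,19.23
A. xylorhiza,SSP5-8.5,91.5,17.75,8.4,1.48,0.1,0.00,19.23
"""


def load_factors() -> pd.DataFrame:
    """Per-variable factors: one row per species x variable."""
    return pd.read_csv(StringIO(_FACTORS))


def load_totals() -> pd.DataFrame:
    """Total indicators per species (vulnerability totals normalized)."""
    return pd.read_csv(StringIO(_TOTALS))


def load_class_shares() -> pd.DataFrame:
    """Vulnerability-class area shares and protected shares per species."""
    return pd.read_csv(StringIO(_CLASS_SHARES))
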