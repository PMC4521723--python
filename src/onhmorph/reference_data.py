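"""Published summary measurements from the longitudinal non-human-primate
experimental-glaucoma study that this package's analyses are modelled on.

The raw images of that study were never deposited, so these printed
summary tables are the only machine-readable record of its measurements.
They serve two purposes here: as inputs to the summary-arithmetic routines
(inter-eye agreement, repeatability coefficients, onset ranking) and as
the calibration targets for the synthetic-data generator's defaults.

Units: ALCSD and MRW in μm, RoC in mm, RNFLT in μm, IOP in mmHg,
cumulative IOP difference in mmHg·days, onset days in days post-laser.
Empty cells mean the quantity was not measurable for that eye.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "normal_fellow_onh",
    "iop_summary",
    "control_repeatability",
    "eg_parameter_summary",
    "onset_days",
]

# ONH parameters in fellow eyes of 6 bilaterally normal animals
# (per-eye means; OD = right eye, OS = left eye).
_NORMAL_FELLOW = """\
animal,alcsd_od,alcsd_os,roc_od,roc_os,mrw_od,mrw_os
M066,191.6,202.4,3.4,4.1,281.8,284.5
M067,175.5,193.2,4.2,3.3,242.8,238.4
M070,177.8,195.2,3.0,3.0,232.7,222.0
M071,202.0,206.4,3.6,2.7,249.9,257.1
M072,199.3,190.0,3.7,3.1,299.1,301.3
M088,206.6,206.1,4.0,3.9,283.7,263.8
"""

# IOP history of the 7 unilaterally lasered animals.
_IOP = """\
animal,age_yr,mean_iop_ctl,sd_iop_ctl,mean_iop_eg,sd_iop_eg,max_iop_ctl,max_iop_eg,reduced_iop_eg,cumulative_iop_diff
OHT-63,3.9,14.1,1.1,24.1,12.1,16,49,18.4,3880
OHT-64,4.2,14.5,2.1,25.5,12.7,21,47,18.3,5280
OHT-65,3.0,10.6,2.6,25.4,14.6,17,51,17.2,8720
OHT-66,3.2,14.5,2.0,33.3,15.5,19,60,18.2,9824
OHT-67,3.3,12.7,2.6,26.8,12.4,18,51,18.1,10441
OHT-68,3.9,13.1,2.5,25.9,9.9,17,45,20.0,6461
OHT-69,4.2,13.2,1.7,34.5,11.3,17,50,24.7,8975
"""

# Control-eye parameter stability across all study visits (mean ± SD).
# OHT-65's control eye could not be quantified for ONH parameters.
_CONTROL_REPEAT = """\
animal,rnflt_mean,rnflt_sd,alcsd_mean,alcsd_sd,roc_mean,roc_sd,mrw_mean,mrw_sd
OHT-63,101.9,1.3,225.9,14.5,3.9,1.1,299.7,5.8
OHT-64,104.0,1.5,215.1,3.9,5.1,0.9,252.1,5.3
OHT-65,106.8,1.9,,,,,,
OHT-66,97.3,1.9,184.5,5.9,2.6,0.3,297.3,6.5
OHT-67,111.8,2.0,237.8,14.3,2.7,0.8,398.2,13.5
OHT-68,100.5,2.0,238.7,9.5,3.0,0.5,259.7,6.1
OHT-69,116.9,1.8,182.1,10.5,4.3,1.0,345.4,6.2
"""

# EG-eye parameter summaries across all study visits, plus per-eye extrema
# (maximum for ALCSD, minima for the parameters that decrease).
_EG_SUMMARY = """\
animal,rnflt_mean,rnflt_sd,rnflt_min,alcsd_mean,alcsd_sd,alcsd_max,roc_mean,roc_sd,roc_min,mrw_mean,mrw_sd,mrw_min
OHT-63,102.4,4.8,92,293.5,66.4,409.6,3.1,1.2,1.3,252.6,47.0,156.9
OHT-64,100.3,10.1,78,348.3,121.0,494.5,2.8,1.5,1.5,188.7,61.1,106.1
OHT-65,78.8,18.7,57,296.6,94.2,460.7,2.6,1.4,1.1,208.6,96.5,105.2
OHT-66,75.5,15.9,46,340.2,102.9,454.6,2.2,1.1,1.2,162.2,94.2,44.2
OHT-67,109.2,6.5,101,295.5,66.1,385.7,2.8,0.9,1.2,306.4,67.2,207.5
OHT-68,69.8,29.3,20,385.1,69.1,475.0,1.9,0.6,1.1,196.9,56.5,104.8
OHT-69,106.5,9.4,98,337.6,64.4,456.7,2.6,1.2,1.4,256.8,74.6,155.1
"""

# Days post-laser of the first sustained change per parameter and eye;
# empty cells = no sustained change during the study (censored).
_ONSET_DAYS = """\
animal,alcsd,mrw,pores,roc,rnflt
OHT-63,343,238,357,343,378
OHT-64,238,238,238,351,365
OHT-65,231,231,231,316,246
OHT-66,49,168,168,130,182
OHT-67,21,504,,,637
OHT-68,14,14,42,224,203
OHT-69,18,18,84,84,84
"""


def _read(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text))


def normal_fellow_onh() -> pd.DataFrame:
    """Fellow-eye ONH parameters of the 6 bilaterally normal animals."""
    return _read(_NORMAL_FELLOW)


def iop_summary() -> pd.DataFrame:
    """Per-animal IOP history and cumulative IOP difference."""
    return _read(_IOP)


def control_repeatability() -> pd.DataFrame:
    """Control-eye per-parameter mean and SD across all visits."""
    return _read(_CONTROL_REPEAT)


def eg_parameter_summary() -> pd.DataFrame:
    """EG-eye per-parameter mean, SD and extremum across all visits."""
    return _read(_EG_SUMMARY)


def onset_days() -> pd.DataFrame:
    """First-change onset days per eye and parameter (NaN = censored)."""
    return _read(_ONSET_DAYS)
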