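"""Bundled benchmark data from the 20-case surgical-planning cohort.

The package ships two small tables from the clinical study the method was
developed on: the per-case maximum absolute geometric errors of the three
generation methods, and the follow-up record used for overall-survival
estimation.  They let the statistics layer be exercised against known
printed summaries without access to the imaging data itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["load_followup", "load_max_abs_errors"]

# months from surgery to death or last follow-up; deaths at 17 and 50 months
_FOLLOWUP_MONTHS = [86, 17, 65, 62, 62, 61, 58, 54, 50, 47,
                    43, 35, 31, 31, 28, 26, 25, 25, 20, 20]
_DIED = [False, True, False, False, False, False, False, False, True, False,
         False, False, False, False, False, False, False, False, False, False]

# per-case maximum absolute geometric error (mm) of each generation method
_MAX_ABS_ERRORS = {
    "dilation": [
        1.2445, 1.5455, 0.7533, 0.9155, 0.7331, 1.3451, 2.5997, 0.8972,
        1.4217, 0.8553, 13.2932, 0.5356, 1.2072, 0.6052, 2.5455, 1.1414,
        0.7435, 10.0286, 20.6174, 8.4768,
    ],
    "distance_transform": [
        1.1513, 1.5259, 1.2342, 1.1702, 1.6167, 1.3451, 1.4409, 1.0667,
        1.2657, 1.2658, 0.8781, 1.2321, 1.2072, 1.1911, 1.4968, 1.5379,
        1.5801, 2.2835, 1.5924, 2.0593,
    ],
    "proposed": [
        0.1776, 0.1957, 0.1835, 0.1837, 0.1819, 0.1777, 0.1777, 0.1831,
        0.1963, 0.1871, 0.1766, 0.1776, 0.1768, 0.1513, 0.1818, 0.1846,
        0.1888, 0.1761, 0.1778, 0.2000,
    ],
}


def load_followup() -> pd.DataFrame:
    """Follow-up cohort: ``months`` to death/last contact and ``event`` flag."""
    return pd.DataFrame(
        {"months": np.array(_FOLLOWUP_MONTHS, dtype=float),
         "event": np.array(_DIED, dtype=bool)}
    )


def load_max_abs_errors() -> pd.DataFrame:
    """Per-case maximum absolute geometric errors (mm) of the three methods."""
    return pd.DataFrame({k: np.array(v) for k, v in _MAX_ABS_ERRORS.items()})
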