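"""Published mariculture-efficiency summaries for China's coastal provinces.

Reported super-SBM efficiency scores and global-Malmquist change rates for
the nine coastal mariculture provinces, 2004-2016 (inputs: farmed area,
workers, vessel tonnage; outputs: yield, production value).  The underlying
yearbook input-output data are not redistributable, so only these score
summaries are carried here.  They anchor the package's reporting
conventions: the efficiency classification rule, per-period ranking, the
EC x BPC decomposition and the cross-province geometric-mean "Overall" row
are all checkable against them without any raw data.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "national_scores",
    "provincial_scores_2016",
    "provincial_change_rates",
    "PROVINCES",
]

PROVINCES = ("Liaoning", "Hebei", "Shandong", "Jiangsu", "Zhejiang",
             "Fujian", "Guangdong", "Guangxi", "Hainan")

# national (all provinces pooled) combined efficiency score per year,
# with the reported efficiency status
_NATIONAL = [
    ("2004", 1.0030, "SBM-efficient"),
    ("2005", 1.0066, "SBM-efficient"),
    ("2006", 1.0956, "SBM-efficient"),
    ("2007", 0.7158, "SBM-inefficient"),
    ("2008", 0.5879, "SBM-inefficient"),
    ("2009", 0.5896, "SBM-inefficient"),
    ("2010", 0.6325, "SBM-inefficient"),
    ("2011", 0.7121, "SBM-inefficient"),
    ("2012", 0.7598, "SBM-inefficient"),
    ("2013", 0.8233, "SBM-inefficient"),
    ("2014", 0.8771, "SBM-inefficient"),
    ("2015", 1.0101, "SBM-efficient"),
    ("2016", 1.0667, "SBM-efficient"),
]

# provincial combined scores and reported ranks for 2016
_PROVINCIAL_2016 = [
    ("Liaoning", 0.58, 8),
    ("Hebei", 0.43, 9),
    ("Shandong", 1.06, 6),
    ("Jiangsu", 1.09, 5),
    ("Zhejiang", 0.60, 7),
    ("Fujian", 1.16, 4),
    ("Guangdong", 1.27, 3),
    ("Guangxi", 3.58, 1),
    ("Hainan", 1.30, 2),
]

# per-province geometric-mean change rates 2004-2016 (GMI, EC, BPC) and the
# reported cross-province Overall row
_CHANGE_RATES = [
    ("Liaoning", 1.0605, 0.9562, 1.1090),
    ("Hebei", 1.0534, 0.9799, 1.0750),
    ("Shandong", 1.0834, 1.0000, 1.0834),
    ("Jiangsu", 1.1177, 1.0000, 1.1177),
    ("Zhejiang", 1.0385, 0.9582, 1.0839),
    ("Fujian", 1.0714, 1.0000, 1.0714),
    ("Guangdong", 1.0927, 1.0169, 1.0745),
    ("Guangxi", 1.0000, 1.0000, 1.0000),
    ("Hainan", 1.0675, 1.0000, 1.0675),
]

_OVERALL = (1.0645, 0.9899, 1.0754)


def national_scores() -> pd.DataFrame:
    """Yearly national combined scores with their reported status."""
    return pd.DataFrame(_NATIONAL, columns=["period", "score", "status"])


def provincial_scores_2016() -> pd.DataFrame:
    """Provincial combined scores and reported ranks for 2016."""
    return pd.DataFrame(_PROVINCIAL_2016, columns=["dmu", "score", "rank"])


def provincial_change_rates(include_overall: bool = False) -> pd.DataFrame:
    """Per-province geometric-mean GMI/EC/BPC over 2004-2016."""
    frame = pd.DataFrame(_CHANGE_RATES, columns=["dmu", "gmi", "ec", "bpc"])
    if include_overall:
        overall = pd.DataFrame([("Overall", *_OVERALL)],
                               columns=["dmu", "gmi", "ec", "bpc"])
        frame = pd.concat([frame, overall], ignore_index=True)
    return frame
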