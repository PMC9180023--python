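"""Packaged reference data.

``contribution_reference_table`` returns a published reference table of
within-zone contribution rates (percent of total Theil inequity
attributable to differences inside economic zones) for China's rural
three-tier healthcare system, 2003-2020, under the population calibre:
18 years x 8 (tier, kind) columns plus the printed arithmetic-mean row.
It serves as the worked example and as the validation fixture for the
contribution-table formatter: feeding the yearly rows through
:func:`equipanel.theil.format_contribution_table` must reproduce the
printed mean row to 2 decimals.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

_COLUMNS = [
    "cmhi_institution", "cmhi_bed", "cmhi_personnel",
    "th_institution", "th_bed", "th_personnel",
    "vc_institution", "vc_personnel",
]

_TABLE = """\
year,cmhi_institution,cmhi_bed,cmhi_personnel,th_institution,th_bed,th_personnel,vc_institution,vc_personnel
2003,79.80,94.86,98.97,67.38,99.52,89.51,95.21,97.40
2004,82.51,95.71,99.27,58.51,99.87,86.92,96.55,98.56
2005,80.05,94.86,98.32,56.83,98.51,83.51,94.50,97.43
2006,81.37,95.26,98.61,57.81,94.51,85.56,94.11,93.21
2007,84.78,96.26,98.74,63.95,93.68,91.81,95.56,96.94
2008,85.11,96.30,99.09,63.51,91.29,92.30,94.96,96.31
2009,85.27,94.90,98.54,63.25,86.22,92.18,94.27,94.70
2010,85.19,93.90,98.51,60.23,85.20,93.85,92.18,94.27
2011,84.99,93.15,98.37,58.23,85.35,94.03,90.59,93.56
2012,85.16,93.43,98.39,57.99,83.92,94.39,90.73,93.46
2013,82.53,89.99,96.62,58.16,81.80,94.57,90.54,93.71
2014,81.18,88.00,95.24,58.32,79.37,92.58,90.14,93.17
2015,81.00,87.21,94.54,59.07,78.78,91.18,89.84,93.13
2016,80.94,87.23,93.98,59.67,77.79,90.20,89.77,92.36
2017,82.43,86.39,92.97,59.69,76.46,88.28,89.34,90.83
2018,85.58,86.89,93.97,60.16,76.09,87.33,90.00,89.27
2019,84.75,84.97,93.48,59.25,75.31,87.94,90.20,87.36
2020,81.65,82.01,89.38,58.64,71.72,82.49,88.41,83.11
mean,83.02,91.18,96.50,60.04,85.30,89.93,92.05,93.27
"""


def contribution_reference_table(include_mean: bool = True) -> pd.DataFrame:
    """The reference contribution-rate table (percent), indexed by year.

    With ``include_mean=False`` only the 18 yearly rows are returned (year
    index as int), suitable as input to the contribution-table formatter;
    with ``include_mean=True`` the printed mean row is appended (string
    index, as published).
    """
    df = pd.read_csv(StringIO(_TABLE), index_col="year")
    df = df[_COLUMNS].astype(float)
    if include_mean:
        return df
    yearly = df.drop(index="mean")
    yearly.index = yearly.index.astype(int)
    return yearly
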