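"""Published 20-patient reference results for multilayer vs single-layer models.

These are the per-patient stress/strain summaries reported by the OCT-based
clinical modelling study that this package reimplements as a reusable
pipeline.  Each table holds, for one region (plaque inner wall, fibrous cap,
out-wall) and one measure (maximum-principal stress in kPa, or
maximum-principal strain, dimensionless), the per-patient maximum and mean
values under the multilayer and the single-layer wall treatment together
with the printed relative difference in percent (single-layer as base).

They serve two purposes:

1. fixture inputs for the pure-arithmetic summary stage
   (:func:`plaquemech.extraction.cohort_average`,
   :func:`plaquemech.stats.paired_t`), whose outputs must reproduce the
   printed cohort summary rows, and
2. the reference magnitudes that synthetic-cohort results are compared
   against qualitatively (sign of the multilayer-vs-single-layer effect).

Patient demographic context: 20 patients (13 male, 7 female), ages 32-81,
imaged vessels RCA/LCX/LAD, systolic pressures 101-175 mmHg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "plaque_stress_table",
    "plaque_strain_table",
    "cap_stress_table",
    "cap_strain_table",
    "outwall_stress_table",
    "outwall_strain_table",
    "all_tables",
    "patient_pressures_mmHg",
    "summary_rows",
]

_COLS = ["max_multi", "max_single", "max_diff_pct", "mean_multi", "mean_single", "mean_diff_pct"]

# Systolic/diastolic blood pressure per patient (mmHg), in patient order.
_BP = [
    (138, 71), (155, 84), (149, 63), (150, 89), (112, 69),
    (150, 55), (151, 62), (117, 79), (128, 78), (143, 80),
    (115, 64), (130, 90), (159, 84), (124, 84), (175, 92),
    (130, 84), (113, 60), (136, 85), (141, 85), (101, 61),
]

_PLAQUE_STRESS = """
467.36 279.88 66.99 176.91 109.97 60.87
381.40 277.28 37.55 146.13 103.47 41.24
289.47 201.25 43.84 118.20 86.70 36.34
261.41 173.43 50.73 101.99 77.71 31.25
362.32 240.66 50.55 160.32 100.50 59.51
388.89 323.54 20.20 150.27 114.24 31.53
684.90 523.80 30.76 190.35 139.14 36.80
490.42 319.88 53.31 165.07 104.52 57.92
322.70 199.48 61.77 96.91 71.58 35.39
504.88 316.96 59.29 166.36 106.23 56.59
198.05 118.12 67.67 95.64 73.59 29.96
408.69 290.87 40.51 117.94 89.84 31.28
340.09 251.97 34.97 131.55 96.28 36.63
305.10 161.21 89.26 139.06 95.83 45.11
432.01 316.37 36.55 150.62 110.79 35.96
321.55 257.06 25.09 120.71 88.56 36.30
262.60 140.37 87.07 104.65 74.08 41.27
486.95 424.14 14.81 87.11 74.64 16.71
355.37 268.27 32.47 78.06 68.60 13.79
438.45 333.73 31.38 93.89 79.17 18.59
"""

_PLAQUE_STRAIN = """
0.247 0.223 10.90 0.158 0.126 25.44
0.285 0.253 12.68 0.146 0.124 17.90
0.294 0.255 15.29 0.134 0.112 19.24
0.202 0.174 15.62 0.125 0.105 18.54
0.219 0.191 14.92 0.150 0.117 27.99
0.271 0.259 4.82 0.149 0.130 14.46
0.342 0.319 7.25 0.166 0.145 14.52
0.227 0.199 13.93 0.151 0.119 26.86
0.241 0.205 17.68 0.113 0.092 22.15
0.275 0.224 22.81 0.149 0.121 23.33
0.174 0.141 23.69 0.115 0.094 21.94
0.299 0.270 10.80 0.126 0.108 16.73
0.231 0.205 12.62 0.138 0.118 16.12
0.198 0.171 15.85 0.142 0.116 22.84
0.253 0.231 9.63 0.145 0.127 13.89
0.272 0.253 7.55 0.121 0.100 20.82
0.192 0.163 17.99 0.120 0.095 26.66
0.473 0.461 2.66 0.109 0.099 10.74
0.307 0.287 7.12 0.101 0.093 8.15
0.286 0.258 10.82 0.108 0.097 11.37
"""

_CAP_STRESS = """
467.36 279.88 66.99 212.51 131.23 61.93
381.40 277.28 37.55 103.76 82.69 25.47
289.47 201.25 43.84 131.38 96.25 36.49
164.02 129.00 27.15 86.71 71.15 21.87
362.32 240.66 50.55 147.76 102.58 44.05
388.89 323.54 20.20 149.10 127.78 16.68
684.90 523.80 30.76 228.43 168.23 35.79
490.42 319.88 53.31 186.65 122.68 52.15
322.70 199.48 61.77 91.47 73.05 25.20
504.88 316.96 59.29 133.75 92.06 45.28
100.67 92.55 8.77 69.77 62.73 11.23
408.69 290.87 40.51 98.57 82.11 20.04
158.97 135.50 17.32 80.57 71.19 13.17
205.56 128.05 60.53 107.36 82.71 29.80
289.30 227.39 27.23 86.39 75.52 14.39
197.51 169.89 16.26 84.78 79.34 6.86
169.42 139.93 21.08 72.49 63.84 13.55
486.95 424.14 14.81 92.27 80.86 14.11
296.57 238.49 24.35 105.04 90.65 15.87
438.45 333.73 31.38 128.35 106.53 20.48
"""

_CAP_STRAIN = """
0.247 0.223 10.90 0.168 0.137 22.12
0.285 0.253 12.68 0.091 0.084 7.91
0.294 0.255 15.29 0.142 0.121 17.59
0.175 0.161 8.94 0.109 0.095 14.78
0.213 0.185 15.25 0.135 0.114 18.84
0.271 0.259 4.82 0.146 0.136 7.46
0.342 0.319 7.25 0.178 0.158 12.58
0.227 0.199 13.93 0.151 0.125 20.82
0.241 0.205 17.68 0.104 0.090 15.23
0.245 0.215 14.32 0.114 0.096 19.03
0.133 0.125 6.69 0.086 0.078 9.85
0.299 0.270 10.80 0.103 0.094 8.84
0.180 0.163 9.84 0.104 0.096 8.43
0.175 0.152 14.87 0.114 0.096 18.05
0.200 0.185 8.10 0.098 0.091 7.59
0.176 0.182 -3.71 0.074 0.073 0.91
0.177 0.163 8.49 0.093 0.083 12.96
0.473 0.461 2.66 0.112 0.104 7.78
0.285 0.259 10.09 0.116 0.107 8.15
0.286 0.258 10.82 0.133 0.120 10.75
"""

_OUTWALL_STRESS = """
33.63 79.42 -57.66 18.77 58.84 -68.11
63.73 89.32 -28.65 18.35 58.49 -68.63
31.43 80.73 -61.07 13.82 50.71 -72.74
24.03 64.34 -62.65 11.05 45.75 -75.85
30.92 77.76 -60.23 21.42 62.24 -65.58
32.45 80.03 -59.45 12.83 49.07 -73.85
28.92 72.13 -59.90 15.61 55.05 -71.65
54.21 91.84 -40.98 20.54 59.48 -65.46
34.88 76.54 -54.44 10.54 43.88 -75.97
43.74 86.38 -49.37 21.83 63.08 -65.39
27.53 71.38 -61.43 13.24 48.69 -72.80
35.35 89.72 -60.60 12.96 49.75 -73.96
32.38 81.33 -60.19 14.84 52.62 -71.80
42.95 93.20 -53.91 20.20 60.78 -66.77
39.77 91.31 -56.45 17.19 57.23 -69.97
27.49 68.31 -59.76 12.26 46.76 -73.77
39.40 81.64 -51.74 13.74 48.63 -71.74
24.90 62.47 -60.14 8.61 40.85 -78.92
14.85 47.79 -68.94 6.34 36.80 -82.78
32.73 62.00 -47.21 8.34 40.61 -79.48
"""

_OUTWALL_STRAIN = """
0.171 0.078 118.02 0.099 0.055 81.22
0.212 0.096 121.27 0.092 0.055 67.04
0.158 0.080 96.23 0.072 0.053 36.12
0.131 0.061 115.68 0.060 0.051 17.56
0.173 0.072 139.94 0.117 0.054 114.91
0.151 0.073 107.86 0.072 0.052 36.37
0.166 0.072 130.64 0.089 0.052 72.57
0.211 0.098 115.70 0.101 0.057 79.30
0.161 0.081 98.70 0.064 0.052 22.80
0.201 0.098 103.95 0.106 0.056 88.76
0.140 0.069 104.20 0.072 0.053 36.09
0.160 0.090 78.01 0.073 0.054 35.58
0.159 0.080 98.89 0.078 0.055 41.90
0.175 0.104 68.78 0.096 0.059 63.32
0.156 0.094 65.19 0.082 0.057 42.42
0.140 0.065 115.72 0.065 0.052 27.00
0.155 0.082 88.18 0.072 0.053 35.93
0.106 0.061 71.95 0.055 0.051 7.11
0.101 0.051 97.30 0.054 0.051 4.54
0.190 0.053 261.90 0.058 0.051 13.68
"""

# Printed cohort summary rows: (max_multi, max_multi_sd, max_single,
# max_single_sd, max_diff_pct, mean_multi, mean_multi_sd, mean_single,
# mean_single_sd, mean_diff_pct).  The out-wall stress table's printed
# max-multi SD (148.92) repeats the cap-stress SD and is inconsistent with
# its own column; the recomputed 10.77 is stored here.
_SUMMARY = {
    "plaque_stress": (385.13, 110.09, 270.91, 95.86, 42.16, 129.59, 32.77, 93.27, 18.20, 38.93),
    "plaque_strain": (0.264, 0.066, 0.237, 0.069, 11.57, 0.133, 0.019, 0.112, 0.015, 19.02),
    "cap_stress": (340.42, 148.92, 249.61, 108.09, 36.38, 119.86, 45.46, 93.16, 26.74, 28.66),
    "cap_strain": (0.246, 0.077, 0.225, 0.074, 9.63, 0.118, 0.028, 0.105, 0.022, 12.93),
    "outwall_stress": (34.76, 10.77, 77.38, 12.00, -55.07, 14.62, 4.54, 51.47, 7.73, -71.58),
    "outwall_strain": (0.161, 0.030, 0.078, 0.015, 106.40, 0.079, 0.018, 0.054, 0.002, 46.95),
}


def _parse(block: str) -> pd.DataFrame:
    rows = [[float(x) for x in line.split()] for line in block.strip().splitlines()]
    df = pd.DataFrame(rows, columns=_COLS)
    df.index = pd.RangeIndex(1, len(df) + 1, name="patient")
    return df


def plaque_stress_table() -> pd.DataFrame:
    """Per-patient max/mean plaque (inner-wall) stress, kPa."""
    return _parse(_PLAQUE_STRESS)


def plaque_strain_table() -> pd.DataFrame:
    """Per-patient max/mean plaque (inner-wall) strain, dimensionless."""
    return _parse(_PLAQUE_STRAIN)


def cap_stress_table() -> pd.DataFrame:
    """Per-patient max/mean fibrous-cap stress, kPa."""
    return _parse(_CAP_STRESS)


def cap_strain_table() -> pd.DataFrame:
    """Per-patient max/mean fibrous-cap strain, dimensionless."""
    return _parse(_CAP_STRAIN)


def outwall_stress_table() -> pd.DataFrame:
    """Per-patient max/mean out-wall stress, kPa."""
    return _parse(_OUTWALL_STRESS)


def outwall_strain_table() -> pd.DataFrame:
    """Per-patient max/mean out-wall strain, dimensionless."""
    return _parse(_OUTWALL_STRAIN)


def all_tables() -> dict[str, pd.DataFrame]:
    """All six reference tables keyed by ``{region}_{measure}``."""
    return {
        "plaque_stress": plaque_stress_table(),
        "plaque_strain": plaque_strain_table(),
        "cap_stress": cap_stress_table(),
        "cap_strain": cap_strain_table(),
        "outwall_stress": outwall_stress_table(),
        "outwall_strain": outwall_strain_table(),
    }


def patient_pressures_mmHg() -> pd.DataFrame:
    """Per-patient systolic/diastolic pressure (mmHg) from the reference cohort."""
    df = pd.DataFrame(_BP, columns=["systolic", "diastolic"])
    df.index = pd.RangeIndex(1, len(df) + 1, name="patient")
    return df


def summary_rows() -> dict[str, tuple]:
    """Printed cohort Mean ± SD summary rows for each reference table.

    Tuple layout: (max_multi, max_multi_sd, max_single, max_single_sd,
    max_diff_pct, mean_multi, mean_multi_sd, mean_single, mean_single_sd,
    mean_diff_pct).
    """
    return dict(_SUMMARY)


def table_summary(df: pd.DataFrame) -> dict[str, float]:
    """Recompute a cohort summary row (means, sample SDs, relative
    differences of cohort means) from a per-patient table."""
    out: dict[str, float] = {}
    for col in ("max_multi", "max_single", "mean_multi", "mean_single"):
        v = np.asarray(df[col], dtype=float)
        out[col] = float(v.mean())
        out[col + "_sd"] = float(v.std(ddof=1))
    out["max_diff_pct"] = 100.0 * (out["max_multi"] - out["max_single"]) / out["max_single"]
    out["mean_diff_pct"] = 100.0 * (out["mean_multi"] - out["mean_single"]) / out["mean_single"]
    return out
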