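"""Published Nurr1–RXRα heterodimer thermodynamic reference panel.

Per-ligand fitted log K_D (log M), association enthalpy ΔH (kcal/mol) and the
derived TΔS (kcal/mol), with per-replicate values as printed.  These are the
inputs for round-trip benchmarks and for anchoring the synthetic generator's
class ranges; they are data, not fitted output of this package.

The 9cRA TΔS average/s.d. as printed (13.539 ± 3.105) disagree both with its
own replicates (12.589, 11.344) and with ΔH − ΔG ≈ 11.97; the row is flagged
``tds_inconsistent`` and excluded from internal-consistency checks rather than
silently corrected.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_panel", "REFERENCE_ROWS", "HOMODIMER_KD", "HOMODIMER_DH"]

HOMODIMER_KD = 1.63e-5  # M
HOMODIMER_DH = -13.10  # kcal/mol

# ligand, class, logKD avg, sd, n, replicates, dH avg, sd, replicates,
# TdS avg, sd, replicates, tds_inconsistent
REFERENCE_ROWS = [
    ("DMSO", "vehicle", -5.335, 0.118, 2, (-5.418, -5.252),
     2.900, 0.240, (3.070, 2.730), 10.179, 0.401, (10.462, 9.895), False),
    ("BRF110", "heterodimer-selective", -4.376, 0.020, 2, (-4.390, -4.362),
     5.365, 0.361, (5.110, 5.620), 11.335, 0.334, (11.099, 11.571), False),
    ("HX600", "heterodimer-selective", -4.662, 0.028, 2, (-4.681, -4.642),
     7.695, 4.320, (4.640, 10.750), 14.054, 4.283, (11.026, 17.083), False),
    ("9cRA", "classical agonist", -5.026, 0.060, 2, (-4.984, -5.068),
     5.110, 0.962, (5.790, 4.430), 13.539, 3.105, (12.589, 11.344), True),
    ("Bexarotene", "classical agonist", -4.619, 0.044, 2, (-4.588, -4.650),
     5.555, 1.336, (4.610, 6.500), 11.857, 1.396, (10.870, 12.844), False),
    ("LG100268", "classical agonist", -5.044, 0.106, 2, (-5.119, -4.969),
     5.135, 0.148, (5.240, 5.030), 12.017, 0.294, (12.224, 11.809), False),
    ("CD3254", "classical agonist", -4.860, 0.099, 2, (-4.930, -4.790),
     4.865, 0.389, (5.140, 4.590), 11.495, 0.524, (11.866, 11.125), False),
    ("SR11237", "classical agonist", -5.053, 0.047, 2, (-5.087, -5.020),
     4.940, 0.962, (5.620, 4.260), 11.834, 1.026, (12.560, 11.109), False),
    ("UVI3003", "antagonist", -4.565, 0.021, 2, (-4.580, -4.550),
     6.125, 2.638, (7.990, 4.260), 12.353, 2.666, (14.238, 10.467), False),
    ("LG100754", "antagonist", -5.222, 0.026, 2, (-5.204, -5.240),
     4.270, 0.226, (4.110, 4.430), 11.394, 0.261, (11.209, 11.579), False),
    ("IRX4204", "classical agonist", -4.673, 0.000, 1, (-4.673,),
     8.460, 0.000, (8.460,), 14.835, 0.000, (14.835,), False),
    ("Rhein", "antagonist", -5.554, 0.077, 2, (-5.499, -5.609),
     2.780, 0.396, (3.060, 2.500), 10.357, 0.290, (10.563, 10.152), False),
    ("HX531", "antagonist", -6.132, 0.133, 2, (-6.226, -6.038),
     2.205, 0.021, (2.190, 2.220), 10.571, 0.160, (10.684, 10.457), False),
    ("Danthron", "antagonist", -5.524, 0.043, 2, (-5.494, -5.554),
     2.920, 0.170, (3.040, 2.800), 10.456, 0.111, (10.535, 10.378), False),
    ("PA452", "antagonist", -5.417, 0.000, 1, (-5.417,),
     4.120, 0.000, (4.120,), 11.510, 0.000, (11.510,), False),
]


def reference_panel() -> pd.DataFrame:
    """Return the published thermodynamic panel as a tidy DataFrame."""
    records = []
    for (name, cls, lk, lk_sd, n, lk_rep, dh, dh_sd, dh_rep,
         tds, tds_sd, tds_rep, bad) in REFERENCE_ROWS:
        records.append(
            dict(
                ligand=name,
                class_label=cls,
                log_kd_avg=lk,
                log_kd_sd=lk_sd,
                n=n,
                log_kd_replicates=lk_rep,
                dh_avg=dh,
                dh_sd=dh_sd,
                dh_replicates=dh_rep,
                tds_avg=tds,
                tds_sd=tds_sd,
                tds_replicates=tds_rep,
                tds_inconsistent=bad,
            )
        )
    return pd.DataFrame.from_records(records).set_index("ligand")
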