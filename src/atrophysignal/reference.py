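"""Published reference values used as analysis inputs.

Two concentration-response parameter sets for the sulfonylureas
(glibenclamide, tolbutamide, glimepiride) and glinides (repaglinide,
nateglinide) in mouse skeletal muscle, as mean +/- SE of four-parameter
logistic fits:

* ``PROTEIN_CONTENT_PARAMS`` - percent change of protein content/muscle
  weight after 24 h incubation (the atrophy endpoint);
* ``KATP_BLOCK_PARAMS`` - percent change of the sarcolemmal KATP channel
  current in excised patches (the channel-block endpoint).

Responses are signed percent reductions, so Emax and Emin are negative.
EC50 values are stored in mol/L.  Rows whose published fit did not
converge carry ``None`` parameters and are kept so that batch code must
handle them.

Also included: the spontaneous-report counts for the muscle-atrophy term
over the eight-month observation window (reaction count and total report
count per drug, plus the all-drugs totals), the efficacy-ranking strings
the concentration-response analysis is expected to reproduce, and the
concentration grids used for the two endpoints.
"""

from __future__ import annotations

from .dose_response import HillParams

__all__ = [
    "DRUG_ABBREV",
    "PROTEIN_CONTENT_PARAMS",
    "KATP_BLOCK_PARAMS",
    "ATROPHY_REPORT_COUNTS",
    "ALL_DRUGS_ATROPHY_COUNT",
    "ALL_DRUGS_TOTAL_REPORTS",
    "DEXAMETHASONE_SIGNAL",
    "PROTEIN_DOSE_RANGE",
    "KATP_DOSE_RANGE",
    "EXPECTED_RANKINGS",
    "complete_rows",
    "as_hill_params",
]

#: short labels used in efficacy-ranking strings
DRUG_ABBREV = {
    "glibenclamide": "glib.",
    "tolbutamide": "tolb.",
    "glimepiride": "glimep.",
    "repaglinide": "repa.",
    "nateglinide": "nate.",
}

# (drug, muscle) -> dict of parameter point estimates and standard errors;
# emax/emin in %, ec50 in mol/L, slope dimensionless. None = no convergent fit.


def _row(emax, emax_se, emin, emin_se, ec50_uM, ec50_se_uM, slope, slope_se):
    return {
        "emax": emax, "emax_se": emax_se,
        "emin": emin, "emin_se": emin_se,
        "ec50": ec50_uM * 1e-6 if ec50_uM is not None else None,
        "ec50_se": ec50_se_uM * 1e-6 if ec50_se_uM is not None else None,
        "slope": slope, "slope_se": slope_se,
    }


_NO_FIT = {k: None for k in ("emax", "emax_se", "emin", "emin_se", "ec50", "ec50_se", "slope", "slope_se")}

PROTEIN_CONTENT_PARAMS = {
    ("glibenclamide", "FDB"): _row(-56.36, 9, -5.98, 0.1, 8.84, 0.1, 0.29, 0.01),
    ("glibenclamide", "EDL"): _row(-33.12, 6, -2.91, 0.2, 66.6, 6, 0.62, 0.02),
    ("glibenclamide", "SOL"): _row(-35.52, 7, -5.43, 0.3, 91.1, 4, 0.61, 0.03),
    ("tolbutamide", "FDB"): _row(-47.08, 9, -1.59, 0.1, 107.1, 11, 0.89, 0.01),
    ("tolbutamide", "EDL"): dict(_NO_FIT, emax=-18.8, emax_se=7),
    ("tolbutamide", "SOL"): _row(-26.56, 6, -1.20, 0.2, 219.2, 12, 1.03, 0.01),
    ("glimepiride", "FDB"): _row(-40.42, 8, -2.39, 0.1, 29.3, 9, 0.45, 0.01),
    ("glimepiride", "EDL"): _row(-28.47, 7, -1.44, 0.2, 202.1, 12, 0.45, 0.02),
    ("glimepiride", "SOL"): dict(_NO_FIT, emax=-10.1, emax_se=6),
    ("repaglinide", "FDB"): _row(-57.52, 9, -1.39, 0.1, 5.21, 2, 0.32, 0.01),
    ("repaglinide", "EDL"): _row(-39.95, 4, -2.62, 0.2, 139.1, 17, 0.75, 0.02),
    ("repaglinide", "SOL"): _row(-45.72, 6, -4.30, 0.3, 71.5, 7, 0.46, 0.02),
    ("nateglinide", "FDB"): _row(-24.73, 2, -2.94, 0.1, 161.2, 12, 1.05, 0.01),
    ("nateglinide", "EDL"): _row(-35.99, 3, -7.71, 0.3, 110.1, 12, 1.27, 0.02),
    ("nateglinide", "SOL"): _row(-29.52, 4, -0.73, 0.1, 180.1, 11, 0.92, 0.01),
}

KATP_BLOCK_PARAMS = {
    ("glibenclamide", "FDB"): _row(-98.9, 9, -2.4, 1, 1.08, 0.2, 0.91, 0.01),
    ("glibenclamide", "EDL"): _row(-78.1, 6, -2.9, 1, 30.7, 7, 0.82, 0.02),
    ("glibenclamide", "SOL"): _row(-70.5, 4, -3.2, 0.7, 35.1, 2, 0.75, 0.03),
    ("tolbutamide", "FDB"): _row(-40.6, 8, -1.59, 0.2, 170.1, 11, 0.61, 0.04),
    ("tolbutamide", "EDL"): dict(_NO_FIT, emax=-26.3, emax_se=5),
    ("tolbutamide", "SOL"): dict(_NO_FIT, emax=-19.1, emax_se=3),
    ("glimepiride", "FDB"): _row(-45.4, 9, -2.3, 0.1, 36.7, 10, 0.93, 0.03),
    ("glimepiride", "EDL"): _row(-80.4, 7, -1.9, 0.2, 48.8, 8, 0.91, 0.02),
    ("glimepiride", "SOL"): _row(-75.3, 6, -2.1, 0.3, 55.1, 11, 0.90, 0.05),
    ("repaglinide", "FDB"): _row(-75.4, 9, -1.3, 0.2, 1.67, 0.9, 0.93, 0.04),
    ("repaglinide", "EDL"): _row(-70.4, 10, -4.9, 0.5, 55.6, 11, 0.82, 0.07),
    ("repaglinide", "SOL"): _row(-78.3, 8, -3.1, 0.5, 17.11, 4, 0.90, 0.08),
    ("nateglinide", "FDB"): _row(-48.7, 7, -1.3, 0.4, 132.1, 18, 0.78, 0.07),
    ("nateglinide", "EDL"): _row(-50.3, 6, -4.9, 0.5, 120.1, 11, 0.67, 0.09),
    ("nateglinide", "SOL"): _row(-55.2, 9, -3.1, 1, 110.1, 21, 0.71, 0.08),
}

#: drug -> (muscle-atrophy report count, total report count), 8-month window
ATROPHY_REPORT_COUNTS = {
    "glibenclamide": (4, 1460),
    "glimepiride": (0, 945),
    "tolbutamide": (0, 34),
    "repaglinide": (0, 337),
    "nateglinide": (0, 83),
}
ALL_DRUGS_ATROPHY_COUNT = 373
ALL_DRUGS_TOTAL_REPORTS = 1_697_582

#: dexamethasone, the positive-control atrophy signal: n reports, PRR, chi-square
DEXAMETHASONE_SIGNAL = {"n_reaction_reports": 20, "prr": 12.2, "chi2": 9.2}

#: concentration grids (mol/L): protein-content curves span 1e-7 to 5e-4,
#: KATP-current curves 1e-9 to 5e-4
PROTEIN_DOSE_RANGE = (1e-7, 5e-4)
KATP_DOSE_RANGE = (1e-9, 5e-4)

#: published efficacy-ranking strings per endpoint and muscle
EXPECTED_RANKINGS = {
    ("protein_content", "FDB"): "repa.≥glib.>glimep.>tolb.>nate.",
    ("protein_content", "SOL"): "repa.≥glib.>nate.≥tolb.>glimep.",
}


def complete_rows(params: dict) -> dict:
    """Subset of a parameter table whose rows have a full 4PL fit."""
    return {key: row for key, row in params.items() if row["ec50"] is not None}


def as_hill_params(row: dict) -> HillParams:
    """Convert a reference row to :class:`HillParams`."""
    return HillParams(emax=row["emax"], emin=row["emin"], ec50=row["ec50"], slope=row["slope"])
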