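"""Stable-isotope habitat-use analysis for a marine/terrestrial forager.

delta13C separates marine from terrestrial carbon sources and delta15N
indexes trophic level, so in a two-endmember world a bird's blood values
should increase linearly with the proportion of its foraging done at sea.
This module converts raw isotope ratios to delta notation, applies lipid
normalization (plasma) and diet-to-tissue discrimination, derives each
individual's proportion of locations at sea from its tracked trips, and
regresses delta values on that proportion per isotope and tissue.

Plasma integrates roughly the 3 days before sampling and red blood cells
3-4 weeks, so the two tissues probe short- and medium-term diet.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import LandscapeMask
from .trajectory import MARINE_CLASSES

#: diet-to-blood trophic discrimination, per mil (aquatic-bird average)
DISCRIMINATION_PERMIL = {"C": 0.7, "N": 2.4}

TISSUES = ("plasma", "red_blood_cells")


def delta_value(r_sample: float, r_standard: float) -> float:
    """Heavy/light isotope ratio expressed as per-mil deviation from standard.

    ``delta = (R_sample / R_standard - 1) * 1000``.
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def lipid_normalize(d13c: float, c_to_n: float) -> float:
    """Correct delta13C for lipid content from the tissue C:N mass ratio.

    ``delta13C_normalized = delta13C - 3.32 + 0.99 * C:N`` (aquatic-animal
    calibration). Intended for plasma, whose variable lipid load depletes
    13C; warns above C:N = 10 where the linear correction is extrapolating.
    """
    if c_to_n <= 0:
        raise ValueError("C:N ratio must be positive")
    if c_to_n > 10:
        warnings.warn(f"C:N = {c_to_n:g} far outside the calibration range; "
                      "normalized value is an extrapolation")
    return d13c - 3.32 + 0.99 * c_to_n


def apply_discrimination(delta: float, isotope: str) -> float:
    """Shift a consumer delta value onto the prey scale.

    Subtracts the trophic discrimination factor (0.7 per mil for carbon,
    2.4 for nitrogen). Not idempotent: use :func:`correct_samples` for
    table-level application with a double-application guard.
    """
    if isotope not in DISCRIMINATION_PERMIL:
        raise ValueError(f"unknown isotope {isotope!r}; expected 'C' or 'N'")
    return delta - DISCRIMINATION_PERMIL[isotope]


def correct_samples(samples: pd.DataFrame,
                    normalize_red_cells: bool = False) -> pd.DataFrame:
    """Lipid-normalize then discriminate, keeping raw columns alongside.

    Adds ``d13C_norm`` (lipid-normalized; plasma only unless
    ``normalize_red_cells``), ``d13C_prey`` and ``d15N_prey``
    (discrimination-corrected). Raises if the table was already corrected.
    """
    if samples.attrs.get("discrimination_applied"):
        raise ValueError("discrimination already applied to this table")
    out = samples.copy()
    norm = out["d13C"].astype(float).copy()
    which = out["tissue"].eq("plasma") | normalize_red_cells
    norm[which] = [lipid_normalize(d, cn) for d, cn in
                   zip(out.loc[which, "d13C"], out.loc[which, "c_to_n"])]
    out["d13C_norm"] = norm
    out["d13C_prey"] = norm - DISCRIMINATION_PERMIL["C"]
    out["d15N_prey"] = out["d15N"].astype(float) - DISCRIMINATION_PERMIL["N"]
    out.attrs["discrimination_applied"] = True
    return out


def sea_fraction(trips, mask: LandscapeMask) -> dict:
    """Per-individual proportion of off-colony trip fixes located at sea.

    Marine fixes (open sea or tidal flat) are counted against all
    off-colony trip fixes; individuals with no off-colony fixes are
    omitted (fraction undefined).
    """
    marine = {}
    total = {}
    for trip in trips:
        fx = trip.fixes
        classes = mask.classify_many(fx["lon"].to_numpy(), fx["lat"].to_numpy())
        off = classes != "colony"
        ind = trip.individual_id
        total[ind] = total.get(ind, 0) + int(off.sum())
        marine[ind] = marine.get(ind, 0) + int(np.isin(classes[off],
                                                       list(MARINE_CLASSES)).sum())
    return {ind: marine[ind] / total[ind] for ind in total if total[ind] > 0}


def isotope_regression(samples: pd.DataFrame, fractions: dict,
                       value_cols=("d13C", "d15N")) -> pd.DataFrame:
    """OLS of delta values on the proportion of foraging at sea.

    One regression per isotope column x tissue over individuals present in
    both inputs; returns slope, intercept, SE, ``t = slope / SE``,
    two-sided p and residual df = n - 2.
    """
    rows = []
    for tissue in sorted(samples["tissue"].unique()):
        sub = samples[samples["tissue"] == tissue]
        sub = sub[sub["individual_id"].isin(fractions)]
        x = np.array([fractions[i] for i in sub["individual_id"]], dtype=float)
        if len(x) < 3:
            raise ValueError(f"need >= 3 matched individuals for {tissue}")
        if np.ptp(x) == 0:
            raise ValueError("sea fractions have zero variance; slope undefined")
        for col in value_cols:
            y = sub[col].to_numpy(dtype=float)
            fit = stats.linregress(x, y)
            n = len(x)
            t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
            p = 2.0 * stats.t.sf(abs(t), n - 2) if np.isfinite(t) else 0.0
            rows.append({"isotope": col, "tissue": tissue, "n": n,
                         "slope": fit.slope, "intercept": fit.intercept,
                         "slope_se": fit.stderr, "t": t, "p": p, "df": n - 2})
    return pd.DataFrame(rows)
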