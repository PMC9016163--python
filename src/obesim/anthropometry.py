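"""Child BMI-for-age z-scores (LMS method) and weight-status classification.

Children are classified on the BMI z-score scale (underweight < -2,
normal [-2, 1), overweight [1, 2), obese >= 2) against an age- and
sex-specific LMS growth reference; adults on the raw BMI scale
(underweight < 18.5, normal [18.5, 25), overweight [25, 30),
obese >= 30 kg/m^2).  The child/adult dispatch age is 18 years so that
the classification boundary coincides with the simulation's adult-stage
boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "WEIGHT_STATUS_CATEGORIES",
    "ADULT_AGE",
    "lms_zscore",
    "zscore_for_age",
    "classify_child",
    "classify_adult",
    "classify",
    "synthetic_growth_reference",
    "validate_growth_reference",
]

WEIGHT_STATUS_CATEGORIES = ("underweight", "normal", "overweight", "obese")

#: Age (years) at which classification switches from the child z-score rule
#: to the adult BMI rule.  Deliberately 18 (not 19) to match the model's
#: adult life stages.
ADULT_AGE = 18.0

GROWTH_REFERENCE_COLUMNS = ("sex", "age_months", "L", "M", "S")


def lms_zscore(bmi, L, M, S):
    """BMI-for-age z-score via the LMS transformation.

    z = ((bmi/M)**L - 1) / (L*S) for L != 0, and ln(bmi/M)/S for L == 0
    (the analytic limit).  Accepts scalars or arrays; bmi, M, S must be
    positive.
    """
    bmi = np.asarray(bmi, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(bmi <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("bmi, M and S must all be positive")
    ratio = bmi / M
    # |L| below ~1e-7 loses all precision in (ratio**L - 1)/L; use the
    # analytic L->0 limit there.
    small = np.abs(L) < 1e-7
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            small,
            np.log(ratio) / S,
            (np.power(ratio, np.where(small, 1.0, L)) - 1.0)
            / np.where(small, 1.0, L * S),
        )
    if z.ndim == 0:
        return float(z)
    return z


def validate_growth_reference(reference: pd.DataFrame) -> list[str]:
    """Return invariant violations of an LMS reference table (empty = valid)."""
    problems = []
    missing = [c for c in GROWTH_REFERENCE_COLUMNS if c not in reference.columns]
    if missing:
        return [f"growth reference missing columns {missing}"]
    if (reference["M"] <= 0).any() or (reference["S"] <= 0).any():
        problems.append("growth reference: M and S must be positive")
    for sex, grp in reference.groupby("sex"):
        ages = grp["age_months"].to_numpy(dtype=float)
        if not np.all(np.diff(ages) > 0):
            problems.append(f"growth reference: ages not strictly increasing for sex={sex}")
        if ages.min() > 24 or ages.max() < 240:
            problems.append(
                f"growth reference: sex={sex} covers {ages.min():g}-{ages.max():g} months, "
                "must cover at least 24-240"
            )
    return problems


def zscore_for_age(bmi, age_years, sex, reference: pd.DataFrame):
    """BMI z-score against a reference, interpolating L, M, S linearly in age.

    Parameters
    ----------
    bmi, age_years, sex
        Scalars or equal-length arrays; ``sex`` coded as in the reference
        table (0/1 in the shipped synthetic table).
    reference
        LMS table with columns sex, age_months, L, M, S.

    Raises
    ------
    ValueError
        If any age falls outside the reference coverage for its sex.
    """
    bmi = np.atleast_1d(np.asarray(bmi, dtype=float))
    age_months = np.atleast_1d(np.asarray(age_years, dtype=float)) * 12.0
    sex = np.atleast_1d(np.asarray(sex))
    bmi, age_months, sex = np.broadcast_arrays(bmi, age_months, sex)
    z = np.full(bmi.shape, np.nan)
    for s in np.unique(sex):
        grp = reference[reference["sex"] == s]
        if grp.empty:
            raise ValueError(f"growth reference has no rows for sex={s!r}")
        ages = grp["age_months"].to_numpy(dtype=float)
        mask = sex == s
        am = age_months[mask]
        if am.min() < ages[0] or am.max() > ages[-1]:
            raise ValueError(
                f"age {am.min() / 12:.2f}-{am.max() / 12:.2f} years outside growth "
                f"reference coverage [{ages[0] / 12:g}, {ages[-1] / 12:g}] for sex={s!r}"
            )
        L = np.interp(am, ages, grp["L"].to_numpy(dtype=float))
        M = np.interp(am, ages, grp["M"].to_numpy(dtype=float))
        S = np.interp(am, ages, grp["S"].to_numpy(dtype=float))
        z[mask] = lms_zscore(bmi[mask], L, M, S)
    if z.size == 1 and np.isscalar(age_years):
        return float(z[0])
    return z


def classify_child(z):
    """Weight status from a BMI z-score (child rule, left-closed boundaries)."""
    z = np.asarray(z, dtype=float)
    out = np.select(
        [z < -2.0, z < 1.0, z < 2.0],
        ["underweight", "normal", "overweight"],
        default="obese",
    )
    return out.item() if out.ndim == 0 else out


def classify_adult(bmi):
    """Weight status from BMI in kg/m^2 (adult rule, left-closed boundaries)."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0):
        raise ValueError("bmi must be positive")
    out = np.select(
        [bmi < 18.5, bmi < 25.0, bmi < 30.0],
        ["underweight", "normal", "overweight"],
        default="obese",
    )
    return out.item() if out.ndim == 0 else out


def classify(age_years, bmi, z=None):
    """Dispatch to the child rule (age < 18, z-score based) or adult rule.

    For mixed-age arrays, ``z`` must be provided wherever age < 18.
    The z-score argument is ignored for adults.
    """
    age = np.asarray(age_years, dtype=float)
    if age.ndim == 0:
        if float(age) < ADULT_AGE:
            if z is None:
                raise ValueError("child classification requires a BMI z-score")
            return classify_child(z)
        return classify_adult(bmi)
    bmi = np.asarray(bmi, dtype=float)
    child = age < ADULT_AGE
    out = np.empty(age.shape, dtype=object)
    if child.any():
        if z is None:
            raise ValueError("child classification requires BMI z-scores")
        out[child] = classify_child(np.asarray(z, dtype=float)[child])
    if (~child).any():
        out[~child] = classify_adult(bmi[~child])
    return out.astype(str)


def synthetic_growth_reference() -> pd.DataFrame:
    """A synthetic LMS growth reference for testing and the default model.

    Shaped like real BMI-for-age references (infancy peak near 9 months,
    adiposity rebound around age 5-6, steady rise through adolescence) but
    with invented parameter values; it is NOT the CDC or WHO table.  Users
    may supply a real table in the same column layout (sex, age_months,
    L, M, S) with sex coded 0 (female) and 1 (male).
    """
    anchor_months = np.array([0, 6, 9, 12, 24, 42, 66, 108, 156, 180, 216, 240], dtype=float)
    anchor_m_male = np.array(
        [13.4, 16.8, 17.0, 16.8, 16.2, 15.7, 15.4, 16.8, 19.2, 20.2, 21.6, 22.2]
    )
    anchor_l = np.array([-0.5, -0.7, -0.8, -0.9, -1.1, -1.4, -1.8, -2.4, -2.2, -2.0, -1.7, -1.5])
    anchor_s = np.array([0.08, 0.08, 0.085, 0.09, 0.095, 0.10, 0.11, 0.13, 0.13, 0.125, 0.12, 0.12])

    months = np.arange(0, 241, 3, dtype=float)
    rows = []
    for sex in (0, 1):
        m_anchor = anchor_m_male if sex == 1 else anchor_m_male - np.where(anchor_months < 120, 0.2, 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age_months": months,
                    "L": np.interp(months, anchor_months, anchor_l),
                    "M": np.interp(months, anchor_months, m_anchor),
                    "S": np.interp(months, anchor_months, anchor_s),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
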