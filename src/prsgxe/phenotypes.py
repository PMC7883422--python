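"""Analysis-variable preparation.

Covariate and outcome transforms used throughout the pipeline:

* LMS growth-reference z-scores for BMI (CDC-style sex/age reference);
* dichotomization of Tanner stage into pre-pubertal vs pubertal;
* rank-based inverse-normal transformation (Blom offset) of BMD outcomes;
* median binarization of PRS and environment variables;
* per-minute energy-expenditure classification into activity intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "LMSReference",
    "synthetic_lms_reference",
    "bmi_zscore",
    "puberty_binary",
    "inverse_normal",
    "binarize_by_median",
    "classify_activity_minutes",
    "PRE_PUBERTAL",
    "PUBERTAL",
    "ACTIVITY_THRESHOLDS",
]

PRE_PUBERTAL = "pre-pubertal"
PUBERTAL = "pubertal"

# kcal/kg per minute cut-points between sedentary/light/moderate/vigorous;
# lower bound of each class is inclusive.
ACTIVITY_THRESHOLDS = (0.01, 0.04, 0.10)

_LN_EPS = 1e-8  # |L| below this uses the log-limit form of the LMS z-score


@dataclass
class LMSReference:
    """Sex- and age-specific LMS growth reference.

    ``table`` columns: sex ('male'/'female'), agemos (age in months),
    L (Box-Cox power), M (median, > 0), S (coefficient of variation, > 0).
    Rows must be unique on (sex, agemos).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "agemos", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"LMS table lacks columns: {sorted(missing)}")
        t = self.table
        if (t["M"] <= 0).any() or (t["S"] <= 0).any():
            raise ValueError("LMS reference requires M > 0 and S > 0")
        if t.duplicated(["sex", "agemos"]).any():
            raise ValueError("duplicate (sex, age) rows in LMS reference")
        self.table = t.sort_values(["sex", "agemos"]).reset_index(drop=True)

    def lookup(self, sex: str, age_months: float) -> tuple[float, float, float]:
        """L, M, S at the given sex and age.

        The nearest tabulated age is used when within 0.5 month; otherwise
        L, M and S are interpolated linearly in age. Ages outside the
        reference range raise.
        """
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise ValueError(f"no LMS rows for sex {sex!r}")
        ages = sub["agemos"].to_numpy(dtype=float)
        if age_months < ages[0] or age_months > ages[-1]:
            raise ValueError(
                f"age {age_months} months outside LMS range [{ages[0]}, {ages[-1]}]"
            )
        nearest = int(np.argmin(np.abs(ages - age_months)))
        if abs(ages[nearest] - age_months) <= 0.5:
            row = sub.iloc[nearest]
            return float(row["L"]), float(row["M"]), float(row["S"])
        return tuple(
            float(np.interp(age_months, ages, sub[c].to_numpy(dtype=float)))
            for c in ("L", "M", "S")
        )

    @classmethod
    def from_tsv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def synthetic_lms_reference(
    age_min_months: int = 24, age_max_months: int = 250
) -> LMSReference:
    """Smooth synthetic LMS reference for BMI over childhood.

    A stand-in with the shape of a pediatric growth chart (median BMI
    dipping around age 5 then rising through adolescence, L < 0 right skew);
    it is not the CDC table and carries no real-population meaning.
    """
    rows = []
    for sex, shift in (("male", 0.0), ("female", -0.2)):
        for age in range(age_min_months, age_max_months + 1):
            years = age / 12.0
            m = 15.3 + 0.012 * (years - 5.5) ** 2 + 0.35 * max(0.0, years - 5.5) + shift
            rows.append(
                {
                    "sex": sex,
                    "agemos": float(age),
                    "L": -1.6 + 0.02 * years,
                    "M": m,
                    "S": 0.10 + 0.004 * years,
                }
            )
    return LMSReference(pd.DataFrame(rows))


def lms_zscore(value: float, L: float, M: float, S: float) -> float:
    """z = ((value/M)^L - 1) / (L*S), with the log-limit form as L -> 0."""
    if value <= 0:
        raise ValueError("measurement must be positive")
    if M <= 0 or S <= 0:
        raise ValueError("LMS parameters require M > 0 and S > 0")
    if abs(L) < _LN_EPS:
        return float(np.log(value / M) / S)
    return float(((value / M) ** L - 1.0) / (L * S))


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement value at z-score ``z`` under an LMS reference row."""
    if abs(L) < _LN_EPS:
        return float(M * np.exp(S * z))
    return float(M * (1.0 + L * S * z) ** (1.0 / L))


def bmi_zscore(
    bmi: float, age_months: float, sex: str, ref: LMSReference
) -> float:
    """Growth-reference BMI z-score via the LMS method."""
    L, M, S = ref.lookup(sex, age_months)
    return lms_zscore(bmi, L, M, S)


def bmi_zscore_bulk(bmi, age_months, sex, ref: LMSReference) -> np.ndarray:
    """Vectorized :func:`bmi_zscore` with the same lookup rule.

    The nearest tabulated age is used within 0.5 month, otherwise L, M and S
    are interpolated linearly in age; ages outside the reference range raise.
    """
    bmi = np.asarray(bmi, dtype=float)
    age_months = np.asarray(age_months, dtype=float)
    sex = np.asarray(sex)
    if (bmi <= 0).any():
        raise ValueError("measurement must be positive")
    out = np.empty(bmi.shape)
    for s in pd.unique(sex):
        mask = sex == s
        sub = ref.table[ref.table["sex"] == s]
        if sub.empty:
            raise ValueError(f"no LMS rows for sex {s!r}")
        ages = sub["agemos"].to_numpy(dtype=float)
        a = age_months[mask]
        if (a < ages[0]).any() or (a > ages[-1]).any():
            raise ValueError("age outside LMS reference range")
        lms = {c: np.interp(a, ages, sub[c].to_numpy(dtype=float)) for c in ("L", "M", "S")}
        # snap to the nearest tabulated row when within half a month
        idx = np.clip(np.searchsorted(ages, a), 1, len(ages) - 1)
        nearest = np.where(np.abs(ages[idx - 1] - a) <= np.abs(ages[idx] - a), idx - 1, idx)
        snap = np.abs(ages[nearest] - a) <= 0.5
        for c in ("L", "M", "S"):
            col = sub[c].to_numpy(dtype=float)
            lms[c] = np.where(snap, col[nearest], lms[c])
        L, M, S = lms["L"], lms["M"], lms["S"]
        b = bmi[mask]
        z = np.where(
            np.abs(L) < _LN_EPS,
            np.log(b / M) / S,
            (np.power(b / M, L) - 1.0) / (L * S),
        )
        out[mask] = z
    return out


def puberty_binary(tanner: int) -> str:
    """Tanner stage 1 -> pre-pubertal; stages 2-5 -> pubertal."""
    tanner = int(tanner)
    if not 1 <= tanner <= 5:
        raise ValueError(f"Tanner stage must be in 1..5, got {tanner}")
    return PRE_PUBERTAL if tanner == 1 else PUBERTAL


def inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Non-missing entries are replaced by Phi^-1((r - 3/8)/(n + 1/4)) where r
    is the average rank (ties averaged) and n the non-missing count; NaN
    entries stay NaN. Strictly monotone in the input among untied values.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("inverse_normal needs at least 2 non-missing values")
    ranks = rankdata(x[obs], method="average")
    out[obs] = norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def binarize_by_median(values) -> np.ndarray:
    """Split at the sample median: >= median -> 1 (high), < median -> 0 (low).

    The median is taken over non-missing values; missing stays NaN. With
    heavy ties at the median the split can be unbalanced (all-equal input
    maps entirely to high) — a direct consequence of the >=-median rule.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if not obs.any():
        raise ValueError("binarize_by_median needs at least one non-missing value")
    med = float(np.median(x[obs]))
    out = np.full(x.shape, np.nan)
    out[obs] = (x[obs] >= med).astype(float)
    return out


def classify_activity_minutes(ee) -> dict:
    """Classify per-minute energy expenditure (kcal/kg/min) into intensities.

    Classes (lower bound inclusive): sedentary < 0.01 <= light < 0.04 <=
    moderate < 0.10 <= vigorous. Returns per-class minute counts plus
    ``mvpa_minutes`` = moderate + vigorous.
    """
    x = np.asarray(ee, dtype=float)
    if (x < 0).any():
        raise ValueError("energy expenditure must be non-negative")
    t1, t2, t3 = ACTIVITY_THRESHOLDS
    counts = {
        "sedentary": int((x < t1).sum()),
        "light": int(((x >= t1) & (x < t2)).sum()),
        "moderate": int(((x >= t2) & (x < t3)).sum()),
        "vigorous": int((x >= t3).sum()),
    }
    counts["mvpa_minutes"] = counts["moderate"] + counts["vigorous"]
    return counts
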