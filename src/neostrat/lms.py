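"""LMS growth-reference z-scores.

The LMS method summarises a growth reference by three age- and sex-specific
curves: the Box-Cox power L, the median M and the coefficient of variation S.
A measurement ``w`` converts to a z-score via

    z = ((w / M)**L - 1) / (L * S)     if L != 0
    z = log(w / M) / S                 if L == 0

Reference tables are pluggable: any table keyed by (sex, gestational age in
completed weeks, postnatal age in days) with columns L, M, S works.  A
synthetic reference covering the very-preterm range is provided for simulated
cohorts; it is a smooth stand-in, not a published growth standard.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REFERENCE_KEY = ["sex", "ga_weeks", "postnatal_day"]
REFERENCE_COLS = REFERENCE_KEY + ["L", "M", "S"]


def lms_zscore(weight, L, M, S):
    """Convert weight(s) to z-score(s) given LMS reference values.

    Parameters are scalars or broadcastable arrays; ``weight`` and ``M`` must
    be positive, ``S`` positive.  Returns NaN where any input is NaN.
    """
    weight = np.asarray(weight, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(weight[np.isfinite(weight)] <= 0):
        raise ValueError("weight must be positive")
    if np.any(M[np.isfinite(M)] <= 0) or np.any(S[np.isfinite(S)] <= 0):
        raise ValueError("M and S reference values must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = weight / M
        z = np.where(
            L == 0.0,
            np.log(ratio) / S,
            (np.power(ratio, L) - 1.0) / (L * S),
        )
    if z.ndim == 0:
        return float(z)
    return z


def lms_weight(z, L, M, S):
    """Invert the LMS transform: the weight whose z-score is ``z``."""
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    z = np.asarray(z, dtype=float)
    w = np.where(
        L == 0.0,
        M * np.exp(S * z),
        M * np.power(1.0 + L * S * z, 1.0 / np.where(L == 0.0, 1.0, L)),
    )
    if w.ndim == 0:
        return float(w)
    return w


def synthetic_lms_reference(max_postnatal_day: int = 250) -> pd.DataFrame:
    """Smooth synthetic LMS reference for gestational ages 22-31 weeks.

    Median weight follows an exponential intrauterine-style curve from a
    GA-dependent birth weight; boys run ~4% heavier.  L and S are held at
    plausible constants.  Synthetic: for simulation and testing only.
    """
    rows = []
    days = np.arange(0, max_postnatal_day + 1)
    for sex in (0, 1):  # 0 boy, 1 girl
        for ga in range(22, 32):
            birth_m = 1000.0 * np.exp(0.16 * (ga - 28))
            m = birth_m * np.exp(0.012 * days)
            factor = 1.04 if sex == 0 else 1.0
            for d, mv in zip(days, m):
                rows.append((sex, ga, int(d), 0.8, factor * mv, 0.11))
    return pd.DataFrame(rows, columns=REFERENCE_COLS)


class LMSReference:
    """Lookup wrapper around an LMS reference table.

    Missing (sex, GA, postnatal day) keys yield NaN z-scores rather than
    errors, so out-of-range stays degrade gracefully.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(REFERENCE_COLS) - set(table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        self._table = table.set_index(REFERENCE_KEY)[["L", "M", "S"]].sort_index()

    @classmethod
    def synthetic(cls, max_postnatal_day: int = 250) -> "LMSReference":
        return cls(synthetic_lms_reference(max_postnatal_day))

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def lookup(self, sex, ga_weeks, postnatal_day):
        """Return (L, M, S) for a single key, or (nan, nan, nan) if absent."""
        try:
            row = self._table.loc[(int(sex), int(ga_weeks), int(postnatal_day))]
        except KeyError:
            return (np.nan, np.nan, np.nan)
        return (float(row["L"]), float(row["M"]), float(row["S"]))

    def zscore(self, weight, sex, ga_weeks, postnatal_day):
        L, M, S = self.lookup(sex, ga_weeks, postnatal_day)
        if not np.isfinite(M):
            return np.nan
        return lms_zscore(weight, L, M, S)

    def weight(self, z, sex, ga_weeks, postnatal_day):
        L, M, S = self.lookup(sex, ga_weeks, postnatal_day)
        if not np.isfinite(M):
            return np.nan
        return lms_weight(z, L, M, S)

    def to_csv(self, path) -> None:
        self._table.reset_index().to_csv(path, index=False)
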