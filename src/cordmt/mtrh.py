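"""The MTR homogeneity index (MTRh).

MTRh summarizes the dispersion of the tract MTR values of one slice in a
participant-invariant way: the (bias-corrected) standard deviation of the
tract values normalized by their root sum of squares,

    MTRh = sqrt(N / (N - 1)) * sqrt( Σ(x_A - x̄)² / Σ x_A² )

where x_A are the tract MTR values, x̄ their mean and N the number of tracts
(8 in the standard analysis). Dividing by Σx² removes the participant- and
slice-specific MT signal scale, so MTRh is invariant to rescaling all tracts
by a common factor. It is 0 when all tracts agree, grows with tract-to-tract
inhomogeneity, and for nonnegative inputs is bounded by 1 (attained by a
single nonzero tract). Algebraically this is the fractional-anisotropy
formula of diffusion imaging applied to the tract-value vector.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: columns of the MTRh record table
MTRH_COLUMNS = ("subject_id", "level", "mtrh", "n_tracts_used", "flag")


def compute_mtrh(values) -> float:
    """MTRh of a vector of tract MTR values.

    Requires at least 2 finite values. Returns 0.0 by convention when all
    values are zero (Σx² = 0). Negative inputs are allowed mathematically but
    void the [0, 1] bound, so they raise a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("compute_mtrh needs a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("compute_mtrh requires finite values")
    if (x < 0).any():
        warnings.warn(
            "negative tract values: the [0, 1] MTRh bound no longer holds",
            stacklevel=2,
        )
    n = x.size
    ss = float((x**2).sum())
    if ss == 0.0:
        return 0.0
    dev = float(((x - x.mean()) ** 2).sum())
    return float(np.sqrt(n / (n - 1)) * np.sqrt(dev / ss))


def mtrh_table(
    tract_table: pd.DataFrame,
    policy: str = "strict",
    min_tracts: int = 6,
) -> pd.DataFrame:
    """One MTRh record per (subject, level) from a long tract MTR table.

    ``strict`` (default) requires all 8 tract values to be present, matching
    the standard N_A = 8 analysis; slices with any missing tract get a
    missing MTRh and an ``insufficient_tracts`` flag. ``relaxed`` recomputes
    with N_A equal to the available count when at least ``min_tracts`` values
    are present. The choice of extraction method is whatever populated
    ``mtr_percent``; it is not re-examined here.
    """
    if policy not in ("strict", "relaxed"):
        raise ValueError(f"unknown policy {policy!r}")
    required = tract_table["tract"].nunique() if len(tract_table) else 8
    rows = []
    for (sid, level), grp in tract_table.groupby(["subject_id", "level"], sort=True):
        vals = grp["mtr_percent"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        n_avail = finite.size
        need = required if policy == "strict" else min_tracts
        if n_avail >= need and n_avail >= 2:
            rows.append(
                {
                    "subject_id": sid,
                    "level": level,
                    "mtrh": compute_mtrh(finite),
                    "n_tracts_used": int(n_avail),
                    "flag": "ok",
                }
            )
        else:
            rows.append(
                {
                    "subject_id": sid,
                    "level": level,
                    "mtrh": np.nan,
                    "n_tracts_used": int(n_avail),
                    "flag": "insufficient_tracts",
                }
            )
    return pd.DataFrame(rows, columns=list(MTRH_COLUMNS))
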