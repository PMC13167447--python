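"""Paired comparisons and cross-slice summaries.

Two-sided paired t-tests are used throughout, matching the study design
(before/after conditions measured in the same slices).  The p-value is
computed from the regularized incomplete beta function,

    p = I_{df/(df + t^2)}(df/2, 1/2),

which is the exact tail relation of Student's t distribution; no external
test routine is involved.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc

__all__ = ["PairedSample", "paired_t_test", "t_sf", "summarize"]


@dataclass
class PairedSample:
    """Matched before/after measurements across slices."""

    before: np.ndarray
    after: np.ndarray

    def __post_init__(self) -> None:
        self.before = np.asarray(self.before, dtype=float)
        self.after = np.asarray(self.after, dtype=float)
        if self.before.shape != self.after.shape:
            raise ValueError("before/after must have equal lengths")
        if self.n < 2:
            raise ValueError(f"need at least 2 paired observations, got {self.n}")

    @property
    def n(self) -> int:
        return self.before.size

    @property
    def differences(self) -> np.ndarray:
        return self.after - self.before


def t_sf(t: float, df: int) -> float:
    """Two-sided tail probability of Student's t via the incomplete beta."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def paired_t_test(sample: PairedSample) -> tuple[float, int, float]:
    """Two-sided paired t-test: returns ``(t, df, p)``.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with the sample SD (n-1 denominator)
    of the paired differences ``d``.  Zero-variance differences make the
    statistic undefined and raise.
    """
    d = sample.differences
    n = sample.n
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise ValueError("paired differences have zero variance; t statistic undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    return t, df, t_sf(t, df)


def summarize(values_by_parameter: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean +/- sample SD per parameter across slices (NaN-aware)."""
    rows = []
    for name, values in values_by_parameter.items():
        arr = np.asarray(list(values), dtype=float)
        arr = arr[np.isfinite(arr)]
        rows.append(
            {
                "parameter": name,
                "n": arr.size,
                "mean": float(arr.mean()) if arr.size else np.nan,
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
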