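"""Group-level summaries and tests.

Normality is assessed with the Jarque-Bera test; normally distributed
group values are reported as mean ± SD and compared with a (Welch)
two-sample t-test at alpha = 0.05.  When Jarque-Bera rejects, a warning is
emitted and a Mann-Whitney U fallback can be requested — the fallback goes
beyond the original protocol and is labeled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .io import SheathQuantError

logger = logging.getLogger("sheathquant.stats")

ALPHA = 0.05


def jarque_bera(values: Sequence[float]) -> Tuple[float, float]:
    """Jarque-Bera normality statistic and its chi2(2) p-value.

    JB = n/6 * (S^2 + (K - 3)^2 / 4) with sample skewness S = m3 / m2^1.5
    and kurtosis K = m4 / m2^2 (population moment estimators).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        raise SheathQuantError(f"Jarque-Bera needs n >= 8, got {n}")
    m = x - x.mean()
    m2 = np.mean(m**2)
    if m2 == 0:
        raise SheathQuantError("degenerate sample (zero variance)")
    s = np.mean(m**3) / m2**1.5
    k = np.mean(m**4) / m2**2
    jb = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
    return float(jb), float(sps.chi2.sf(jb, df=2))


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> Tuple[float, float]:
    """Welch (default) or pooled two-sample t-test; two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SheathQuantError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise SheathQuantError("both groups have zero variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def percent_of_control(
    treated: Sequence[float],
    control: Sequence[float],
    paired: bool = False,
) -> Tuple[float, float]:
    """Treated response as mean ± SD percent of control.

    Default (unpaired): each treated value is divided by the control group
    mean; the SD is that of the resulting percentages.  ``paired=True``
    divides elementwise (groups must match in length).
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if paired:
        if treated.shape != control.shape:
            raise SheathQuantError("paired mode needs equal-length groups")
        if np.any(control == 0):
            raise SheathQuantError("paired control contains zeros")
        ratios = treated / control * 100.0
    else:
        cm = control.mean()
        if cm == 0:
            raise SheathQuantError("control mean is zero")
        ratios = treated / cm * 100.0
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return float(ratios.mean()), sd


@dataclass
class GroupSummary:
    """One group's report line: n, mean ± SD, and JB normality p."""

    label: str
    values: np.ndarray
    unit: str = "vessels"  # countable unit carried as metadata (vessels/cells)

    n: int = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)
    jb_stat: float = field(init=False)
    normality_p: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n = self.values.size
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=1)) if self.n > 1 else 0.0
        self.jb_stat, self.normality_p = jarque_bera(self.values)

    def __str__(self) -> str:
        return f"{self.label}: {self.mean:.2g} ± {self.sd:.2g} (n={self.n} {self.unit})"


def compare_groups(
    a: GroupSummary,
    b: GroupSummary,
    nonparametric_fallback: bool = False,
) -> dict:
    """Compare two summarized groups; Welch t by default.

    If either group fails Jarque-Bera normality (p < alpha) a warning is
    logged; with ``nonparametric_fallback`` a Mann-Whitney U test is run
    instead (beyond the original protocol, labeled in the output).
    """
    non_normal = a.normality_p < ALPHA or b.normality_p < ALPHA
    if non_normal:
        logger.warning(
            "Jarque-Bera rejects normality (p=%.3g / %.3g)",
            a.normality_p, b.normality_p,
        )
    if non_normal and nonparametric_fallback:
        u, p = sps.mannwhitneyu(a.values, b.values, alternative="two-sided")
        return {
            "test": "mann-whitney (fallback beyond protocol)",
            "stat": float(u),
            "p": float(p),
            "significant": bool(p < ALPHA),
        }
    t, p = two_sample_ttest(a.values, b.values)
    return {"test": "welch-t", "stat": t, "p": p, "significant": bool(p < ALPHA)}
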