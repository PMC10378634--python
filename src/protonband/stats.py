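"""Statistical comparisons on pipeline outputs.

Classical equal-variance Student's t-tests (a Welch option sits behind a
flag), following the source study's choices: fractions are pooled as
independent observations and no multiple-testing correction is applied —
both known limitations, documented here rather than fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSampleError, ValidationError

__all__ = [
    "StatResult",
    "two_sample_ttest",
    "paired_one_sided_ttest",
    "shift_comparisons",
]

_SIDED = {"two": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class StatResult:
    name: str
    groups: tuple[str, str]
    statistic: float
    df: float
    p_value: float
    sided: str
    paired: bool
    n: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "groups": list(self.groups),
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "sided": self.sided,
            "paired": self.paired,
            "n": list(self.n),
        }


def _clean(sample, label: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size < 2:
        raise DegenerateSampleError(label, f"needs n >= 2, got n={arr.size}")
    if not np.all(np.isfinite(arr)):
        raise DegenerateSampleError(label, "contains non-finite values")
    return arr


def two_sample_ttest(
    a,
    b,
    sided: str = "two",
    equal_var: bool = True,
    name: str = "two_sample_t",
    groups: tuple[str, str] = ("a", "b"),
) -> StatResult:
    """Two-sample Student's t-test (pooled variance unless ``equal_var=False``).

    ``sided='greater'`` tests mean(a) > mean(b); ``'less'`` the reverse.
    """
    if sided not in _SIDED:
        raise ValidationError(f"sided must be one of {sorted(_SIDED)}, got {sided!r}")
    xa, xb = _clean(a, groups[0]), _clean(b, groups[1])
    if xa.var(ddof=1) == 0.0 and xb.var(ddof=1) == 0.0:
        raise DegenerateSampleError(
            f"{groups[0]}+{groups[1]}", "zero pooled variance (both samples constant)"
        )
    res = sps.ttest_ind(xa, xb, equal_var=equal_var, alternative=_SIDED[sided])
    df = float(res.df) if hasattr(res, "df") else float(xa.size + xb.size - 2)
    return StatResult(
        name=name,
        groups=groups,
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        sided=sided,
        paired=False,
        n=(xa.size, xb.size),
    )


def paired_one_sided_ttest(
    x,
    y,
    alternative: str = "less",
    name: str = "paired_one_sided_t",
    groups: tuple[str, str] = ("x", "y"),
) -> StatResult:
    """Paired t-test on differences x - y with a one-sided alternative.

    ``alternative='less'`` (default) tests mean(x) < mean(y).  All-zero
    differences are the exact null midpoint and return t = 0, p = 0.5
    (scipy yields NaN there).
    """
    if alternative not in ("less", "greater"):
        raise ValidationError(f"alternative must be 'less' or 'greater', got {alternative!r}")
    xx = np.asarray(x, dtype=float).ravel()
    yy = np.asarray(y, dtype=float).ravel()
    if xx.size != yy.size:
        raise ValidationError(f"paired samples differ in length: {xx.size} vs {yy.size}")
    xx, yy = _clean(xx, groups[0]), _clean(yy, groups[1])
    diffs = xx - yy
    n = diffs.size
    if np.all(diffs == 0.0):
        return StatResult(
            name=name,
            groups=groups,
            statistic=0.0,
            df=float(n - 1),
            p_value=0.5,
            sided=alternative,
            paired=True,
            n=(n, n),
        )
    if diffs.std(ddof=1) == 0.0:
        # constant nonzero difference: t is infinite, p degenerates to 0 or 1
        sign = np.sign(diffs[0])
        t = float(sign * np.inf)
        p = 0.0 if (sign < 0) == (alternative == "less") else 1.0
        return StatResult(name, groups, t, float(n - 1), p, alternative, True, (n, n))
    res = sps.ttest_rel(xx, yy, alternative=alternative)
    return StatResult(
        name=name,
        groups=groups,
        statistic=float(res.statistic),
        df=float(n - 1),
        p_value=float(res.pvalue),
        sided=alternative,
        paired=True,
        n=(n, n),
    )


def shift_comparisons(
    shift_log: pd.DataFrame,
    patient_classes: Mapping[str, str],
    class_pair: tuple[str, str] = ("PO", "PNN"),
) -> list[StatResult]:
    """Cohort-level comparisons of daily shift magnitudes.

    Expects a log with columns ``patient``, ``fraction`` and ``magnitude_mm``
    (per-fraction translation norms).  Runs (1) a two-sample test of
    magnitudes between the two classes and (2) a paired test per patient of
    first-half vs second-half mean magnitude.  A class with fewer than 2
    patients triggers a warning and that test is skipped.
    """
    required = {"patient", "fraction", "magnitude_mm"}
    if not required.issubset(shift_log.columns):
        raise ValidationError(f"shift log needs columns {sorted(required)}")
    df = shift_log.copy()
    df["patient_class"] = df["patient"].map(dict(patient_classes))
    results: list[StatResult] = []

    ca, cb = class_pair
    counts = df.groupby("patient_class")["patient"].nunique()
    if counts.get(ca, 0) >= 2 and counts.get(cb, 0) >= 2:
        results.append(
            two_sample_ttest(
                df.loc[df["patient_class"] == ca, "magnitude_mm"],
                df.loc[df["patient_class"] == cb, "magnitude_mm"],
                sided="two",
                name="shift_magnitude_class",
                groups=class_pair,
            )
        )
    else:
        warnings.warn(
            f"need >= 2 patients per class for the {ca} vs {cb} shift test; skipped"
        )

    firsts, seconds = [], []
    for _, grp in df.sort_values("fraction").groupby("patient"):
        mags = grp["magnitude_mm"].to_numpy()
        half = len(mags) // 2
        if half < 1:
            continue
        firsts.append(float(mags[:half].mean()))
        seconds.append(float(mags[half:].mean()))
    if len(firsts) >= 2:
        xa, xb = np.asarray(firsts), np.asarray(seconds)
        res = sps.ttest_rel(xa, xb, alternative="two-sided")
        results.append(
            StatResult(
                name="shift_magnitude_halves",
                groups=("first_half", "second_half"),
                statistic=float(res.statistic),
                df=float(len(firsts) - 1),
                p_value=float(res.pvalue),
                sided="two",
                paired=True,
                n=(len(firsts), len(seconds)),
            )
        )
    else:
        warnings.warn("need >= 2 patients for the half-course shift test; skipped")
    return results
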