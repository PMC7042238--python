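"""Group comparisons: pooled t-tests and one-way ANOVA with Bonferroni
post-hoc tests versus control groups, plus mean +/- SEM summaries.

The ANOVA is the classical fixed-effects between/within decomposition,
F = MSB / MSW with p from the F distribution.  Post-hoc comparisons are
two-sample pooled-variance Student t-tests (each pair pools only its
own two groups, the classical Bonferroni post-test), multiplied by the
size m of the declared comparison family and capped at 1.  The family
defaults to all pairs, or all pairs involving a named control group
when one is given — the convention of comparing every treatment to the
lesion-only group and the lesion-only group to naive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosthocComparison",
    "one_way_anova",
    "t_test",
    "sem_summary",
    "significance_stars",
]


@dataclass(frozen=True)
class PosthocComparison:
    pair: tuple[str, str]
    t: float
    raw_p: float
    bonferroni_p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.bonferroni_p)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_value: float
    posthoc: list[PosthocComparison]
    n_comparisons: int


def significance_stars(p: float) -> str:
    """Conventional annotation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def t_test(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def one_way_anova(
    data: dict[str, np.ndarray],
    control: str | None = None,
    comparisons: list[tuple[str, str]] | None = None,
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over named groups.

    ``comparisons`` fixes the post-hoc family explicitly; otherwise all
    pairs involving ``control`` (when given) or all pairs are compared.
    Bonferroni multiplies each raw p by the family size m.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs n >= 2 for a variance estimate")
    names = list(groups)
    all_vals = np.concatenate([groups[k] for k in names])
    n_total = len(all_vals)
    k = len(names)
    if n_total <= k:
        raise ValueError("total n must exceed the number of groups")

    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n_total - k
    msw = ss_within / df_w
    if msw == 0:
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df_b) / msw
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0

    if comparisons is None:
        if control is not None:
            if control not in groups:
                raise ValueError(f"control group {control!r} not in data")
            comparisons = [(g, control) for g in names if g != control]
        else:
            comparisons = [
                (names[i], names[j]) for i in range(k) for j in range(i + 1, k)
            ]
    m = len(comparisons)
    posthoc = []
    for ga, gb in comparisons:
        t, raw = t_test(groups[ga], groups[gb])
        posthoc.append(
            PosthocComparison((ga, gb), t, raw, min(1.0, raw * m))
        )
    return AnovaResult(float(f), df_b, df_w, p, posthoc, m)


def sem_summary(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD / sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need n >= 2 for a SEM")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))
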