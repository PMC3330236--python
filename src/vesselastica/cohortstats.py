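"""Group-comparison protocol for cohort tables.

The comparison rule mirrors the classic two-stage practice: screen the
groups for equality of variances first, then pick the test.

* two groups — equal variances: unpaired Student's t-test; unequal:
  Mann–Whitney U. Summaries are mean ± SEM.
* three or more groups — equal variances: one-way ANOVA with Dunnett
  many-to-one post-hoc comparisons against a named baseline group;
  unequal: Kruskal–Wallis (omnibus only).

The variance screen (Levene by default, Bartlett available) and its alpha
are explicit, configurable parameters, and every result records which screen
outcome produced which test, so a comparison is fully reproducible from its
recorded inputs. The automatic routing can be overridden per call
(``route='anova-dunnett'`` or ``route='kruskal'``) when an analysis plan
fixes the test a priori.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["ComparisonResult", "compare_two", "compare_many"]

_VARIANCE_TESTS = {"levene": stats.levene, "bartlett": stats.bartlett}


@dataclass
class ComparisonResult:
    """Outcome of one dispatched comparison.

    ``summaries`` maps each group label to {mean, sem, n}; ``posthoc`` (only
    on the ANOVA + Dunnett route) is one dict per non-baseline group with its
    adjusted p-value and significance flag.
    """

    groups: list
    test: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    summaries: dict
    variance_test: str
    variance_p: float
    route: str
    baseline: object = None
    posthoc: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "groups": [str(g) for g in self.groups],
            "test": self.test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "alpha": self.alpha,
            "significant": bool(self.significant),
            "summaries": {str(k): v for k, v in self.summaries.items()},
            "variance_test": self.variance_test,
            "variance_p": float(self.variance_p),
            "route": self.route,
            "baseline": None if self.baseline is None else str(self.baseline),
            "posthoc": self.posthoc,
        }


def _summarize(label, x) -> dict:
    x = np.asarray(x, dtype=float)
    return {
        "mean": float(np.mean(x)),
        "sem": float(np.std(x, ddof=1) / np.sqrt(len(x))),
        "n": int(len(x)),
    }


def _screen(samples, variance_test: str, alpha: float) -> tuple[float, bool]:
    """Equality-of-variances p-value and the 'variances equal' verdict."""
    if variance_test not in _VARIANCE_TESTS:
        raise ValidationError(f"variance_test: unknown '{variance_test}'")
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = _VARIANCE_TESTS[variance_test](*samples)
    if not np.isfinite(p):  # e.g. all-constant groups: no evidence of inequality
        return 1.0, True
    return float(p), bool(p >= alpha)


def compare_two(
    group_a,
    group_b,
    labels: tuple = ("group_a", "group_b"),
    alpha: float = 0.05,
    variance_test: str = "levene",
    variance_alpha: float | None = None,
) -> ComparisonResult:
    """Two-group comparison with variance-screened test selection.

    Equal variances (screen p >= alpha) route to the unpaired Student's
    t-test; unequal variances to the Mann–Whitney U test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("compare_two: each group needs n >= 3")
    v_alpha = alpha if variance_alpha is None else variance_alpha
    var_p, equal = _screen([a, b], variance_test, v_alpha)
    if equal:
        test = "t"
        with np.errstate(invalid="ignore"):
            stat, p = stats.ttest_ind(a, b, equal_var=True)
        if not np.isfinite(p):  # two identical constant samples
            stat, p = 0.0, 1.0
    else:
        test = "mann-whitney"
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        groups=list(labels),
        test=test,
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
        summaries={labels[0]: _summarize(labels[0], a), labels[1]: _summarize(labels[1], b)},
        variance_test=variance_test,
        variance_p=var_p,
        route="auto",
    )


def compare_many(
    groups: dict,
    baseline=None,
    alpha: float = 0.05,
    variance_test: str = "levene",
    variance_alpha: float | None = None,
    route: str = "auto",
    random_state: int = 0,
) -> ComparisonResult:
    """Many-group comparison: ANOVA + Dunnett vs baseline, or Kruskal–Wallis.

    ``groups`` maps labels to samples; ``baseline`` names the control group
    for the many-to-one Dunnett comparisons (required on the parametric
    route). ``route`` is 'auto' (variance screen decides), 'anova-dunnett'
    or 'kruskal'. Dunnett p-values come from the multivariate-t distribution,
    evaluated by randomized quadrature; ``random_state`` pins that evaluation
    so identical inputs give identical results.
    """
    if len(groups) < 3:
        raise ValidationError("compare_many: need >= 3 groups")
    if route not in ("auto", "anova-dunnett", "kruskal"):
        raise ValidationError(f"route: unknown '{route}'")
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(s) < 3 for s in samples):
        raise ValidationError("compare_many: each group needs n >= 3")

    v_alpha = alpha if variance_alpha is None else variance_alpha
    var_p, equal = _screen(samples, variance_test, v_alpha)
    parametric = equal if route == "auto" else (route == "anova-dunnett")

    summaries = {k: _summarize(k, s) for k, s in zip(labels, samples)}
    posthoc: list = []
    if parametric:
        if baseline is None or baseline not in groups:
            raise ValidationError(
                "baseline: a valid baseline group id is required for the "
                "ANOVA + Dunnett route"
            )
        with np.errstate(invalid="ignore"):
            stat, p = stats.f_oneway(*samples)
        if not np.isfinite(p):
            stat, p = 0.0, 1.0
        others = [k for k in labels if k != baseline]
        dn = stats.dunnett(*[np.asarray(groups[k], dtype=float) for k in others],
                           control=np.asarray(groups[baseline], dtype=float),
                           random_state=np.random.default_rng(random_state))
        for k, stat_k, p_k in zip(others, np.atleast_1d(dn.statistic),
                                  np.atleast_1d(dn.pvalue)):
            posthoc.append({
                "group": str(k),
                "vs": str(baseline),
                "statistic": float(stat_k),
                "p_value": float(p_k),
                "significant": bool(p_k < alpha),
            })
        test = "anova+dunnett"
    else:
        stat, p = stats.kruskal(*samples)
        test = "kruskal-wallis"

    return ComparisonResult(
        groups=labels,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
        summaries=summaries,
        variance_test=variance_test,
        variance_p=var_p,
        route=route,
        baseline=baseline,
        posthoc=posthoc,
    )
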