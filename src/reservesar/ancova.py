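"""Cross-group comparison of SAR parameters by analysis of covariance.

Two nested-model F-tests on the pooled log-log data with a group factor:

* slope homogeneity — separate slopes + intercepts vs common slope +
  separate intercepts (tests whether z differs among groups);
* intercept differences — common slope + separate intercepts vs a single
  line (tests whether c differs among groups, given a shared z).

Both are incremental F-tests, F = ((RSS_reduced − RSS_full)/Δdf) / MSE_full.
Pairwise intercept contrasts order the groups by species-per-unit-area and
mark statistically indistinguishable neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import GroupDataset
from .sar import fit_ols

#: Predictor shared by all groups in the ANCOVA designs.
_COVARIATE = "log_area"


@dataclass(frozen=True)
class AncovaResult:
    test: str  # "slopes" or "intercepts"
    groups: tuple[str, ...]
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    rss_full: float
    rss_reduced: float
    #: intercept of each group under the constrained (common-slope) model
    group_intercepts: Mapping[str, float]
    common_slope: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    f_statistic: float
    p_value: float
    significant: bool


def _stack(datasets: Sequence[GroupDataset]):
    if len(datasets) < 2:
        raise ValueError("need at least two groups")
    names = [d.group for d in datasets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names in ANCOVA input")
    for d in datasets:
        if d.n < 3:
            raise ValueError(f"group {d.group!r} has fewer than 3 cases")
    x = np.concatenate([np.asarray(d.predictors[_COVARIATE]) for d in datasets])
    y = np.concatenate([np.asarray(d.response) for d in datasets])
    g = np.concatenate([np.full(d.n, i) for i, d in enumerate(datasets)])
    return x, y, g, tuple(names)


def _designs(x, g, n_groups):
    """Dummy-coded designs for the three nested models (no implicit intercept)."""
    dummies = {f"g{i}": (g == i).astype(float) for i in range(n_groups)}
    sep_lines = {**dummies, **{f"x:g{i}": dummies[f"g{i}"] * x for i in range(n_groups)}}
    common_slope = {**dummies, "x": x}
    single_line = {"x": x}  # fit_ols adds the intercept
    return sep_lines, common_slope, single_line


def _incremental_f(rss_full, df_full, rss_red, df_red):
    df_num = df_red - df_full
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_full)
    p = float(stats.f.sf(f, df_num, df_full))
    return float(f), df_num, df_full, p


def _fit_models(datasets: Sequence[GroupDataset]):
    x, y, g, names = _stack(datasets)
    G = len(names)
    sep, common, single = _designs(x, g, G)
    fit_sep = fit_ols(y, sep, include_intercept=False)
    fit_common = fit_ols(y, common, include_intercept=False)
    fit_single = fit_ols(y, single, include_intercept=True)
    return names, len(y), fit_sep, fit_common, fit_single


def test_slope_homogeneity(datasets: Sequence[GroupDataset]) -> AncovaResult:
    """F-test of the slope-by-group interaction (do z-values differ?)."""
    names, n, fit_sep, fit_common, _ = _fit_models(datasets)
    f, df_num, df_den, p = _incremental_f(
        fit_sep.rss, fit_sep.df_resid, fit_common.rss, fit_common.df_resid
    )
    return AncovaResult(
        test="slopes", groups=names, f_statistic=f, df_num=df_num,
        df_den=df_den, p_value=p, rss_full=fit_sep.rss,
        rss_reduced=fit_common.rss,
        group_intercepts={nm: float(fit_common.params[f"g{i}"]) for i, nm in enumerate(names)},
        common_slope=float(fit_common.params["x"]), n=n,
    )


def test_intercept_differences(datasets: Sequence[GroupDataset]) -> AncovaResult:
    """F-test of the group main effect under a common slope (do c-values differ?)."""
    names, n, _, fit_common, fit_single = _fit_models(datasets)
    f, df_num, df_den, p = _incremental_f(
        fit_common.rss, fit_common.df_resid, fit_single.rss, fit_single.df_resid
    )
    return AncovaResult(
        test="intercepts", groups=names, f_statistic=f, df_num=df_num,
        df_den=df_den, p_value=p, rss_full=fit_common.rss,
        rss_reduced=fit_single.rss,
        group_intercepts={nm: float(fit_common.params[f"g{i}"]) for i, nm in enumerate(names)},
        common_slope=float(fit_common.params["x"]), n=n,
    )


def pairwise_intercepts(
    datasets: Sequence[GroupDataset],
    alpha: float = 0.05,
    *,
    holm: bool = False,
) -> tuple[list[PairwiseComparison], list[str], str]:
    """All pairwise intercept ANCOVAs plus a descending c-value ordering.

    Returns ``(comparisons, ordering, ordering_string)`` where ``ordering``
    lists the groups by their own SAR intercept log10(c) (most species per
    unit area first — the scale on which c-values are reported) and
    ``ordering_string`` joins neighbours with ``">"`` when their pairwise
    intercept test is significant at ``alpha`` and ``"~"`` when not.

    Raw p-values are reported; ``holm=True`` applies a Holm step-down
    correction before flagging significance (off by default).
    """
    if len(datasets) < 2:
        raise ValueError("need at least two groups")
    by_name = {d.group: d for d in datasets}
    own_intercept = {
        d.group: float(
            fit_ols(d.response, {_COVARIATE: d.predictors[_COVARIATE]}).params[
                "intercept"
            ]
        )
        for d in datasets
    }
    ordering = sorted(by_name, key=own_intercept.__getitem__, reverse=True)

    pairs, raw_p = [], []
    names = list(by_name)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = test_intercept_differences([by_name[a], by_name[b]])
            pairs.append((a, b, res.f_statistic, res.p_value))
            raw_p.append(res.p_value)

    if holm:
        order = np.argsort(raw_p)
        m = len(raw_p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw_p[idx])
            adj[idx] = min(running, 1.0)
        sig = [adj[i] < alpha for i in range(m)]
    else:
        sig = [p < alpha for p in raw_p]

    comparisons = [
        PairwiseComparison(a, b, f, p, s)
        for (a, b, f, p), s in zip(pairs, sig)
    ]
    sig_of = {frozenset((c.group_a, c.group_b)): c.significant for c in comparisons}
    parts = [ordering[0]]
    for prev, nxt in zip(ordering, ordering[1:]):
        sep = " > " if sig_of[frozenset((prev, nxt))] else " ~ "
        parts.append(sep + nxt)
    return comparisons, ordering, "".join(parts)
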