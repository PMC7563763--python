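"""Exhaustive all-subsets OLS with AICc ranking.

Every subset of the candidate predictors (including the intercept-only
model) is fitted on the same complete-case rows of one group, ranked by
ascending AICc, and models within a ΔAICc threshold (default 2) of the best
are reported as equally supported.  When the best model retains area along
with other covariates, its area coefficient serves as the z-value for
extinction projection: the influence of geography and orography is held
fixed while area shrinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .data import PREDICTORS, GroupDataset
from .sar import OlsFit, fit_ols

_MAX_PREDICTORS = 12  # combinatorial guard: 2^12 = 4096 candidates


def enumerate_subsets(predictors: Sequence[str]) -> list[tuple[str, ...]]:
    """All subsets of ``predictors``, ordered by size then lexicographically.

    Includes the empty (intercept-only) subset.  Refuses more than
    ``_MAX_PREDICTORS`` names.
    """
    names = list(predictors)
    if not names:
        raise ValueError("need at least one predictor")
    if len(set(names)) != len(names):
        raise ValueError("duplicate predictor names")
    if len(names) > _MAX_PREDICTORS:
        raise ValueError(
            f"{len(names)} predictors would enumerate {2 ** len(names)} models; "
            f"limit is {_MAX_PREDICTORS}"
        )
    out: list[tuple[str, ...]] = []
    for size in range(len(names) + 1):
        out.extend(sorted(combinations(sorted(names), size)))
    return out


@dataclass(frozen=True)
class CandidateModel:
    """One fitted predictor subset in an all-subsets search."""

    predictors: tuple[str, ...]
    fit: OlsFit
    aicc: float
    delta_aicc: float
    r_squared_adj: float

    @property
    def df(self) -> int:
        """Total estimated parameters: coefficients + intercept + residual variance."""
        return len(self.predictors) + 2


@dataclass(frozen=True)
class ModelSelectionResult:
    group: str
    candidates: tuple[CandidateModel, ...]  # ascending AICc
    best_set: tuple[CandidateModel, ...]  # delta_aicc <= threshold
    threshold: float
    dropped: tuple[tuple[str, ...], ...]  # subsets with undefined AICc

    @property
    def best(self) -> CandidateModel:
        return self.candidates[0]


def select_models(
    dataset: GroupDataset,
    predictors: Sequence[str] = PREDICTORS,
    *,
    threshold: float = 2.0,
) -> ModelSelectionResult:
    """Fit all predictor subsets for one group and rank them by AICc.

    Every candidate is fitted on the identical complete-case rows, a
    requirement for AICc comparability.  Subsets whose AICc is undefined
    (n ≤ k + 1) are dropped with a warning rather than failing the search;
    exactly collinear subsets are fitted by pseudo-inverse and flagged on
    their :class:`~reservesar.sar.OlsFit`.  Ties in AICc break toward fewer
    predictors, then lexicographic subset order.
    """
    if not dataset.transformed:
        raise ValueError("dataset must be log-transformed before selection")
    missing = [p for p in predictors if p not in dataset.predictors]
    if missing:
        raise KeyError(f"predictors not in dataset: {missing}")

    fitted: list[CandidateModel] = []
    dropped: list[tuple[str, ...]] = []
    for subset in enumerate_subsets(predictors):
        k = len(subset) + 2
        if dataset.n - k - 1 <= 0:
            dropped.append(subset)
            warnings.warn(
                f"group {dataset.group!r}: AICc undefined for subset {subset} "
                f"(n={dataset.n}, k={k}); candidate dropped",
                stacklevel=2,
            )
            continue
        fit = fit_ols(
            dataset.response,
            dataset.predictor_matrix(subset),
            on_singular="pinv",
        )
        fitted.append(
            CandidateModel(
                predictors=subset, fit=fit, aicc=fit.aicc,
                delta_aicc=0.0, r_squared_adj=fit.r_squared_adj,
            )
        )

    fitted.sort(key=lambda c: (c.aicc, len(c.predictors), c.predictors))
    best_aicc = fitted[0].aicc
    ranked = tuple(
        CandidateModel(
            predictors=c.predictors, fit=c.fit, aicc=c.aicc,
            delta_aicc=c.aicc - best_aicc, r_squared_adj=c.r_squared_adj,
        )
        for c in fitted
    )
    best_set = tuple(c for c in ranked if c.delta_aicc <= threshold)
    return ModelSelectionResult(
        group=dataset.group, candidates=ranked, best_set=best_set,
        threshold=threshold, dropped=tuple(dropped),
    )


def area_coefficient_for_projection(
    result: ModelSelectionResult, *, area_name: str = "log_area"
) -> tuple[float, float, tuple[CandidateModel, ...]]:
    """The best model's area coefficient, as a z-value for extinction projection.

    Returns ``(coefficient, se, alternatives)``; ``alternatives`` are the
    other equally supported models (ΔAICc ≤ threshold), which may suggest
    different exponents.  Raises if the AICc-best model does not retain area.
    """
    best = result.best
    if area_name not in best.predictors:
        raise ValueError(
            f"area not selected in the best model for {result.group!r}; "
            "projection undefined"
        )
    coef = float(best.fit.params[area_name])
    se = float(best.fit.bse[area_name])
    return coef, se, result.best_set[1:]
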