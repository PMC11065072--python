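"""Covariate-adjusted logistic enrichment of outcomes on candidate status.

The model is ``outcome ~ is_candidate [+ category one-hot] [+ n_targets]``
fit by maximum likelihood; the enrichment effect size is the exponentiated
candidate coefficient with a Wald CI and two-sided p.  The category
reference level is the largest category; ``n_targets`` enters untransformed
by default (natural-log option available).  A balanced-weights variant
reweights rows by inverse class frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

try:  # raised by some statsmodels versions instead of warning
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    PerfectSeparationError = RuntimeError

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "fit_enrichment", "fit_by_category", "fit_by_phase"]

_SE_SEPARATION = 1e2  # candidate-term s.e. beyond this is unidentified


@dataclass(frozen=True)
class EnrichmentResult:
    """Fitted enrichment: OR with 95% Wald CI and analytic p."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficients: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_rows: int = 0
    n_outcome_pos: int = 0
    separated: bool = False

    @property
    def log_odds(self) -> float:
        return float(np.log(self.odds_ratio))


def _design(
    pairs: pd.DataFrame, adjust: Iterable[str], log_n_targets: bool
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = pairs["outcome"].to_numpy(dtype=float)
    cols: list[np.ndarray] = [
        np.ones(len(pairs)),
        pairs["is_candidate"].to_numpy(dtype=float),
    ]
    names = ["const", "is_candidate"]
    adjust = tuple(adjust)
    if "category" in adjust:
        counts = pairs["category"].value_counts()
        if len(counts) < 2:
            logger.debug("category covariate dropped: single level")
        else:
            ref = counts.index[0]
            for level in sorted(c for c in counts.index if c != ref):
                cols.append((pairs["category"] == level).to_numpy(dtype=float))
                names.append(f"category[{level}]")
    if "n_targets" in adjust:
        nt = pairs["n_targets"].to_numpy(dtype=float)
        cols.append(np.log(nt) if log_n_targets else nt)
        names.append("log_n_targets" if log_n_targets else "n_targets")
    return y, np.column_stack(cols), names


def _crude_or(pairs: pd.DataFrame) -> float:
    cand = pairs["is_candidate"].to_numpy(dtype=bool)
    out = pairs["outcome"].to_numpy(dtype=bool)
    a = float(np.sum(cand & out))
    b = float(np.sum(cand & ~out))
    c = float(np.sum(~cand & out))
    d = float(np.sum(~cand & ~out))
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


def _separated_result(pairs: pd.DataFrame) -> EnrichmentResult:
    warnings.warn("perfect separation: odds ratio reported as sentinel")
    crude = _crude_or(pairs)
    sentinel = np.inf if (np.isnan(crude) or crude >= 1) else 0.0
    return EnrichmentResult(
        odds_ratio=sentinel,
        ci_low=0.0,
        ci_high=np.inf,
        p_value=np.nan,
        coefficients={},
        n_rows=len(pairs),
        n_outcome_pos=int(pairs["outcome"].sum()),
        separated=True,
    )


def fit_enrichment(
    pairs: pd.DataFrame,
    adjust: Iterable[str] = ("category", "n_targets"),
    weights: str = "none",
    log_n_targets: bool = False,
) -> EnrichmentResult:
    """Fit the logistic enrichment model on a pair table.

    Parameters
    ----------
    pairs : frame with columns is_candidate, outcome, and any adjusted
        covariates (category, n_targets).
    adjust : subset of {"category", "n_targets"} to include.
    weights : "none" for plain ML, "balanced" for inverse-class-frequency
        row weights ``N / (2 * N_class)``.

    Raises ``ValueError`` when either the outcome or the candidate flag is
    single-class.  Perfect separation yields a flagged sentinel result
    rather than silent regularization.
    """
    n_pos = int(pairs["outcome"].sum())
    if n_pos == 0 or n_pos == len(pairs):
        raise ValueError("outcome has a single class; cannot fit enrichment model")
    n_cand = int(pairs["is_candidate"].sum())
    if n_cand == 0:
        raise ValueError("no candidate rows")
    if n_cand == len(pairs):
        raise ValueError("no non-candidate rows")

    y, X, names = _design(pairs, adjust, log_n_targets)
    if weights == "balanced":
        n = len(y)
        w_pos = n / (2.0 * n_pos)
        w_neg = n / (2.0 * (n - n_pos))
        freq_w = np.where(y == 1, w_pos, w_neg)
    elif weights == "none":
        freq_w = None
    else:
        raise ValueError(f"unknown weights mode {weights!r}")

    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=freq_w)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return _separated_result(pairs)
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        return _separated_result(pairs)

    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    idx = names.index("is_candidate")
    if not np.isfinite(bse[idx]) or bse[idx] > _SE_SEPARATION:
        return _separated_result(pairs)

    est, se = params[idx], bse[idx]
    z = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(est / se))
    return EnrichmentResult(
        odds_ratio=float(np.exp(est)),
        ci_low=float(np.exp(est - z * se)),
        ci_high=float(np.exp(est + z * se)),
        p_value=float(p),
        coefficients={
            name: (float(params[i]), float(bse[i])) for i, name in enumerate(names)
        },
        n_rows=len(pairs),
        n_outcome_pos=n_pos,
    )


def fit_by_category(
    pairs: pd.DataFrame,
    adjust: Iterable[str] = ("n_targets",),
    weights: str = "none",
) -> dict[str, EnrichmentResult]:
    """One enrichment fit per disease category (category term dropped).

    Categories whose rows carry a single outcome or candidate class are
    skipped with a warning.
    """
    out: dict[str, EnrichmentResult] = {}
    for category, sub in pairs.groupby("category", sort=True):
        try:
            out[str(category)] = fit_enrichment(sub, adjust=adjust, weights=weights)
        except ValueError as exc:
            logger.warning("category %s skipped: %s", category, exc)
    return out


def fit_by_phase(
    tables: Mapping[str, pd.DataFrame],
    adjust: Iterable[str] = ("category", "n_targets"),
    weights: str = "none",
) -> dict[str, EnrichmentResult]:
    """One enrichment fit per phase-stratified pair table.

    ``tables`` maps a stratum label (e.g. ``phase_2``, ``indicated_only``)
    to a pair table whose outcome encodes that stratum.  Strata that
    cannot be fit are skipped with a warning.
    """
    out: dict[str, EnrichmentResult] = {}
    for label, table in tables.items():
        try:
            out[label] = fit_enrichment(table, adjust=adjust, weights=weights)
        except ValueError as exc:
            logger.warning("phase stratum %s skipped: %s", label, exc)
    return out
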