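"""Trait -> network-role regression with AIC model averaging.

Species-level network metrics (degree, strength, d') are regressed on species
traits: every variable is log10-transformed, every predictor subset is fit as
an ordinary Gaussian linear model, and coefficients are synthesized by Akaike
weights (full averaging: a model without the predictor contributes zero).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class ModelAveragingResult:
    response: str
    #: per-predictor table: estimate, se, z, p, importance (sum of weights of
    #: models containing the predictor)
    coefficients: pd.DataFrame
    #: per-model table: predictors, k, aic, delta_aic, weight
    models: pd.DataFrame

    @property
    def best_model(self) -> pd.Series:
        return self.models.iloc[0]


# ---------------------------------------------------------------------------
# Transformation
# ---------------------------------------------------------------------------

#: variables kept on their original scale (category codes, not magnitudes)
UNTRANSFORMED = ("fruit_color",)


def transform_and_check(
    frame: pd.DataFrame,
    *,
    offset: str | float = "auto",
    skip: tuple[str, ...] = UNTRANSFORMED,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log10-transform an analysis frame and attach distribution diagnostics.

    Zeros are handled per column: with ``offset='auto'`` they are replaced by
    half the smallest positive observed value before the log (a documented
    convention for proportional generalists with d' = 0); a numeric offset is
    added verbatim; ``offset=None`` raises, naming the species and variable.
    Columns listed in ``skip`` (category codes) pass through unchanged.

    Returns the transformed frame and a per-variable diagnostic table
    (skewness and a Kolmogorov-Smirnov normality p-value on standardized
    values) -- informational only, never gating the fit.
    """
    out = frame.copy()
    diags = []
    for col in frame.columns:
        series = frame[col]
        if col in skip or not pd.api.types.is_numeric_dtype(series):
            continue
        values = series.astype(float).copy()
        nonmissing = values.dropna()
        if (nonmissing < 0).any():
            bad = values.index[values < 0].tolist()
            raise ValueError(f"negative values in {col!r} for {bad}: cannot log10")
        zeros = nonmissing.index[nonmissing == 0]
        if len(zeros) > 0:
            if offset is None:
                raise ValueError(
                    f"zero value in {col!r} for {list(zeros)}; enable an offset to log10"
                )
            if offset == "auto":
                positive = nonmissing[nonmissing > 0]
                if positive.empty:
                    raise ValueError(f"column {col!r} is all zeros")
                shift = positive.min() / 2.0
                values.loc[zeros] = shift
            else:
                values = values + float(offset)
        out[col] = np.log10(values)
        x = out[col].dropna().to_numpy()
        if len(x) >= 3 and x.std(ddof=1) > 0:
            zstd = (x - x.mean()) / x.std(ddof=1)
            ks = stats.kstest(zstd, "norm")
            diags.append((col, float(stats.skew(x)), float(ks.statistic), float(ks.pvalue)))
        else:
            diags.append((col, np.nan, np.nan, np.nan))
    diagnostics = pd.DataFrame(
        diags, columns=["variable", "skewness", "ks_stat", "ks_p"]
    ).set_index("variable")
    return out, diagnostics


# ---------------------------------------------------------------------------
# All-subsets fitting and averaging
# ---------------------------------------------------------------------------


def fit_all_subsets(
    frame: pd.DataFrame,
    response: str,
    predictors: list[str],
    *,
    average: str = "full",
) -> ModelAveragingResult:
    """Fit every predictor subset by OLS and model-average the coefficients.

    AIC uses the Gaussian maximum-likelihood convention (constant-consistent
    across subsets, so Akaike weights depend only on fit and size).  Averaging
    is ``'full'`` (absent coefficient enters as 0, the default) or
    ``'conditional'`` (average only over models containing the predictor).
    The averaged standard error uses the unconditional-variance formula
    se = sum_k w_k * sqrt(se_k^2 + (b_k - b_bar)^2); z = |b_bar| / se with a
    standard-normal p-value.
    """
    if average not in ("full", "conditional"):
        raise ValueError("average must be 'full' or 'conditional'")
    if len(predictors) > 8:
        raise ValueError("at most 8 predictors (256 subsets) are supported")
    data = frame[[response] + predictors].dropna()
    n = len(data)
    if n <= 2:
        raise ValueError(f"need more than 2 complete rows, have {n}")
    y = data[response].to_numpy(dtype=float)

    rows = []
    fits: list[tuple[tuple[str, ...], float, dict[str, tuple[float, float]]]] = []
    for size in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, size):
            X = sm.add_constant(
                data[list(subset)].to_numpy(dtype=float), has_constant="add"
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                warnings.warn(
                    f"rank-deficient design for subset {subset}; skipped", stacklevel=2
                )
                continue
            res = sm.OLS(y, X).fit()
            coef = {"Intercept": (float(res.params[0]), float(res.bse[0]))}
            for i, name in enumerate(subset, start=1):
                coef[name] = (float(res.params[i]), float(res.bse[i]))
            # Gaussian ML AIC counting intercept, slopes and residual variance
            aic = -2.0 * float(res.llf) + 2.0 * (len(subset) + 2)
            fits.append((subset, aic, coef))

    aics = np.array([f[1] for f in fits])
    delta = aics - aics.min()
    weights = np.exp(-0.5 * delta)
    weights /= weights.sum()

    order = np.argsort(aics, kind="stable")
    for idx in order:
        subset, aic, _ = fits[idx]
        rows.append(
            {
                "predictors": "+".join(subset) if subset else "(intercept)",
                "k": len(subset) + 2,  # intercept + slopes + residual variance
                "aic": aic,
                "delta_aic": float(delta[idx]),
                "weight": float(weights[idx]),
            }
        )
    models = pd.DataFrame(rows)

    terms = ["Intercept"] + list(predictors)
    coef_rows = []
    for term in terms:
        present = np.array([term in f[2] for f in fits])
        b = np.array([f[2].get(term, (0.0, 0.0))[0] for f in fits])
        se = np.array([f[2].get(term, (0.0, 0.0))[1] for f in fits])
        importance = float(weights[present].sum())
        if average == "full" or term == "Intercept":
            wts, bb, ss = weights, b, se
        else:
            if not present.any():
                continue
            wts = weights[present] / weights[present].sum()
            bb, ss = b[present], se[present]
        b_bar = float((wts * bb).sum())
        se_bar = float((wts * np.sqrt(ss**2 + (bb - b_bar) ** 2)).sum())
        if se_bar > 0:
            zval = abs(b_bar) / se_bar
            pval = 2.0 * float(stats.norm.sf(zval))
        else:
            zval, pval = np.nan, np.nan
        coef_rows.append(
            {
                "variable": term,
                "estimate": b_bar,
                "se": se_bar,
                "z": zval,
                "p": pval,
                "importance": importance,
            }
        )
    coefficients = pd.DataFrame(coef_rows).set_index("variable")
    return ModelAveragingResult(response=response, coefficients=coefficients, models=models)


def fit_trait_models(
    metrics_frame: pd.DataFrame,
    traits: pd.DataFrame,
    responses: tuple[str, ...] = ("degree", "strength", "dprime"),
    predictors: list[str] | None = None,
    *,
    average: str = "full",
) -> dict[str, ModelAveragingResult]:
    """Regress species-level metrics on traits for one side of the network.

    ``metrics_frame`` is indexed by species_id with columns degree/strength/
    dprime; ``traits`` is the matching trait table.  Both are joined, log10-
    transformed (with the documented zero offset) and fed to
    :func:`fit_all_subsets` per response.
    """
    joined = metrics_frame.join(traits, how="inner")
    if joined.empty:
        raise ValueError("no species shared between metrics and trait table")
    if predictors is None:
        predictors = [c for c in traits.columns if c in joined.columns]
    transformed, _ = transform_and_check(joined)
    return {
        resp: fit_all_subsets(transformed, resp, predictors, average=average)
        for resp in responses
    }
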