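"""The six estimation strategies and the instrument diagnostics.

Strategies (all proportional-odds outcome models; the reported coefficient
is on T for a-c and on the instrument Z for d-f):

    a  univariable:            Y ~ T
    b  covariate adjustment:   Y ~ C_obs + T
    c  propensity adjustment:  Y ~ PS + T   (PS = logistic linear predictor
                                             of T on the observed covariates)
    d  IV:                     Y ~ Z
    e  adjusted IV:            Y ~ Z + hospital adjustment
    f  fully adjusted IV:      Y ~ Z + hospital adjustment + C_obs + U

Strategies d-f estimate the effect of the *treatment preference*, not of the
individual treatment; the two coincide in scale here because the preference
enters the treatment model on the probability scale (one unit of Z is one
unit of treatment probability).

Hospital adjustment: Z is constant within hospital, so per-hospital
indicator dummies are exactly collinear with Z and would leave the Z
coefficient unidentified.  The default ``hospital_adjustment="performance"``
therefore adjusts for the hospital's performance value eta_h as a single
continuous covariate — the literal common cause, knowable in simulation.  A
``"dummies"`` mode exists but deliberately raises
:class:`~adjiv._errors.IdentifiabilityError` when Z is hospital-constant.
In scenarios without a performance effect eta is identically zero; the
collinearity screen then drops it and strategy e degenerates to d, which is
the intended behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._errors import ConfigurationError, IdentifiabilityError
from .cumlogit import LogisticRegressionMLE, ProportionalOddsRegressor, pseudo_r2
from .outcome import SimulatedDataset

__all__ = [
    "STRATEGIES",
    "EffectEstimate",
    "compute_propensity",
    "estimate_effect",
    "instrument_relevance",
    "balance_by_instrument",
]

STRATEGIES = ("a", "b", "c", "d", "e", "f")

_STRATEGY_LABELS = {
    "a": "univariable",
    "b": "covariate_adjustment",
    "c": "propensity_adjustment",
    "d": "iv",
    "e": "adjusted_iv",
    "f": "fully_adjusted_iv",
}


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass(frozen=True)
class EffectEstimate:
    """One strategy's estimate on one dataset (log-odds scale)."""

    strategy: str
    estimand: str  # treatment_effect (a-c, coefficient on T) or preference_effect (d-f, on Z)
    beta: float
    se: float
    converged: bool

    @property
    def label(self) -> str:
        return _STRATEGY_LABELS[self.strategy]


def compute_propensity(dataset: SimulatedDataset, scale: str = "logit") -> np.ndarray:
    """Propensity score: logistic fit of T on the observed covariates only.

    Returns the fitted linear predictor per patient (log-odds scale by
    default; ``scale="probability"`` for fitted probabilities).
    """
    X, names = dataset.covariates.design("observed")
    model = LogisticRegressionMLE().fit(X, dataset.t, feature_names=names)
    if not model.converged_:
        raise ConfigurationError("propensity-score logistic fit did not converge")
    lp = model.decision_function(X)
    if scale == "probability":
        return expit(lp)
    if scale != "logit":
        raise ConfigurationError(f"unknown propensity scale {scale!r}")
    return lp


def _strategy_design(strategy, dataset, hospital_adjustment):
    """Build (X, names, target_name) for one strategy."""
    Xo, names_o = dataset.covariates.design("observed")
    cols, names = [], []
    if strategy in ("a", "b", "c"):
        target = "t"
        if strategy == "b":
            cols.append(Xo)
            names += names_o
        elif strategy == "c":
            cols.append(compute_propensity(dataset)[:, None])
            names.append("ps")
        cols.append(dataset.t[:, None].astype(float))
        names.append("t")
    elif strategy in ("d", "e", "f"):
        target = "z"
        cols.append(dataset.z[:, None])
        names.append("z")
        if strategy in ("e", "f"):
            if hospital_adjustment == "performance":
                cols.append(dataset.performance[:, None])
                names.append("hospital_performance")
            elif hospital_adjustment == "dummies":
                _check_dummy_identifiability(dataset)
                d = pd.get_dummies(pd.Categorical(dataset.hospital_id), drop_first=True)
                cols.append(d.to_numpy(dtype=float))
                names += [f"hospital_{h}" for h in d.columns]
            else:
                raise ConfigurationError(
                    f"unknown hospital_adjustment {hospital_adjustment!r}"
                )
        if strategy == "f":
            Xu, names_u = dataset.covariates.design("unobserved")
            cols.append(Xo)
            names += names_o
            cols.append(Xu)
            names += names_u
    else:
        raise ConfigurationError(f"unknown strategy {strategy!r}; use one of {STRATEGIES}")
    return np.hstack(cols), names, target


def _check_dummy_identifiability(dataset):
    df = pd.DataFrame({"h": dataset.hospital_id, "z": dataset.z})
    if (df.groupby("h")["z"].nunique() <= 1).all():
        raise IdentifiabilityError(
            "the instrument Z is constant within hospital, so per-hospital "
            "dummies are exactly collinear with Z and the Z coefficient is "
            "unidentified; use hospital_adjustment='performance' (adjust for "
            "the hospital performance covariate) instead"
        )


def estimate_effect(
    strategy: str,
    dataset: SimulatedDataset,
    hospital_adjustment: str = "performance",
    **fit_options,
) -> EffectEstimate:
    """Fit one strategy's proportional-odds model and extract its coefficient.

    Returns the coefficient on T (strategies a-c, estimand
    ``treatment_effect``) or on Z (d-f, estimand ``preference_effect``) with
    its model-based standard error.  A degenerate design that removes the
    target coefficient (e.g. a constant instrument) yields a non-converged
    estimate with NaN coefficient rather than a silent answer.
    """
    X, names, target = _strategy_design(strategy, dataset, hospital_adjustment)
    estimand = "treatment_effect" if target == "t" else "preference_effect"
    model = ProportionalOddsRegressor(**fit_options).fit(X, dataset.y, feature_names=names)
    res = model.result_
    if target in res.dropped:
        warnings.warn(
            f"strategy {strategy}: target column {target!r} dropped as degenerate "
            "(constant or collinear); estimate is unidentified",
            WeakInstrumentWarning,
            stacklevel=2,
        )
        return EffectEstimate(strategy, estimand, float("nan"), float("nan"), False)
    return EffectEstimate(
        strategy, estimand, res.beta(target), res.stderr(target), res.converged
    )


def instrument_relevance(dataset: SimulatedDataset, kind: str = "nagelkerke") -> float:
    """Instrument strength: pseudo-R² of the logistic fit T ~ Z.

    Returns 0 with a weak-instrument warning when Z is constant.
    """
    z = np.asarray(dataset.z, dtype=float)
    if np.ptp(z) == 0.0:
        warnings.warn(
            "instrument Z is constant; relevance is zero (no instrument)",
            WeakInstrumentWarning,
            stacklevel=2,
        )
        return 0.0
    fit = LogisticRegressionMLE().fit(z[:, None], dataset.t, feature_names=["z"]).result_
    return pseudo_r2(fit, kind=kind)


def _smd(x: np.ndarray, g: np.ndarray) -> float:
    """Standardized mean difference of x across binary groups g."""
    x0, x1 = x[g == 0], x[g == 1]
    if len(x0) == 0 or len(x1) == 0:
        return float("nan")
    pooled = np.sqrt((x0.var(ddof=1) + x1.var(ddof=1)) / 2.0)
    if pooled <= 1e-12 * max(1.0, abs(x.mean())):  # constant up to float noise
        return 0.0
    return float((x1.mean() - x0.mean()) / pooled)


def balance_by_instrument(dataset: SimulatedDataset, covariate: str):
    """Covariate balance, stratified by the instrument versus by treatment.

    Returns ``(levels, summary)`` where ``levels`` is a DataFrame with one
    row per covariate level (quartile bins for age): n, median and IQR of
    the Z distribution, and the treated fraction; and ``summary`` is a dict
    with the maximum pairwise standardized mean difference of Z across
    covariate levels (``smd_z_across_levels``, ~0 when the instrument is as
    good as randomly assigned), and the SMD of the covariate's numeric score
    between treatment arms (``smd_by_treatment``) and between above/below-
    median instrument halves (``smd_by_instrument``).
    """
    f = dataset.covariates.frame
    if covariate not in f.columns:
        raise ConfigurationError(f"unknown covariate {covariate!r}")
    x = f[covariate]
    if covariate == "age":
        levels = pd.qcut(x, 4, duplicates="drop")
        numeric = x.to_numpy(dtype=float)
    else:
        levels = pd.Categorical(x)
        codes = pd.Categorical(x).codes.astype(float)
        numeric = codes
    z = np.asarray(dataset.z, dtype=float)
    t = np.asarray(dataset.t)
    df = pd.DataFrame({"level": levels, "z": z, "t": t})
    per_level = (
        df.groupby("level", observed=True)
        .agg(
            n=("z", "size"),
            z_median=("z", "median"),
            z_q1=("z", lambda s: s.quantile(0.25)),
            z_q3=("z", lambda s: s.quantile(0.75)),
            treated_fraction=("t", "mean"),
        )
        .reset_index()
    )
    # max pairwise SMD of Z across covariate levels
    groups = [g["z"].to_numpy() for _, g in df.groupby("level", observed=True) if len(g)]
    smd_z = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i], groups[j]
            pooled = np.sqrt((gi.var(ddof=1) + gj.var(ddof=1)) / 2.0) if min(len(gi), len(gj)) > 1 else 0.0
            tiny = 1e-12 * max(1.0, abs(z.mean()))  # constant up to float noise
            d = abs(gi.mean() - gj.mean()) / pooled if pooled > tiny else 0.0
            smd_z = max(smd_z, d)
    high_z = (z > np.median(z)).astype(int)
    summary = {
        "smd_z_across_levels": float(smd_z),
        "smd_by_treatment": abs(_smd(numeric, t)),
        "smd_by_instrument": abs(_smd(numeric, high_z)) if np.ptp(z) > 0 else 0.0,
    }
    return per_level, summary
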