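"""Synthetic patient cohorts with severe-TBI-like prognostic factors.

Real registry rows are not redistributable, so cohorts are drawn from
configurable *marginal* distributions of the six prognostic factors used in
comparative-effectiveness work on traumatic brain injury: Glasgow Coma Scale
(GCS) motor score, age and sex (treated as the *observed* confounders) and
pupillary reactivity, subarachnoid hemorrhage (SAH) and the Marshall CT
classification (treated as the hypothetically *unobserved* confounders).
Factors are mutually independent by construction; joint dependence of the
real data is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError

__all__ = [
    "CovariateMarginals",
    "CovariateTable",
    "generate_covariates",
    "encode_design",
    "decode_design",
    "OBSERVED_FACTORS",
    "UNOBSERVED_FACTORS",
]

# Exhaustive, disjoint partition of the six prognostic factors.
OBSERVED_FACTORS = ("gcs_motor", "age", "sex")
UNOBSERVED_FACTORS = ("pupils", "sah", "ct_class")

PUPILS_LEVELS = ("both", "one", "none")  # reactive pupils
CT_LEVELS = ("I", "II", "III", "IV", "V", "VI")  # Marshall classification
GCS_MOTOR_LEVELS = (1, 2, 3, 4, 5, 6)

_PROB_TOL = 1e-9


def _check_probs(name: str, probs: Sequence[float], k: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (k,):
        raise ConfigurationError(f"{name} must have {k} entries, got shape {p.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ConfigurationError(f"{name} entries must lie in [0, 1]: {p}")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ConfigurationError(f"{name} must sum to 1 (got {p.sum():.12f})")
    return p


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal distributions of the six prognostic factors.

    Parameters
    ----------
    age_distribution
        Either ``{"kind": "shifted_lognormal", "shift": s, "mu": m, "sigma": sd}``
        (age = s + LogNormal(m, sd), years) or
        ``{"kind": "empirical", "values": [...]}`` (resampled with replacement).
    sex_male_prob
        P(male).
    gcs_motor_probs
        Probability vector over the six GCS motor levels 1 (none) .. 6 (obeys).
    pupils_probs
        Probability vector over (both reactive, one reactive, none reactive).
    sah_prob
        P(subarachnoid hemorrhage present).
    ct_class_probs
        Probability vector over Marshall CT classes I..VI.
    gcs_motor_categorical
        Whether the GCS motor score enters design matrices as dummies
        (default) or as a single linear term.
    """

    age_distribution: dict = field(
        default_factory=lambda: {
            "kind": "shifted_lognormal",
            "shift": 15.0,
            "mu": 3.0,
            "sigma": 0.6,
        }
    )
    sex_male_prob: float = 0.75
    gcs_motor_probs: tuple = (0.16, 0.10, 0.13, 0.22, 0.25, 0.14)
    pupils_probs: tuple = (0.63, 0.14, 0.23)
    sah_prob: float = 0.45
    ct_class_probs: tuple = (0.07, 0.25, 0.18, 0.05, 0.27, 0.18)
    gcs_motor_categorical: bool = True

    def __post_init__(self):
        _check_probs("gcs_motor_probs", self.gcs_motor_probs, 6)
        _check_probs("pupils_probs", self.pupils_probs, 3)
        _check_probs("ct_class_probs", self.ct_class_probs, 6)
        for name in ("sex_male_prob", "sah_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        kind = self.age_distribution.get("kind")
        if kind == "shifted_lognormal":
            if self.age_distribution.get("shift", 0.0) < 0:
                raise ConfigurationError("age shift must be non-negative")
            if self.age_distribution.get("sigma", 1.0) <= 0:
                raise ConfigurationError("age sigma must be positive")
        elif kind == "empirical":
            vals = np.asarray(self.age_distribution.get("values", []), dtype=float)
            if vals.size == 0 or np.any(vals <= 0):
                raise ConfigurationError("empirical age values must be positive and non-empty")
        else:
            raise ConfigurationError(f"unknown age distribution kind: {kind!r}")

    @property
    def age_mean(self) -> float:
        d = self.age_distribution
        if d["kind"] == "shifted_lognormal":
            return d["shift"] + float(np.exp(d["mu"] + d["sigma"] ** 2 / 2.0))
        return float(np.mean(d["values"]))

    @property
    def age_sd(self) -> float:
        d = self.age_distribution
        if d["kind"] == "shifted_lognormal":
            m = np.exp(d["mu"] + d["sigma"] ** 2 / 2.0)
            return float(m * np.sqrt(np.exp(d["sigma"] ** 2) - 1.0))
        return float(np.std(d["values"], ddof=0))

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateMarginals":
        d = dict(d)
        for key in ("gcs_motor_probs", "pupils_probs", "ct_class_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CovariateTable:
    """A cohort of patients with the six prognostic factors, no missing values.

    ``frame`` columns (stable order): age, sex, gcs_motor, pupils, sah, ct_class.
    The encoding to numeric design columns (dummy coding with the first level
    as reference, age z-scored with the configured mean/SD) is deterministic
    given ``marginals``.
    """

    frame: pd.DataFrame
    marginals: CovariateMarginals

    COLUMNS = ("age", "sex", "gcs_motor", "pupils", "sah", "ct_class")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"covariate table missing columns: {sorted(missing)}")
        self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if len(self.frame):
            if self.frame.isna().any().any():
                raise ConfigurationError("covariate table contains missing values")
            if not self.frame["gcs_motor"].isin(GCS_MOTOR_LEVELS).all():
                raise ConfigurationError("gcs_motor outside 1..6")
            if not self.frame["pupils"].isin(PUPILS_LEVELS).all():
                raise ConfigurationError("pupils outside declared levels")
            if not self.frame["ct_class"].isin(CT_LEVELS).all():
                raise ConfigurationError("ct_class outside Marshall I..VI")
            for b in ("sex", "sah"):
                if not self.frame[b].isin((0, 1)).all():
                    raise ConfigurationError(f"{b} must be binary 0/1")

    def __len__(self) -> int:
        return len(self.frame)

    def design(self, subset: Literal["observed", "unobserved", "all"] = "all"):
        """Numeric design block for the requested confounder subset.

        Returns ``(X, names)`` with X of shape (n, p).  No intercept column.
        """
        return encode_design(self, subset)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def generate_covariates(
    n: int, marginals: CovariateMarginals | None = None, seed=0
) -> CovariateTable:
    """Draw ``n`` independent patients from the configured marginals.

    Deterministic for a fixed seed; ``n == 0`` yields an empty table with the
    full schema.
    """
    if marginals is None:
        marginals = CovariateMarginals()
    if n < 0:
        raise ConfigurationError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    d = marginals.age_distribution
    if d["kind"] == "shifted_lognormal":
        age = d["shift"] + rng.lognormal(d["mu"], d["sigma"], size=n)
    else:
        age = rng.choice(np.asarray(d["values"], dtype=float), size=n, replace=True)
    frame = pd.DataFrame(
        {
            "age": age,
            "sex": rng.binomial(1, marginals.sex_male_prob, size=n),
            "gcs_motor": rng.choice(GCS_MOTOR_LEVELS, size=n, p=marginals.gcs_motor_probs),
            "pupils": rng.choice(PUPILS_LEVELS, size=n, p=marginals.pupils_probs),
            "sah": rng.binomial(1, marginals.sah_prob, size=n),
            "ct_class": rng.choice(CT_LEVELS, size=n, p=marginals.ct_class_probs),
        }
    )
    return CovariateTable(frame, marginals)


def _column_spec(marginals: CovariateMarginals, subset: str):
    """Ordered (name, kind, payload) encoding spec for a confounder subset."""
    obs = []
    if marginals.gcs_motor_categorical:
        obs += [(f"gcs_motor_{lvl}", "dummy", ("gcs_motor", lvl)) for lvl in GCS_MOTOR_LEVELS[1:]]
    else:
        obs += [("gcs_motor", "linear", ("gcs_motor", None))]
    obs += [("age_z", "zscore", ("age", (marginals.age_mean, marginals.age_sd)))]
    obs += [("sex_male", "binary", ("sex", None))]
    unobs = [(f"pupils_{lvl}", "dummy", ("pupils", lvl)) for lvl in PUPILS_LEVELS[1:]]
    unobs += [("sah", "binary", ("sah", None))]
    unobs += [(f"ct_class_{lvl}", "dummy", ("ct_class", lvl)) for lvl in CT_LEVELS[1:]]
    if subset == "observed":
        return obs
    if subset == "unobserved":
        return unobs
    if subset == "all":
        return obs + unobs
    raise ConfigurationError(f"unknown subset {subset!r}; use observed/unobserved/all")


def encode_design(table: CovariateTable, subset: str = "all"):
    """Encode a covariate table into a numeric design block.

    Categories are dummy-coded against the first (reference) level; age is
    z-scored with the configured marginal mean/SD.  Returns ``(X, names)``.
    """
    spec = _column_spec(table.marginals, subset)
    n = len(table)
    X = np.empty((n, len(spec)), dtype=float)
    f = table.frame
    for j, (name, kind, (col, payload)) in enumerate(spec):
        if kind == "dummy":
            X[:, j] = (f[col].to_numpy() == payload).astype(float)
        elif kind == "zscore":
            mean, sd = payload
            X[:, j] = (f[col].to_numpy(dtype=float) - mean) / sd
        else:  # binary or linear: raw numeric value
            X[:, j] = f[col].to_numpy(dtype=float)
    return X, [name for name, _, _ in spec]


def decode_design(X: np.ndarray, marginals: CovariateMarginals, subset: str = "all") -> pd.DataFrame:
    """Invert :func:`encode_design` (categories from dummies, age from z-score)."""
    spec = _column_spec(marginals, subset)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(spec):
        raise ConfigurationError(
            f"design block has {X.shape[1]} columns, expected {len(spec)} for subset {subset!r}"
        )
    out: dict[str, np.ndarray] = {}
    ref_levels = {"gcs_motor": GCS_MOTOR_LEVELS[0], "pupils": PUPILS_LEVELS[0], "ct_class": CT_LEVELS[0]}
    for j, (name, kind, (col, payload)) in enumerate(spec):
        if kind == "dummy":
            if col not in out:
                out[col] = np.full(X.shape[0], ref_levels[col], dtype=object)
            out[col][X[:, j] == 1.0] = payload
        elif kind == "zscore":
            mean, sd = payload
            out[col] = X[:, j] * sd + mean
        else:
            out[col] = X[:, j].astype(int) if col in ("sex", "sah", "gcs_motor") else X[:, j]
    df = pd.DataFrame(out)
    if "gcs_motor" in df.columns and df["gcs_motor"].dtype == object:
        df["gcs_motor"] = df["gcs_motor"].astype(int)
    return df
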