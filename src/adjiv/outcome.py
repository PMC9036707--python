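"""Treatment assignment and ordinal-outcome generation under scenario switches.

Generation follows five steps: (1) draw patient covariates, (2)–(3) draw
hospital preference p_h and performance eta_h, (4) draw binary treatment
from a logistic model in the covariates and the hospital preference, and
(5) draw a 4-level ordinal outcome from a proportional-odds model in the
covariates, treatment and hospital performance:

    T_i ~ Bernoulli( expit( o_h(i) + C_i b_CT + U_i b_UT ) )
    logit P(Y_i <= k) = alpha_k + C_i b_CY + U_i b_UY + T_i b_T - eta_h(i) * s

Outcome categories are 1 (worst: death/vegetative combined) .. 4 (best), so
the default treatment coefficient b_T = -0.5 (odds ratio exp(0.5) = 1.65 for
better outcome) is *beneficial*.  eta_h is latent hospital quality (higher =
better), hence the minus sign on the cumulative logit of the worse-or-equal
categories.

Hospital preference enters through a calibrated offset o_h: by default o_h
solves  mean_i expit(o_h + c_i) = p_h  over the realized covariate
distribution, so each hospital's expected treated proportion equals its
preference exactly and the instrument Z lives on an interpretable
probability scale (a hospital preferring 40% treats ~40%).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._errors import ConfigurationError, DegenerateInputError
from .cohort import CovariateMarginals, CovariateTable, generate_covariates
from .hospitals import HospitalConfig, HospitalTable, assign_patients, draw_hospitals

__all__ = [
    "CoefficientConfig",
    "ScenarioSpec",
    "SCENARIOS",
    "SimulatedDataset",
    "assign_treatment",
    "generate_outcome",
    "compute_instrument",
    "simulate_dataset",
]

# Calibration defaults: the treatment-model coefficients are proportional to
# the outcome-model ones (sicker patients are both more likely to be treated
# and to do worse), scaled so that unmeasured confounding visibly biases
# covariate-adjusted estimates and total confounding flips the sign of the
# unadjusted estimate.  These are generator knobs, not empirical estimates.
_DEFAULT_BETA_CT = {
    "gcs_motor_2": -0.4, "gcs_motor_3": -0.7, "gcs_motor_4": -1.0,
    "gcs_motor_5": -1.3, "gcs_motor_6": -1.7,
    "age_z": 0.6, "sex_male": -0.1,
}
_DEFAULT_BETA_CY = {
    "gcs_motor_2": -0.18, "gcs_motor_3": -0.315, "gcs_motor_4": -0.45,
    "gcs_motor_5": -0.585, "gcs_motor_6": -0.765,
    "age_z": 0.27, "sex_male": -0.045,
}
_DEFAULT_BETA_UT = {
    "pupils_one": 0.72, "pupils_none": 1.56, "sah": 0.6,
    "ct_class_II": 0.36, "ct_class_III": 1.08, "ct_class_IV": 0.84,
    "ct_class_V": 1.32, "ct_class_VI": 1.56,
}
_DEFAULT_BETA_UY = {
    "pupils_one": 0.36, "pupils_none": 0.78, "sah": 0.3,
    "ct_class_II": 0.18, "ct_class_III": 0.54, "ct_class_IV": 0.42,
    "ct_class_V": 0.66, "ct_class_VI": 0.78,
}


@dataclass(frozen=True)
class CoefficientConfig:
    """Generating coefficients, keyed by design-column name.

    ``alpha_Y`` are the three ordered cut-points of the 4-level outcome
    (default split roughly 40/15/20/25 across categories 1..4).  ``alpha_T``
    is the treatment-model intercept used when no hospital preference is
    active (default gives ~37.5% treated, the preference-range midpoint).
    ``beta_hT`` scales logit(p_h) in the uncalibrated preference mode.
    """

    beta_CT: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_CT))
    beta_UT: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_UT))
    beta_CY: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_CY))
    beta_UY: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_UY))
    beta_hT: float = 1.0
    alpha_T: float = float(logit(0.375))
    beta_T: float = -0.5
    beta_HY_scale: float = 1.0
    alpha_Y: tuple = (float(logit(0.40)), float(logit(0.55)), float(logit(0.75)))

    def __post_init__(self):
        a = np.asarray(self.alpha_Y, dtype=float)
        if a.ndim != 1 or len(a) < 1 or np.any(np.diff(a) <= 0):
            raise ConfigurationError(f"alpha_Y cut-points must be strictly increasing, got {self.alpha_Y}")
        if not np.isfinite(self.beta_T):
            raise ConfigurationError("beta_T must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientConfig":
        d = dict(d)
        if "alpha_Y" in d:
            d["alpha_Y"] = tuple(d["alpha_Y"])
        return cls(**d)


def _coef_vector(mapping: dict, names: list[str], label: str) -> np.ndarray:
    unknown = set(mapping) - set(names)
    if unknown:
        raise ConfigurationError(
            f"{label} names {sorted(unknown)} not in design columns {names}"
        )
    return np.array([float(mapping.get(nm, 0.0)) for nm in names])


@dataclass(frozen=True)
class ScenarioSpec:
    """Switches defining one simulation scenario.

    ``measured_confounding_on`` gates the C -> T path only: the observed
    prognostic factors always affect the outcome (that is what makes the
    marginal estimates of strategies a/c/d conservative relative to the
    conditional strategy-b estimate even under randomization).  The
    hypothetically unmeasured factors exist as *confounders* or not at all:
    ``unmeasured_confounding_on`` gates both U -> T and U -> Y.  The common
    cause (hospital performance, correlated with preference at
    ``common_cause_rho``) is active only when ``performance_on`` is set.
    """

    id: int
    name: str
    treatment_effect_on: bool = True
    measured_confounding_on: bool = True
    unmeasured_confounding_on: bool = True
    preference_on: bool = True
    performance_on: bool = False
    common_cause_rho: float = 0.0

    def __post_init__(self):
        if self.common_cause_rho != 0.0 and not self.performance_on:
            raise ConfigurationError(
                "common_cause_rho requires performance_on (the common cause is "
                "the correlated hospital performance effect)"
            )

    def with_rho(self, rho: float) -> "ScenarioSpec":
        if rho == 0.0:
            return replace(self, common_cause_rho=0.0)
        return replace(self, performance_on=True, common_cause_rho=rho)


#: The seven pre-registered scenarios: six controls of increasing complexity
#: plus the "realistic" one with a common cause of instrument and outcome.
SCENARIOS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec(1, "null", treatment_effect_on=False, measured_confounding_on=False,
                    unmeasured_confounding_on=False, preference_on=False),
    2: ScenarioSpec(2, "rct", measured_confounding_on=False,
                    unmeasured_confounding_on=False, preference_on=False),
    3: ScenarioSpec(3, "measured_confounding", unmeasured_confounding_on=False,
                    preference_on=False),
    4: ScenarioSpec(4, "measured_confounding_with_instrument",
                    unmeasured_confounding_on=False),
    5: ScenarioSpec(5, "unmeasured_confounding", preference_on=False),
    6: ScenarioSpec(6, "unmeasured_confounding_with_instrument"),
    7: ScenarioSpec(7, "common_cause", performance_on=True, common_cause_rho=0.3),
}


def _treatment_covariate_lp(cov: CovariateTable, coefs: CoefficientConfig,
                            scenario: ScenarioSpec) -> np.ndarray:
    lp = np.zeros(len(cov))
    if scenario.measured_confounding_on:
        X, names = cov.design("observed")
        lp = lp + X @ _coef_vector(coefs.beta_CT, names, "beta_CT")
    if scenario.unmeasured_confounding_on:
        X, names = cov.design("unobserved")
        lp = lp + X @ _coef_vector(coefs.beta_UT, names, "beta_UT")
    return lp


def _calibrated_offsets(c_centered: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Offsets o with mean_i expit(o + c_i) = target, via a monotone grid inverse."""
    grid = np.linspace(-12.0, 12.0, 1201)
    # mean response curve over the realized covariate distribution
    m = expit(grid[:, None] + c_centered[None, :]).mean(axis=1)
    if np.any(targets <= m[0]) or np.any(targets >= m[-1]):
        raise DegenerateInputError("preference target outside calibratable range")
    return np.interp(targets, m, grid)


def assign_treatment(
    cov: CovariateTable,
    hosp_ids: np.ndarray,
    hospitals: HospitalTable,
    coefs: CoefficientConfig,
    scenario: ScenarioSpec,
    seed=0,
    calibration: str = "marginal",
) -> np.ndarray:
    """Draw the binary treatment vector (step 4).

    ``calibration`` controls how the hospital preference p_h enters the
    treatment logit when ``scenario.preference_on``:

    - ``"marginal"`` (default): per-hospital offset solving
      E[expit(o_h + c)] = p_h over the realized covariates, so each
      hospital's expected treated share is exactly its preference;
    - ``"logit_offset"``: logit(p_h) * beta_hT added to the mean-centered
      covariate score (equality with p_h holds at average covariates only);
    - ``"none"``: alpha_T + beta_hT * logit(p_h) + uncentered covariate score.
    """
    rng = np.random.default_rng(seed)
    c = _treatment_covariate_lp(cov, coefs, scenario)
    pref_map = dict(zip(hospitals.frame["hospital_id"], hospitals.preference))
    try:
        p_h = np.array([pref_map[h] for h in hosp_ids])
    except KeyError as e:
        raise ConfigurationError(f"hospital id {e} not in hospital table") from None
    if scenario.preference_on:
        if calibration == "marginal":
            c_cent = c - c.mean()
            uniq = np.unique(hosp_ids)
            targets = np.array([pref_map[h] for h in uniq])
            offs = _calibrated_offsets(c_cent, targets)
            off_map = dict(zip(uniq, offs))
            lp = np.array([off_map[h] for h in hosp_ids]) + c_cent
        elif calibration == "logit_offset":
            lp = coefs.beta_hT * logit(p_h) + (c - c.mean())
        elif calibration == "none":
            lp = coefs.alpha_T + coefs.beta_hT * logit(p_h) + c
        else:
            raise ConfigurationError(f"unknown calibration {calibration!r}")
    else:
        lp = coefs.alpha_T + (c - c.mean() if len(c) else c)
    return rng.binomial(1, expit(lp))


def generate_outcome(
    cov: CovariateTable,
    T: np.ndarray,
    hosp_ids: np.ndarray,
    hospitals: HospitalTable,
    coefs: CoefficientConfig,
    scenario: ScenarioSpec,
    seed=0,
) -> np.ndarray:
    """Draw the 4-level ordinal outcome (step 5); category 1 is worst."""
    rng = np.random.default_rng(seed)
    n = len(cov)
    Xo, no_ = cov.design("observed")
    Xu, nu_ = cov.design("unobserved")
    lp = Xo @ _coef_vector(coefs.beta_CY, no_, "beta_CY")
    if scenario.unmeasured_confounding_on:
        lp += Xu @ _coef_vector(coefs.beta_UY, nu_, "beta_UY")
    if scenario.treatment_effect_on:
        lp += coefs.beta_T * np.asarray(T, dtype=float)
    if scenario.performance_on:
        perf_map = dict(zip(hospitals.frame["hospital_id"], hospitals.performance))
        eta = np.array([perf_map[h] for h in hosp_ids])
        lp -= coefs.beta_HY_scale * eta  # higher performance -> better outcomes
    alpha = np.asarray(coefs.alpha_Y, dtype=float)
    F = expit(alpha[None, :] + lp[:, None])  # cumulative P(Y <= k), k=1..K-1
    u = rng.random(n)
    return 1 + (u[:, None] > F).sum(axis=1)


def compute_instrument(
    T: np.ndarray,
    hosp_ids: np.ndarray,
    mode: str = "empirical",
    hospitals: HospitalTable | None = None,
) -> np.ndarray:
    """Per-patient instrument Z (step between 4 and the analyses).

    ``empirical`` (default): the proportion treated in the patient's own
    hospital, including the patient — the instrument observable in real
    data; ``leave_one_out``: excluding the patient; ``assigned``: the
    hospital's generating preference p_h (simulation-only oracle).
    """
    T = np.asarray(T, dtype=float)
    hosp_ids = np.asarray(hosp_ids)
    if len(T) != len(hosp_ids):
        raise ConfigurationError("T and hospital ids differ in length")
    if len(T) == 0:
        raise DegenerateInputError("no patients")
    if mode == "assigned":
        if hospitals is None:
            raise ConfigurationError("assigned mode needs the hospital table")
        pref_map = dict(zip(hospitals.frame["hospital_id"], hospitals.preference))
        return np.array([pref_map[h] for h in hosp_ids])
    uniq, inv, counts = np.unique(hosp_ids, return_inverse=True, return_counts=True)
    sums = np.bincount(inv, weights=T)
    if mode == "empirical":
        return (sums / counts)[inv]
    if mode == "leave_one_out":
        if np.any(counts < 2):
            raise DegenerateInputError("leave_one_out needs >= 2 patients per hospital")
        return (sums[inv] - T) / (counts[inv] - 1)
    raise ConfigurationError(f"unknown instrument mode {mode!r}")


@dataclass
class SimulatedDataset:
    """One simulated cohort: covariates, hospital ids, instrument Z, T, Y."""

    covariates: CovariateTable
    hospital_id: np.ndarray
    hospitals: HospitalTable
    z: np.ndarray
    t: np.ndarray
    y: np.ndarray

    FORMAT_VERSION = "adjiv-dataset-v1"

    def __post_init__(self):
        n = len(self.covariates)
        for nm in ("hospital_id", "z", "t", "y"):
            if len(getattr(self, nm)) != n:
                raise ConfigurationError(f"{nm} length does not match covariates ({n})")
        if n:
            if not np.isin(self.t, (0, 1)).all():
                raise ConfigurationError("T must be binary 0/1")
            if not np.isin(self.y, (1, 2, 3, 4)).all():
                raise ConfigurationError("Y must lie in {1, 2, 3, 4}")
            df = pd.DataFrame({"h": self.hospital_id, "z": self.z})
            if (df.groupby("h")["z"].nunique() > 1).any():
                raise ConfigurationError("Z must be constant within hospital")

    def __len__(self) -> int:
        return len(self.covariates)

    @property
    def performance(self) -> np.ndarray:
        """Per-patient hospital performance eta (the common-cause covariate)."""
        perf_map = dict(zip(self.hospitals.frame["hospital_id"], self.hospitals.performance))
        return np.array([perf_map[h] for h in self.hospital_id])

    def to_frame(self) -> pd.DataFrame:
        df = self.covariates.frame.copy()
        df["hospital_id"] = self.hospital_id
        df["z"] = self.z
        df["t"] = self.t
        df["y"] = self.y
        df["performance"] = self.performance
        return df

    def to_csv(self, path) -> None:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(f"# {self.FORMAT_VERSION}\n")
            fh.write(buf.getvalue())

    @classmethod
    def read_csv(cls, path, marginals: CovariateMarginals | None = None) -> "SimulatedDataset":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            if header != cls.FORMAT_VERSION:
                raise ConfigurationError(f"unrecognized dataset header {header!r}")
            df = pd.read_csv(fh)
        marginals = marginals or CovariateMarginals()
        cov = CovariateTable(df[list(CovariateTable.COLUMNS)], marginals)
        hframe = (
            df[["hospital_id", "z", "performance"]]
            .groupby("hospital_id", as_index=False)
            .first()
            .rename(columns={"z": "preference"})
        )
        hospitals = HospitalTable(hframe[["hospital_id", "preference", "performance"]])
        return cls(cov, df["hospital_id"].to_numpy(), hospitals,
                   df["z"].to_numpy(float), df["t"].to_numpy(int), df["y"].to_numpy(int))


def simulate_dataset(
    n_patients: int = 15_000,
    marginals: CovariateMarginals | None = None,
    hospital_config: HospitalConfig | None = None,
    coefs: CoefficientConfig | None = None,
    scenario: ScenarioSpec | int = 6,
    seed=0,
    instrument_mode: str = "empirical",
    assignment_mode: str = "balanced",
    calibration: str = "marginal",
) -> SimulatedDataset:
    """Run generation steps 1-5 and attach the instrument.

    The scenario gates the hospital-performance common cause: unless
    ``scenario.performance_on``, hospital performance is forced to zero
    (performance_sd = 0) and the copula correlation with preference to the
    scenario's ``common_cause_rho``.
    """
    if isinstance(scenario, int):
        scenario = SCENARIOS[scenario]
    marginals = marginals or CovariateMarginals()
    hospital_config = hospital_config or HospitalConfig()
    coefs = coefs or CoefficientConfig()
    if scenario.performance_on:
        hospital_config = replace(hospital_config, rho=scenario.common_cause_rho)
    else:
        hospital_config = replace(hospital_config, performance_sd=0.0, rho=0.0)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_cov, s_hosp, s_assign, s_treat, s_out = ss.spawn(5)
    cov = generate_covariates(n_patients, marginals, s_cov)
    hospitals = draw_hospitals(hospital_config, s_hosp)
    hosp_ids = assign_patients(n_patients, hospital_config, s_assign, mode=assignment_mode)
    T = assign_treatment(cov, hosp_ids, hospitals, coefs, scenario, s_treat,
                         calibration=calibration)
    Y = generate_outcome(cov, T, hosp_ids, hospitals, coefs, scenario, s_out)
    Z = compute_instrument(T, hosp_ids, mode=instrument_mode, hospitals=hospitals)
    return SimulatedDataset(cov, hosp_ids, hospitals, Z, T, Y)
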