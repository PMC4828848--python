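"""Generation of complete longitudinal two-arm trial data.

The generating model is a parallel two-group repeated-measures design with a
saturated arm-by-occasion mean structure, a subject-level random intercept
``b_i ~ N(0, sigma_b^2)`` and occasion-level noise ``e_ij ~ N(0, sigma_e^2)``:

    Y_ij = mu[arm_i, j] + b_i + e_ij

which induces a compound-symmetric within-subject covariance
``Sigma = sigma_b^2 J + sigma_e^2 I`` with within-subject correlation
``rho = sigma_b^2 / (sigma_b^2 + sigma_e^2)``.

Outcomes emulate SF-36 norm-based composite scores: population mean 50,
total variance 110 (SD ~ 10.49), continuous Gaussian (no rounding to
integer questionnaire scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignError",
    "TrialDesign",
    "MeanMatrix",
    "VarianceSpec",
    "LongDataset",
    "make_linear_trajectory",
    "make_custom_trajectory",
    "variance_components",
    "simulate_trial",
    "theoretical_ttest_power",
]

#: Default total outcome variance (SF-36 norm-based scale).
DEFAULT_TOTAL_VARIANCE = 110.0
#: Baseline population mean on the SF-36 norm-based scale.
NORM_MEAN = 50.0
#: Default end-of-study treatment effect in score units.
DEFAULT_EFFECT = 4.18


class DesignError(ValueError):
    """Raised when a trial design, mean matrix or variance spec is invalid."""


@dataclass(frozen=True)
class TrialDesign:
    """Per-arm sample size, number of occasions and significance level.

    Defaults correspond to a trial with 100 participants per arm measured at
    4 occasions, tested two-sided at alpha = 0.05.
    """

    n_per_arm: int = 100
    n_times: int = 4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise DesignError("n_per_arm must be >= 2")
        if self.n_times < 2:
            raise DesignError("n_times must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise DesignError("alpha must be in (0, 1)")

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_arm


@dataclass(frozen=True)
class MeanMatrix:
    """True cell means: row 0 = control arm, row 1 = treatment arm.

    Baselines must coincide across arms (randomization guarantees equal
    means at the first occasion).
    """

    mu: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim != 2 or mu.shape[0] != 2 or mu.shape[1] < 2:
            raise DesignError("mu must be a 2 x n_times array with n_times >= 2")
        if not np.isclose(mu[0, 0], mu[1, 0]):
            raise DesignError(
                "baseline means must be equal across arms "
                f"(got {mu[0, 0]} and {mu[1, 0]})"
            )
        object.__setattr__(self, "mu", mu)

    @property
    def n_times(self) -> int:
        return self.mu.shape[1]

    @property
    def final_effect(self) -> float:
        """Treatment-minus-control difference at the last occasion."""
        return float(self.mu[1, -1] - self.mu[0, -1])


@dataclass(frozen=True)
class VarianceSpec:
    """Between-person (sigma_b^2) and within-person (sigma_e^2) variance."""

    sigma_b_sq: float
    sigma_e_sq: float

    def __post_init__(self) -> None:
        if self.sigma_b_sq < 0:
            raise DesignError("sigma_b_sq must be >= 0")
        if self.sigma_e_sq <= 0:
            raise DesignError("sigma_e_sq must be > 0")

    @property
    def total(self) -> float:
        return self.sigma_b_sq + self.sigma_e_sq

    @property
    def rho(self) -> float:
        """Within-subject correlation under compound symmetry."""
        return self.sigma_b_sq / self.total

    def covariance(self, n_times: int) -> np.ndarray:
        """The n_times x n_times compound-symmetric covariance matrix."""
        return self.sigma_b_sq * np.ones((n_times, n_times)) + self.sigma_e_sq * np.eye(
            n_times
        )


@dataclass
class LongDataset:
    """Subject-level repeated measures in wide layout with observedness flags.

    ``values`` and ``observed`` are (n_subjects, n_times) arrays; ``arm`` is
    0 (control) / 1 (treatment) per subject. Every subject keeps a full row
    of occasions — missingness is flagged, never deleted, so dropout
    patterns stay auditable. Simulated-then-deleted values are retained in
    ``values`` for diagnostics but carry ``observed = False`` and are never
    used by estimators.
    """

    values: np.ndarray
    observed: np.ndarray
    arm: np.ndarray
    subject_id: np.ndarray
    audit: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.arm = np.asarray(self.arm, dtype=int)
        self.subject_id = np.asarray(self.subject_id, dtype=int)
        n, j = self.values.shape
        if self.observed.shape != (n, j):
            raise DesignError("values and observed must have matching shapes")
        if self.arm.shape != (n,) or self.subject_id.shape != (n,):
            raise DesignError("arm and subject_id must have one entry per subject")
        if not np.isin(self.arm, [0, 1]).all():
            raise DesignError("arm codes must be 0 (control) or 1 (treatment)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def is_monotone(self) -> bool:
        """True if no subject returns after a missed occasion."""
        obs = self.observed.astype(int)
        return bool((np.diff(obs, axis=1) <= 0).all())

    def baseline_complete(self) -> bool:
        return bool(self.observed[:, 0].all())

    def validate_monotone(self) -> None:
        """Assert the simulated-dropout contract (complete baseline, monotone)."""
        if not self.baseline_complete():
            raise DesignError("baseline occasion must be fully observed")
        if not self.is_monotone():
            raise DesignError("missingness must be monotone (no returns after dropout)")

    def copy(self) -> "LongDataset":
        return LongDataset(
            self.values.copy(),
            self.observed.copy(),
            self.arm.copy(),
            self.subject_id.copy(),
            dict(self.audit) if self.audit is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format records: subject_id, arm, time_index (1-based), value, observed."""
        n, j = self.values.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_id, j),
                "arm": np.repeat(self.arm, j),
                "time_index": np.tile(np.arange(1, j + 1), n),
                "value": self.values.ravel(),
                "observed": self.observed.ravel().astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LongDataset":
        """Rebuild from the long format written by :meth:`to_frame`."""
        required = {"subject_id", "arm", "time_index", "value", "observed"}
        missing = required - set(frame.columns)
        if missing:
            raise DesignError(f"long-format frame missing columns: {sorted(missing)}")
        frame = frame.sort_values(["subject_id", "time_index"])
        times = np.sort(frame["time_index"].unique())
        j = len(times)
        subjects = frame["subject_id"].unique()
        n = len(subjects)
        if len(frame) != n * j:
            raise DesignError("every subject must have exactly one record per occasion")
        values = frame["value"].to_numpy(dtype=float).reshape(n, j)
        observed = frame["observed"].to_numpy().astype(bool).reshape(n, j)
        arm = frame.groupby("subject_id", sort=True)["arm"].first().to_numpy()
        return cls(values, observed, np.asarray(arm), subjects)


def make_linear_trajectory(
    baseline: float, final_effect: float, n_times: int
) -> MeanMatrix:
    """Control arm flat at ``baseline``; treatment arm rises linearly.

    The treatment mean is interpolated from ``baseline`` to
    ``baseline + final_effect`` across the ``n_times`` occasions, e.g. the
    default trial scenario runs 50 -> 54.18 over four visits with no change
    in the control group.
    """
    if n_times < 2:
        raise DesignError("a trajectory needs at least 2 occasions")
    control = np.full(n_times, float(baseline))
    treatment = np.linspace(baseline, baseline + final_effect, n_times)
    return MeanMatrix(np.vstack([control, treatment]))


def make_custom_trajectory(
    control_means: Sequence[float], treatment_means: Sequence[float]
) -> MeanMatrix:
    """Arbitrary (e.g. non-linear) mean trajectories for the two arms.

    Used for scenarios where the treatment effect is initially large and
    attenuates over time while the control group shows a transient bump;
    callers supply the cell means directly.
    """
    control = np.asarray(control_means, dtype=float)
    treatment = np.asarray(treatment_means, dtype=float)
    if control.shape != treatment.shape or control.ndim != 1:
        raise DesignError("control and treatment trajectories must have equal length")
    if control.size < 2:
        raise DesignError("a trajectory needs at least 2 occasions")
    return MeanMatrix(np.vstack([control, treatment]))


#: Illustrative non-linear trajectory: a large early treatment effect that
#: attenuates to the same 4.18 end-of-study difference, and a transient
#: control-group improvement that returns to baseline.
NONLINEAR_CONTROL = (50.0, 52.0, 51.0, 50.0)
NONLINEAR_TREATMENT = (50.0, 58.0, 56.0, 54.18)


def make_nonlinear_trajectory() -> MeanMatrix:
    """The package's default attenuating-effect trajectory (illustrative)."""
    return make_custom_trajectory(NONLINEAR_CONTROL, NONLINEAR_TREATMENT)


def variance_components(total_var: float, rho: float) -> VarianceSpec:
    """Split a total variance into between/within parts at correlation ``rho``.

    ``sigma_b_sq = rho * total_var``; ``sigma_e_sq = (1 - rho) * total_var``.
    """
    if total_var <= 0:
        raise DesignError("total_var must be > 0")
    if not 0.0 <= rho < 1.0:
        raise DesignError("rho must be in [0, 1)")
    return VarianceSpec(sigma_b_sq=rho * total_var, sigma_e_sq=(1.0 - rho) * total_var)


def simulate_trial(
    design: TrialDesign,
    means: MeanMatrix,
    variance: VarianceSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> LongDataset:
    """Draw one complete trial: ``Y_ij = mu[arm, j] + b_i + e_ij``.

    Subjects 1..n_per_arm are control, n_per_arm+1..2*n_per_arm treatment.
    The per-subject intercepts are drawn first, then the occasion noise, so
    identical seeds reproduce identical datasets bit for bit.
    """
    if means.n_times != design.n_times:
        raise DesignError(
            f"mean matrix has {means.n_times} occasions, design has {design.n_times}"
        )
    rng = np.random.default_rng(seed)
    n = design.n_total
    j = design.n_times
    arm = (np.arange(n) >= design.n_per_arm).astype(int)
    b = rng.normal(0.0, np.sqrt(variance.sigma_b_sq), size=n)
    e = rng.normal(0.0, np.sqrt(variance.sigma_e_sq), size=(n, j))
    values = means.mu[arm] + b[:, None] + e
    return LongDataset(
        values=values,
        observed=np.ones((n, j), dtype=bool),
        arm=arm,
        subject_id=np.arange(1, n + 1),
    )


def theoretical_ttest_power(
    n_per_arm: int, delta: float, sd: float, alpha: float = 0.05
) -> float:
    """Exact power of the two-sided pooled two-sample t-test.

    Uses the noncentral t distribution with noncentrality
    ``delta / (sd * sqrt(2/n))`` and ``2n - 2`` degrees of freedom. With
    n = 100 per arm, delta = 4.18 and sd = sqrt(110) this gives the 80%
    design power of the default trial.
    """
    if n_per_arm < 2 or sd <= 0:
        raise DesignError("need n_per_arm >= 2 and sd > 0")
    if not 0.0 < alpha < 1.0:
        raise DesignError("alpha must be in (0, 1)")
    df = 2 * n_per_arm - 2
    nc = delta / (sd * np.sqrt(2.0 / n_per_arm))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def write_long_csv(data: LongDataset, path) -> None:
    """Write long-format CSV (subject_id, arm, time_index, value, observed)."""
    frame = data.to_frame()
    frame.to_csv(path, index=False)


def read_written_csv(path) -> LongDataset:
    """Read back a CSV produced by :func:`write_long_csv`."""
    return LongDataset.from_frame(pd.read_csv(path))
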