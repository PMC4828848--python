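"""Monotone dropout under MCAR, MAR and MNAR selection.

Dropout is imposed wave by wave on an initially complete dataset. Baseline
is never deleted; once a subject drops, all later occasions are missing
(monotone dropout). The cumulative per-arm dropout rate by the final
occasion is the calibrated quantity:

* MCAR — every still-observed subject drops with the same constant per-wave
  hazard, independent of the outcome.
* MAR — the per-wave dropout probability is logistic in the *previous*
  occasion's observed value.
* MNAR — logistic in the *current* (about-to-be-deleted) value.

For outcome-dependent mechanisms the logistic intercept is recalibrated per
arm and wave on that replicate's at-risk subjects, so realized dropout
matches the target rate in expectation regardless of the selection slope.
Two directions of selection are supported: ``low_only`` (subjects feeling
particularly poorly stay home) and ``both_tails`` (poorly *or* particularly
well — the "vacation" mechanism), both measured from the population norm
of 50.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .trial_simulator import LongDataset, NORM_MEAN, DesignError

__all__ = [
    "DropoutSpec",
    "SCENARIOS",
    "make_scenario",
    "per_wave_rate",
    "calibrate_intercept",
    "apply_mcar",
    "apply_mar",
    "apply_mnar",
    "apply_dropout",
    "realized_dropout",
]

MECHANISMS = ("MCAR", "MAR", "MNAR")
REASONS = ("none", "low_only", "both_tails")

#: Default selection slope, in log-odds per score unit. 0.25 per unit is
#: strong selection (~ odds ratio 12 across one 10-point SD).
DEFAULT_SLOPE = 0.25


@dataclass(frozen=True)
class DropoutSpec:
    """Mechanism, direction of selection, and per-arm cumulative targets.

    ``target_rate_by_arm`` is indexed by arm code: (control, treatment).
    ``dependence_strength`` is the log-odds slope per score unit of the
    selection covariate (ignored under MCAR).
    """

    mechanism: str
    reasons: str = "none"
    target_rate_by_arm: tuple[float, float] = (0.4, 0.4)
    dependence_strength: float = DEFAULT_SLOPE
    schedule: str = "constant_hazard"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise DesignError(f"mechanism must be one of {MECHANISMS}")
        if self.reasons not in REASONS:
            raise DesignError(f"reasons must be one of {REASONS}")
        if self.mechanism == "MCAR" and self.reasons != "none":
            raise DesignError("MCAR dropout cannot have an outcome-based reason")
        if self.mechanism != "MCAR" and self.reasons == "none":
            raise DesignError("MAR/MNAR dropout needs a selection direction")
        for r in self.target_rate_by_arm:
            if not 0.0 <= r < 1.0:
                raise DesignError("target dropout rates must be in [0, 1)")
        if self.dependence_strength < 0:
            raise DesignError("dependence_strength must be >= 0")
        if self.schedule != "constant_hazard":
            raise DesignError("only the constant_hazard schedule is implemented")


#: Registry of the study's missingness scenarios. ``complete`` is the
#: no-dropout reference; the rest mirror the MCAR / MAR / MNAR grid with
#: equal (40%/40%) or unequal (50% control / 30% treatment) dropout and one
#: (low_only) or two (both_tails) reasons for dropping out.
SCENARIOS: dict[str, DropoutSpec | None] = {
    "complete": None,
    "mcar_equal": DropoutSpec("MCAR", "none", (0.4, 0.4), 0.0),
    "mar_unequal_one": DropoutSpec("MAR", "low_only", (0.5, 0.3)),
    "mar_unequal_two": DropoutSpec("MAR", "both_tails", (0.5, 0.3)),
    "mar_equal": DropoutSpec("MAR", "both_tails", (0.4, 0.4)),
    "mnar_unequal_one": DropoutSpec("MNAR", "low_only", (0.5, 0.3)),
    "mnar_unequal_two": DropoutSpec("MNAR", "both_tails", (0.5, 0.3)),
    "mnar_equal": DropoutSpec("MNAR", "both_tails", (0.4, 0.4)),
}


def make_scenario(key: str, missing_scale: float = 1.0) -> DropoutSpec | None:
    """Look up a registry scenario, optionally scaling the target rates.

    ``missing_scale`` supports reduced-missingness variants (e.g. 0.3 turns
    the 40/40 design into 12/12 percent dropout).
    """
    if key not in SCENARIOS:
        raise DesignError(f"unknown scenario {key!r}; known: {sorted(SCENARIOS)}")
    spec = SCENARIOS[key]
    if spec is None or missing_scale == 1.0:
        return spec
    scaled = tuple(r * missing_scale for r in spec.target_rate_by_arm)
    return replace(spec, target_rate_by_arm=scaled)


def per_wave_rate(cumulative: float, n_waves: int) -> float:
    """Constant per-wave hazard d with 1 - (1-d)^n_waves = cumulative."""
    if not 0.0 <= cumulative < 1.0:
        raise DesignError("cumulative dropout must be in [0, 1)")
    if n_waves < 1:
        raise DesignError("n_waves must be >= 1")
    return 1.0 - (1.0 - cumulative) ** (1.0 / n_waves)


def _calibrate_offset(eta: np.ndarray, target: float) -> float:
    """Solve mean(expit(alpha + eta)) = target for alpha (eta fixed offsets)."""
    if not 0.0 < target < 1.0:
        raise DesignError("calibration target must be strictly inside (0, 1)")
    eta = np.asarray(eta, dtype=float)
    if eta.size == 0:
        raise DesignError("cannot calibrate on an empty at-risk set")
    base = logit(target)
    lo = base - float(eta.max())
    hi = base - float(eta.min())
    if np.isclose(lo, hi):
        return base - float(eta[0])

    def f(alpha: float) -> float:
        return float(expit(alpha + eta).mean() - target)

    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def calibrate_intercept(values, slope: float, target: float) -> float:
    """Logistic intercept hitting a marginal dropout rate over ``values``.

    Returns alpha such that ``mean(expit(alpha + slope * (v - 50)))`` over
    the supplied values equals ``target`` (bracketed root-finding; the mean
    is matched to ~1e-12). Deviations are measured from the population norm
    of 50.
    """
    values = np.asarray(values, dtype=float)
    return _calibrate_offset(slope * (values - NORM_MEAN), target)


def _selection_covariate(y: np.ndarray, reasons: str) -> np.ndarray:
    """g(y): positive values mean higher dropout propensity."""
    dev = y - NORM_MEAN
    if reasons == "low_only":
        return -dev
    if reasons == "both_tails":
        return np.abs(dev)
    raise DesignError(f"no selection covariate for reasons={reasons!r}")


def _apply_selection(
    data: LongDataset,
    spec: DropoutSpec,
    seed,
    covariate_wave: str,
) -> LongDataset:
    """Shared wave loop for MCAR/MAR/MNAR ('prior'/'current'/'none' covariate)."""
    if not data.observed.all():
        raise DesignError("dropout mechanisms require a complete input dataset")
    data.validate_monotone()
    rng = np.random.default_rng(seed)
    out = data.copy()
    n_waves = data.n_times - 1
    hazards = [per_wave_rate(r, n_waves) for r in spec.target_rate_by_arm]
    for j in range(1, data.n_times):  # 0-based column of wave j+1
        for arm in (0, 1):
            d = hazards[arm]
            if d == 0.0:
                continue
            at_risk = np.flatnonzero((out.arm == arm) & out.observed[:, j])
            if at_risk.size == 0:
                continue
            if covariate_wave == "none" or spec.dependence_strength == 0.0:
                p = np.full(at_risk.size, d)
            else:
                col = j - 1 if covariate_wave == "prior" else j
                y = out.values[at_risk, col]
                eta = spec.dependence_strength * _selection_covariate(y, spec.reasons)
                alpha = _calibrate_offset(eta, d)
                p = expit(alpha + eta)
            drop = at_risk[rng.random(at_risk.size) < p]
            out.observed[drop, j:] = False
    return out


def apply_mcar(data: LongDataset, spec: DropoutSpec, seed) -> LongDataset:
    """Outcome-independent dropout at a constant per-wave hazard per arm."""
    if spec.mechanism != "MCAR":
        raise DesignError("apply_mcar requires an MCAR spec")
    return _apply_selection(data, spec, seed, "none")


def apply_mar(data: LongDataset, spec: DropoutSpec, seed) -> LongDataset:
    """Dropout logistic in the previous occasion's (observed) value."""
    if spec.mechanism != "MAR":
        raise DesignError("apply_mar requires a MAR spec")
    return _apply_selection(data, spec, seed, "prior")


def apply_mnar(data: LongDataset, spec: DropoutSpec, seed) -> LongDataset:
    """Dropout logistic in the current occasion's (deleted) value."""
    if spec.mechanism != "MNAR":
        raise DesignError("apply_mnar requires an MNAR spec")
    return _apply_selection(data, spec, seed, "current")


def apply_dropout(data: LongDataset, spec: DropoutSpec | None, seed) -> LongDataset:
    """Dispatch on the spec's mechanism; ``None`` means keep data complete."""
    if spec is None:
        return data
    return {
        "MCAR": apply_mcar,
        "MAR": apply_mar,
        "MNAR": apply_mnar,
    }[spec.mechanism](data, spec, seed)


def realized_dropout(data: LongDataset) -> np.ndarray:
    """Per-arm fraction of subjects unobserved at the final occasion."""
    missing_final = ~data.observed[:, -1]
    return np.array(
        [missing_final[data.arm == g].mean() if (data.arm == g).any() else 0.0
         for g in (0, 1)]
    )
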