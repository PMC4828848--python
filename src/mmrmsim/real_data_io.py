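"""Reading external longitudinal trial data and the three-way comparison.

Real studies (e.g. the HELP trial's SF-36 mental composite score, measured
at baseline and 6/12/18/24 months) arrive as long-format CSV with
study-specific column names and time codes. ``read_long_csv`` maps such a
file onto the package's wide layout. Unlike simulated dropout, real
missingness need not be monotone; non-monotone patterns are kept (the
observed-data MMRM likelihood handles arbitrary observed subsets) and
counted in the dataset's audit note. The reader never imputes — every
value it emits existed in the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trial_simulator import DesignError, LongDataset
from .estimators import (
    ContrastResult,
    EstimationError,
    complete_case_ttest,
    final_time_contrast,
    fit_mmrm,
)

__all__ = ["ColumnMap", "HELP_MCS_MAP", "read_long_csv", "run_example", "ExampleComparison"]


@dataclass(frozen=True)
class ColumnMap:
    """How a long-format file maps onto (subject, arm, occasion, value).

    ``time_levels`` lists the raw time codes in order; they become 1-based
    occasion indices. ``arm_levels`` is (control code, treatment code) —
    arm coding is always explicit, never inferred alphabetically.
    """

    subject_col: str
    arm_col: str
    time_col: str
    value_col: str
    time_levels: Sequence
    arm_levels: tuple = (0, 1)


#: Column map for the public HELP study dataset (helpfull.csv layout): the
#: mental composite score `mcs` by visit month, `treat` 0 = usual care.
HELP_MCS_MAP = ColumnMap(
    subject_col="id",
    arm_col="treat",
    time_col="time",
    value_col="mcs",
    time_levels=(0, 6, 12, 18, 24),
    arm_levels=(0, 1),
)


def read_long_csv(path, colmap: ColumnMap) -> LongDataset:
    """Read a long-format CSV into a :class:`LongDataset`.

    Absent (subject, time) rows and empty values become ``observed=False``
    with a NaN placeholder value. Duplicate (subject, time) rows and
    unmappable arm codes raise with the offending row numbers. The returned
    dataset's ``audit`` dict reports subject counts per arm and the number
    of non-monotone missingness patterns.
    """
    frame = pd.read_csv(path)
    for col in (colmap.subject_col, colmap.arm_col, colmap.time_col, colmap.value_col):
        if col not in frame.columns:
            raise DesignError(f"column {col!r} not found in {path}")
    keep = frame[frame[colmap.time_col].isin(list(colmap.time_levels))].copy()
    dup = keep.duplicated([colmap.subject_col, colmap.time_col], keep=False)
    if dup.any():
        rows = (keep.index[dup] + 2).tolist()[:5]  # header is line 1
        raise DesignError(f"duplicate (subject, time) records at file lines {rows}")
    arm_codes = {colmap.arm_levels[0]: 0, colmap.arm_levels[1]: 1}
    bad = ~keep[colmap.arm_col].isin(list(arm_codes))
    if bad.any():
        row = int(keep.index[bad][0]) + 2
        val = keep.loc[keep.index[bad][0], colmap.arm_col]
        raise DesignError(
            f"unmappable arm value {val!r} at file line {row}; "
            f"expected one of {colmap.arm_levels}"
        )

    time_pos = {t: j for j, t in enumerate(colmap.time_levels)}
    subjects = np.sort(keep[colmap.subject_col].unique())
    sub_pos = {s: i for i, s in enumerate(subjects)}
    n, J = len(subjects), len(colmap.time_levels)
    values = np.full((n, J), np.nan)
    observed = np.zeros((n, J), dtype=bool)
    arm = np.zeros(n, dtype=int)
    for _, rec in keep.iterrows():
        i = sub_pos[rec[colmap.subject_col]]
        j = time_pos[rec[colmap.time_col]]
        arm[i] = arm_codes[rec[colmap.arm_col]]
        v = rec[colmap.value_col]
        if pd.notna(v):
            values[i, j] = float(v)
            observed[i, j] = True
    obs_int = observed.astype(int)
    non_monotone = int((np.diff(obs_int, axis=1) > 0).any(axis=1).sum())
    audit = {
        "n_subjects": n,
        "n_control": int((arm == 0).sum()),
        "n_treatment": int((arm == 1).sum()),
        "n_non_monotone": non_monotone,
    }
    return LongDataset(values, observed, arm, subjects, audit=audit)


@dataclass
class ExampleComparison:
    """The three contrasts at one occasion, with per-method failure notes."""

    time_index: int
    ttest: ContrastResult | None
    mmrm_cs: ContrastResult | None
    mmrm_un: ContrastResult | None
    notes: dict[str, str]

    def results(self) -> dict[str, ContrastResult | None]:
        return {"ttest": self.ttest, "mmrm_cs": self.mmrm_cs, "mmrm_un": self.mmrm_un}

    def report(self) -> str:
        lines = [f"Treatment contrast at occasion {self.time_index}"]
        for name, r in self.results().items():
            if r is None:
                lines.append(f"  {name:8s}: unavailable ({self.notes[name]})")
            else:
                lines.append(
                    f"  {name:8s}: estimate {r.estimate:6.2f}  SE {r.std_error:5.2f}"
                    f"  p {r.p_value:.4f}  (n = {r.n_used[0]} + {r.n_used[1]})"
                )
        return "\n".join(lines)


def run_example(data: LongDataset, time_index: int | None = None) -> ExampleComparison:
    """Compare t-test, MMRM-CS and MMRM-UN contrasts at one occasion.

    The t-test can fail where the MMRM is still estimable (e.g. an arm with
    no completers at the target occasion but data earlier); such asymmetries
    are reported in the comparison's notes rather than raised.
    """
    j = data.n_times if time_index is None else int(time_index)
    results: dict[str, ContrastResult | None] = {}
    notes: dict[str, str] = {}
    try:
        results["ttest"] = complete_case_ttest(data, j)
    except EstimationError as err:
        results["ttest"] = None
        notes["ttest"] = str(err)
    for name, structure in (("mmrm_cs", "CS"), ("mmrm_un", "UN")):
        try:
            fit = fit_mmrm(data, structure=structure)
            results[name] = final_time_contrast(fit, j)
            if not fit.converged:
                notes[name] = "optimizer did not report convergence"
        except (EstimationError, np.linalg.LinAlgError) as err:
            results[name] = None
            notes[name] = str(err)
    return ExampleComparison(j, results["ttest"], results["mmrm_cs"], results["mmrm_un"], notes)
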