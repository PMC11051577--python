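"""Validation of fitting approaches through the prediction-error metric.

The prediction error (PE) is a median-based modification of the mean
absolute error: for each variable the median over subjects and stimulus
levels of the absolute relative error is taken, and the overall PE is 100
times the mean of those per-variable medians::

    PE% = 100 * (1/N) * sum_j median_{i,k} | (yexp - ysim) / yexp |

with N variables, i subjects and k stimulus levels. The median makes the
metric robust to the occasional badly predicted cell.

Three parameter sets are compared on the same record: the time-specific fit
(gold standard of the optimization), the traditional single-time fit (the
first record's population fit carried forward), and the dynamic fit (ARX
trend predictions). Per-(subject, variable) median errors are paired across
approaches and tested with the Wilcoxon signed-rank test (exact null
distribution up to n = 25, normal approximation with continuity correction
beyond).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import erfc, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DynfitError
from .model import EnvironmentConditions, PhysiologicalModel
from .parameters import ParameterSet
from .records import LongitudinalRecord

EXACT_WILCOXON_MAX_N = 25


@dataclass
class PEReport:
    """Per-variable and overall prediction-error summary for one approach."""

    approach: str
    per_variable: pd.DataFrame   # index variable, columns median/iqr (fractions)
    overall_pe: float            # percent
    n_subjects: int
    n_variables: int
    n_levels: int

    def __post_init__(self) -> None:
        expected = 100.0 * float(self.per_variable["median"].mean())
        if abs(self.overall_pe - expected) > 1e-9:
            raise ValueError("overall_pe must equal the mean of per-variable medians")


@dataclass
class ComparisonReport:
    """Pairwise Wilcoxon comparison of the approaches' paired PE samples."""

    p_values: dict[tuple[str, str], float]
    pairing: str
    alpha_mild: float = 0.05
    alpha_strong: float = 0.01

    def significance(self, a: str, b: str) -> str:
        """'**' for p < 0.01, '*' for p < 0.05, '' otherwise."""
        p = self.p_values[self._key(a, b)]
        if p < self.alpha_strong:
            return "**"
        if p < self.alpha_mild:
            return "*"
        return ""

    def _key(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if (a, b) in self.p_values else (b, a)


def _check_positive_exp(exp: np.ndarray) -> None:
    if np.any(exp == 0):
        idx = tuple(int(v) for v in np.argwhere(exp == 0)[0])
        raise ZeroDivisionError(f"experimental value is zero at cell {idx}")


def prediction_error(
    exp: np.ndarray,
    sim: np.ndarray,
    variables: Sequence[str],
    approach: str = "",
) -> PEReport:
    """PE report over arrays indexed ``(subject, variable, level)``.

    Two-dimensional input ``(variable, level)`` is treated as one subject.
    """
    exp = np.asarray(exp, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if exp.shape != sim.shape:
        raise ValueError(f"shape mismatch: exp {exp.shape} vs sim {sim.shape}")
    if exp.ndim == 2:
        exp, sim = exp[None], sim[None]
    _check_positive_exp(exp)
    rel = np.abs((exp - sim) / exp)  # (subject, variable, level)
    med = np.median(rel, axis=(0, 2))
    q1 = np.quantile(rel, 0.25, axis=(0, 2))
    q3 = np.quantile(rel, 0.75, axis=(0, 2))
    per_var = pd.DataFrame(
        {"median": med, "iqr": q3 - q1}, index=list(variables)[: exp.shape[1]]
    )
    return PEReport(
        approach=approach,
        per_variable=per_var,
        overall_pe=100.0 * float(med.mean()),
        n_subjects=exp.shape[0],
        n_variables=exp.shape[1],
        n_levels=exp.shape[2],
    )


def _signed_ranks(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of |diff| and the signs, zero differences already removed."""
    absd = np.abs(diff)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty_like(absd)
    ranks[order] = np.arange(1, absd.size + 1, dtype=float)
    # mid-rank ties
    for v in np.unique(absd):
        mask = absd == v
        if mask.sum() > 1:
            ranks[mask] = ranks[mask].mean()
    return ranks, np.sign(diff)


def _exact_p_value(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p-value by dynamic programming over the 2^n sign flips.

    Ranks are doubled to integers (mid-ranks are half-integers), and the
    distribution of the positive-rank sum is built by convolution.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; ties get mid-ranks. The null distribution
    is enumerated exactly for up to 25 remaining pairs and approximated by a
    continuity-corrected normal beyond that. All-zero differences are the
    degenerate case and return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        return 1.0
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    ranks, signs = _signed_ranks(diff)
    w_plus = float(ranks[signs > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        return _exact_p_value(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # variance with tie correction
    _, counts = np.unique(np.abs(diff), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / sqrt(var)
    return float(erfc(abs(z) / sqrt(2.0)))


def compare_approaches(
    record: LongitudinalRecord,
    model: PhysiologicalModel,
    param_sets: Mapping[str, ParameterSet],
    stimuli=None,
) -> tuple[dict[str, PEReport], ComparisonReport]:
    """Simulate one record under several parameter sets and compare their PEs.

    ``param_sets`` maps approach labels (e.g. ``time_specific``,
    ``single_time``, ``dynamic``) to parameter sets. ``stimuli`` overrides the
    record's own stimulus grid (used when the grid must derive from the
    preceding record's AT for consistency with the dynamic approach); the
    record's observations are then interpolated onto the override grid along
    the VCO2 axis so that experiment and simulation are compared at the same
    stimulus values (end values are clamped when the override grid extends
    past the measured range). Approaches whose simulation fails are dropped
    from the comparison.
    """
    variables = list(model.variable_names)
    exp = record.observation_matrix(variables)
    if stimuli is None:
        stims = record.stimuli
    else:
        stims = list(stimuli)
        grid = np.array([s.vco2 for s in stims])
        exp = np.vstack([
            np.interp(grid, record.stimulus_vco2, exp[i]) for i in range(exp.shape[0])
        ])
    reports: dict[str, PEReport] = {}
    paired: dict[str, np.ndarray] = {}
    for label, params in param_sets.items():
        try:
            sim = model.simulate_grid(params, stims, record.env)
        except DynfitError:
            continue
        reports[label] = prediction_error(exp, sim, variables, approach=label)
        # pairing unit: per-(subject, variable) median absolute relative error
        paired[label] = np.median(np.abs((exp - sim) / exp), axis=1)
    p_values = {}
    for a, b in combinations(paired, 2):
        p_values[(a, b)] = wilcoxon_signed_rank(paired[a], paired[b])
    comparison = ComparisonReport(
        p_values=p_values, pairing="per-(subject, variable) median absolute relative error",
    )
    return reports, comparison


def validation_table(reports: Mapping[str, PEReport]) -> pd.DataFrame:
    """Stacked per-variable medians/IQRs (%) and overall PE per approach."""
    frames = []
    for label, rep in reports.items():
        df = 100.0 * rep.per_variable.copy()
        df.insert(0, "approach", label)
        df["overall_pe"] = rep.overall_pe
        frames.append(df.reset_index(names="variable"))
    return pd.concat(frames, ignore_index=True)
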