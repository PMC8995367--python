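"""Confidence sets, the Confidence Modulation Index, and descriptive surfaces.

The confidence forced-choice paradigm yields, per trial, one decision
"chosen" as relatively more confident.  Splitting decisions into the
*chosen* set (one decision per trial) and the *unsorted* set (every
decision) and fitting a psychometric function to each gives two contrast
sensitivities whose relative gain is the Confidence Modulation Index

    CMI = 100 * (sensitivity_chosen - sensitivity_unsorted) / sensitivity_unsorted

An observer whose confidence choices are unrelated to the quality of the
underlying evidence has CMI near zero; the tighter the link, the larger the
CMI.  Being a proportional measure, CMIs are arcsine-square-root
transformed before inferential statistics; outliers are flagged with Tukey
fences on the untransformed values over the pooled sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psychometric import PsychometricFit, aggregate_proportions, fit_cumulative_gaussian

CONDITIONS = ("lower_lower", "lower_higher", "higher_lower", "higher_higher",
              "aggregate")


def split_sets(trials: pd.DataFrame,
               decisions: pd.DataFrame | None = None,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a session into (chosen, unsorted) decision sets.

    ``chosen`` holds exactly the decision selected in the confidence task on
    each trial (confidence code 1); ``unsorted`` is the ensemble of all
    perceptual decisions, each carrying its 0/1 confidence code.
    """
    from .design import decisions_long

    bad = ~trials["conf_choice"].isin((1, 2))
    if bad.any():
        ids = trials.loc[bad, "trial"].tolist()
        raise ValueError(f"missing/invalid conf_choice on trials {ids}")
    unsorted_set = decisions_long(trials) if decisions is None else decisions
    chosen = unsorted_set[unsorted_set["confident"] == 1].copy()
    return chosen, unsorted_set


def fit_confidence_sets(trials: pd.DataFrame
                        ) -> tuple[PsychometricFit, PsychometricFit]:
    """Psychometric fits of the chosen and unsorted sets of one session."""
    chosen, unsorted_set = split_sets(trials)
    fit_c = fit_cumulative_gaussian(
        aggregate_proportions(chosen["delta"], chosen["decision"]))
    fit_u = fit_cumulative_gaussian(
        aggregate_proportions(unsorted_set["delta"], unsorted_set["decision"]))
    return fit_c, fit_u


def cmi(sens_chosen: float, sens_unsorted: float) -> float:
    """Confidence Modulation Index: percent sensitivity gain of the chosen
    over the unsorted set."""
    if sens_unsorted <= 0:
        raise ValueError("unsorted sensitivity must be positive "
                         "(degenerate psychometric fit upstream)")
    return 100.0 * (sens_chosen - sens_unsorted) / sens_unsorted


def transform_cmi(cmi_value: float) -> float:
    """Signed arcsine-square-root transform of a CMI (percent scale).

    ``sign(c) * arcsin(sqrt(|c|/100))``: odd, strictly monotone, equal to
    the plain arcsine-square-root transform for non-negative values.
    Values beyond +/-100 are clipped with a warning.
    """
    c = np.asarray(cmi_value, dtype=float)
    if np.any(np.abs(c) > 100):
        warnings.warn("CMI beyond +/-100 clipped before transform",
                      RuntimeWarning)
        c = np.clip(c, -100.0, 100.0)
    out = np.sign(c) * np.arcsin(np.sqrt(np.abs(c) / 100.0))
    return float(out) if np.isscalar(cmi_value) else out


def flag_outliers(values) -> np.ndarray:
    """Tukey-fence outlier flags (1.5 x IQR beyond the quartiles).

    Quartiles use linear interpolation; the fences are computed once from
    the complete sample passed in.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need >= 4 values for quartile-based fences")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


@dataclass(frozen=True)
class ConfidenceResult:
    """Per-participant confidence-efficiency summary."""

    participant_id: str
    sensitivity_chosen: float
    sensitivity_unsorted: float
    cmi: float
    cmi_transformed: float
    outlier: bool = False


def confidence_by_difficulty(trials: pd.DataFrame, n_boot: int = 2000,
                             seed: int = 0) -> pd.DataFrame:
    """Mean confidence by task difficulty and correctness.

    Per absolute contrast difference and correctness class, the mean of the
    0/1 confidence codes with a percentile bootstrap 95% CI (confidence
    judgements are collapsed across the other task's difficulty).  Decisions
    at zero contrast difference, whose correctness label is arbitrary, form
    their own class.
    """
    from .design import decisions_long

    dec = decisions_long(trials)
    dec["difficulty"] = dec["delta"].abs()
    rng = np.random.default_rng(seed)
    rows = []
    for (diff, corr), grp in dec.groupby(["difficulty", "correct"]):
        x = grp["confident"].to_numpy(dtype=float)
        boots = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"difficulty": diff, "correct": corr,
                     "mean_confidence": x.mean(), "ci_low": lo, "ci_high": hi,
                     "n": x.size})
    return pd.DataFrame(rows)


@dataclass
class ConfidenceMap:
    """Probability of choosing the first decision as more confident,
    indexed by (task-1 delta, task-2 delta).

    ``grid`` rows are task-1 deltas, columns task-2 deltas; cells that never
    occur are NaN (undefined).  ``counts`` holds trials per cell.
    """

    grid: pd.DataFrame
    counts: pd.DataFrame
    condition: str

    def to_long(self) -> pd.DataFrame:
        long = self.grid.stack(future_stack=True).rename("p").reset_index()
        long.columns = ["delta1", "delta2", "p"]
        long["n"] = self.counts.stack(future_stack=True).to_numpy()
        long["condition"] = self.condition
        return long


def choice_probability_map(trials: pd.DataFrame,
                           condition: str = "aggregate") -> ConfidenceMap:
    """Empirical confidence-choice map for one decision combination.

    ``condition`` is 'aggregate' or '<decision1>_<decision2>' with each part
    'lower' or 'higher' (the report about the test patch in tasks 1 and 2).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {CONDITIONS}")
    sub = trials
    if condition != "aggregate":
        d1, d2 = condition.split("_")
        sub = trials[(trials["decision1"] == d1) & (trials["decision2"] == d2)]
    deltas1 = np.unique(trials["task1_delta"])
    deltas2 = np.unique(trials["task2_delta"])
    counts = pd.DataFrame(0, index=deltas1, columns=deltas2, dtype=int)
    first = pd.DataFrame(0, index=deltas1, columns=deltas2, dtype=int)
    grp = sub.groupby(["task1_delta", "task2_delta"])["conf_choice"]
    agg = grp.agg(n="size", k=lambda s: int((s == 1).sum()))
    for (a, b), row in agg.iterrows():
        counts.loc[a, b] = row["n"]
        first.loc[a, b] = row["k"]
    with np.errstate(invalid="ignore"):
        grid = first / counts.where(counts > 0)
    return ConfidenceMap(grid=grid, counts=counts, condition=condition)
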