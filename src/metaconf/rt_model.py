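"""Exponential response-time model separating stimulus intensity and
confidence effects.

Stimulus values are first normalized per participant: ``S`` is the signed
distance between a contrast-difference level and the point of subjective
equality, in SD units of the (unsorted-set) psychometric function.  Median
RTs are computed per level for the chosen and the unsorted confidence sets
(the chosen set has mean confidence code C = 1 by construction, the
unsorted set the fraction of its decisions that were chosen), and the model

    RT(S) = alpha - beta * exp(-S^2 / 2) - gamma * C

is fitted by least squares over all cells jointly.  ``alpha`` is the
generic RT, ``beta`` the exponential RT change with stimulus intensity
(negative when responses slow down near the PSE) and ``gamma`` the linear
RT change with confidence (positive when confident decisions are faster).
The model is linear in its parameters, so the least-squares problem is
solved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psychometric import PsychometricFit


@dataclass(frozen=True)
class RTModelFit:
    """Exponential RT model parameters for one participant."""

    alpha: float
    beta: float
    gamma: float
    rss: float
    n_cells: int

    def predict(self, s, c) -> np.ndarray:
        s = np.asarray(s, float)
        return self.alpha - self.beta * np.exp(-0.5 * s**2) - self.gamma * c


def cell_medians(decisions: pd.DataFrame, fit_unsorted: PsychometricFit,
                 ) -> pd.DataFrame:
    """Median RT cells per confidence set and stimulus level.

    ``decisions`` is a decision-level table (already RT-filtered) carrying
    ``delta``, ``rt_ms`` and the 0/1 ``confident`` code.  ``S`` is computed
    from the unsorted-set psychometric fit so both sets share one
    normalization.  Empty cells are omitted with a warning.

    Returns a table with columns set_label, delta, S, median_rt_ms, C, n.
    """
    levels = np.sort(decisions["delta"].unique())
    rows = []
    for set_label in ("chosen", "unsorted"):
        sub = decisions if set_label == "unsorted" \
            else decisions[decisions["confident"] == 1]
        for delta in levels:
            cell = sub[sub["delta"] == delta]
            if len(cell) == 0:
                warnings.warn(
                    f"empty RT cell ({set_label}, delta={delta}) omitted",
                    RuntimeWarning)
                continue
            rows.append({
                "set_label": set_label,
                "delta": float(delta),
                "S": (delta - fit_unsorted.mu) / fit_unsorted.sigma,
                "median_rt_ms": float(cell["rt_ms"].median()),
                "C": float(cell["confident"].mean()),
                "n": len(cell),
            })
    return pd.DataFrame(rows)


def fit_rt_model(cells: pd.DataFrame) -> RTModelFit:
    """Exact least-squares fit of the exponential RT model over all cells.

    Requires at least 4 cells with at least 2 distinct S values and 2
    distinct C values; otherwise beta or gamma is unidentifiable and an
    error names the missing variation.
    """
    if len(cells) < 4:
        raise ValueError(f"need >= 4 RT cells, got {len(cells)}")
    s = cells["S"].to_numpy(dtype=float)
    c = cells["C"].to_numpy(dtype=float)
    rt = cells["median_rt_ms"].to_numpy(dtype=float)
    g = np.exp(-0.5 * s**2)
    if np.unique(np.round(g, 12)).size < 2:
        raise ValueError("beta unidentifiable: all cells share one "
                         "exp(-S^2/2) value (need >= 2 distinct |S|)")
    if np.unique(np.round(c, 12)).size < 2:
        raise ValueError("gamma unidentifiable: mean confidence C constant "
                         "across cells (need both confidence sets)")
    design = np.column_stack([np.ones_like(s), -g, -c])
    coef, _, rank, _ = np.linalg.lstsq(design, rt, rcond=None)
    if rank < 3:
        raise ValueError("RT design is rank deficient: S and C variation "
                         "are collinear")
    resid = rt - design @ coef
    return RTModelFit(alpha=float(coef[0]), beta=float(coef[1]),
                      gamma=float(coef[2]), rss=float(resid @ resid),
                      n_cells=len(cells))
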