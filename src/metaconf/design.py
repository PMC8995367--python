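"""Experimental design, trial-level data model, tabular I/O and RT filtering.

The confidence forced-choice paradigm collects, on every trial, two
consecutive contrast discrimination decisions (test patch vs. a 22% standard)
followed by a single confidence choice between them.  The contrast of each
test patch is drawn by the method of constant stimuli from seven levels
(13-31% in steps of 3%), independently for the two task positions, so a
default session has 7 levels x 60 repetitions = 420 trials split into 6
blocks of 70.

Trial tables are plain :class:`pandas.DataFrame` objects with one row per
trial (schema in :data:`TRIAL_COLUMNS`); decision-level analyses use the
long format produced by :func:`decisions_long` (two rows per trial, one per
perceptual decision).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("metaconf")

#: Allowed values for categorical trial fields.
SIDES = ("left", "right")
DECISIONS = ("higher", "lower")
CONF_CHOICES = (1, 2)

#: Column order of a session table (one row per trial).
TRIAL_COLUMNS = [
    "participant_id", "block", "trial",
    "task1_delta", "task1_side", "decision1", "rt1_ms",
    "task2_delta", "task2_side", "decision2", "rt2_ms",
    "conf_choice",
]

#: Column order of a participants table.
PARTICIPANT_COLUMNS = [
    "participant_id", "age_group", "age",
    "dsst", "tmt_b_s", "vst_c_s", "lps3", "digit_span",
]

COGNITIVE_MEASURES = ("dsst", "tmt_b_s", "vst_c_s", "lps3", "digit_span")


@dataclass(frozen=True)
class DesignSpec:
    """Method-of-constant-stimuli design for one session.

    Parameters
    ----------
    levels
        Test-patch contrasts in percent.  The study used 13..31 in steps
        of 3.
    standard
        Standard-patch contrast in percent (22 in the study).
    reps_per_level
        Repetitions of each level *per task position*.
    blocks
        Number of equally sized blocks the session is divided into.
    """

    levels: tuple[float, ...] = (13.0, 16.0, 19.0, 22.0, 25.0, 28.0, 31.0)
    standard: float = 22.0
    reps_per_level: int = 60
    blocks: int = 6

    @property
    def n_trials(self) -> int:
        return len(self.levels) * self.reps_per_level

    @property
    def deltas(self) -> np.ndarray:
        """Signed contrast differences test - standard, in % contrast."""
        return np.asarray(self.levels, dtype=float) - float(self.standard)

    def validate(self) -> None:
        if len(self.levels) == 0:
            raise ValueError("design needs at least one contrast level")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("contrast levels must be unique")
        if self.reps_per_level < 1 or self.blocks < 1:
            raise ValueError("reps_per_level and blocks must be positive")
        rem = self.n_trials % self.blocks
        if rem:
            raise ValueError(
                f"{self.n_trials} trials cannot be divided into "
                f"{self.blocks} equal blocks (remainder {rem})"
            )


def generate_design(spec: DesignSpec = DesignSpec(), seed: int = 0,
                    participant_id: str = "sim") -> pd.DataFrame:
    """Generate trial templates (deltas, sides, block structure; no responses).

    Each contrast level appears exactly ``reps_per_level`` times in each task
    position; the two positions are counterbalanced independently and the
    trial order is shuffled deterministically by ``seed``.  Response columns
    (decisions, RTs, confidence choice) are left as NA.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_trials
    deltas = spec.deltas
    # exact marginal counts per task position, independent randomisation
    d1 = rng.permutation(np.repeat(deltas, spec.reps_per_level))
    d2 = rng.permutation(np.repeat(deltas, spec.reps_per_level))
    per_block = n // spec.blocks
    df = pd.DataFrame({
        "participant_id": participant_id,
        "block": np.repeat(np.arange(1, spec.blocks + 1), per_block),
        "trial": np.arange(1, n + 1),
        "task1_delta": d1,
        "task1_side": rng.choice(SIDES, size=n),
        "decision1": pd.array([pd.NA] * n, dtype="string"),
        "rt1_ms": np.nan,
        "task2_delta": d2,
        "task2_side": rng.choice(SIDES, size=n),
        "decision2": pd.array([pd.NA] * n, dtype="string"),
        "rt2_ms": np.nan,
        "conf_choice": pd.array([pd.NA] * n, dtype="Int64"),
    })
    return df[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# validation and I/O
# ---------------------------------------------------------------------------

def validate_trials(trials: pd.DataFrame, spec: DesignSpec | None = None,
                    responses_required: bool = True) -> None:
    """Check a session table against the trial-record invariants.

    Raises ``ValueError`` naming the first offending row (1-based file row
    counting excluding the header, i.e. the dataframe position + 1).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if spec is not None:
        allowed = set(np.round(spec.deltas, 9))
        for col in ("task1_delta", "task2_delta"):
            bad = ~trials[col].round(9).isin(allowed)
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 1
                raise ValueError(
                    f"row {row}: {col} = {trials[col].iloc[row - 1]} not in "
                    f"design deltas {sorted(allowed)}"
                )
    for col in ("task1_side", "task2_side"):
        bad = ~trials[col].isin(SIDES)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(f"row {row}: {col} must be one of {SIDES}")
    if responses_required:
        for col in ("decision1", "decision2"):
            bad = ~trials[col].isin(DECISIONS)
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 1
                raise ValueError(
                    f"row {row}: {col} must be one of {DECISIONS}")
        bad = ~trials["conf_choice"].isin(CONF_CHOICES)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(
                f"row {row}: conf_choice = {trials['conf_choice'].iloc[row - 1]}"
                f" must be 1 or 2")
        for col in ("rt1_ms", "rt2_ms"):
            vals = pd.to_numeric(trials[col], errors="coerce")
            bad = ~(vals > 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise ValueError(f"row {row}: {col} must be positive")
    logger.debug("validated %d trial rows", len(trials))


def write_session_table(trials: pd.DataFrame, path) -> None:
    """Write a session table as comma-separated text (full float precision)."""
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_session_table(path, spec: DesignSpec | None = None,
                       participants: pd.DataFrame | None = None,
                       ) -> tuple[pd.Series | None, pd.DataFrame]:
    """Read and validate one session file.

    Returns ``(participant_record, trials)``; the participant record is the
    matching row of ``participants`` if a participants table is supplied,
    else ``None``.
    """
    trials = pd.read_csv(path, dtype={"participant_id": str})
    validate_trials(trials, spec=spec)
    trials["conf_choice"] = trials["conf_choice"].astype(int)
    record = None
    if participants is not None:
        pid = trials["participant_id"].iloc[0]
        match = participants[participants["participant_id"] == pid]
        if match.empty:
            raise ValueError(f"participant {pid!r} not in participants table")
        record = match.iloc[0]
    logger.info("read %d trials from %s", len(trials), path)
    return record, trials


def write_participants_table(records: pd.DataFrame, path) -> None:
    records[PARTICIPANT_COLUMNS].to_csv(path, index=False)


def read_participants_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"participants table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# decision-level view
# ---------------------------------------------------------------------------

def correctness(delta: np.ndarray, decision: np.ndarray) -> np.ndarray:
    """Correctness labels; decisions at zero contrast difference are
    'arbitrary' (there is no correct answer when test == standard)."""
    higher = np.asarray(decision) == "higher"
    delta = np.asarray(delta, dtype=float)
    out = np.where((delta > 0) == higher, "correct", "incorrect")
    return np.where(delta == 0, "arbitrary", out)


def decisions_long(trials: pd.DataFrame) -> pd.DataFrame:
    """Expand a session table to one row per perceptual decision.

    Columns: participant_id, trial, position (1 or 2), delta, decision,
    rt_ms, confident (1 if this decision was selected in the confidence
    choice, else 0), correct ('correct'/'incorrect'/'arbitrary').
    """
    frames = []
    for pos in (1, 2):
        frames.append(pd.DataFrame({
            "participant_id": trials["participant_id"],
            "trial": trials["trial"],
            "position": pos,
            "delta": trials[f"task{pos}_delta"].astype(float),
            "decision": trials[f"decision{pos}"],
            "rt_ms": trials[f"rt{pos}_ms"].astype(float),
            "confident": (trials["conf_choice"] == pos).astype(int),
        }))
    out = pd.concat(frames, ignore_index=True)
    out["correct"] = correctness(out["delta"], out["decision"])
    return out


def filter_rts(decisions: pd.DataFrame, low_ms: float = 100.0,
               high_ms: float = 3000.0) -> tuple[pd.DataFrame, pd.Series]:
    """Discard anticipatory/delayed decisions from RT analyses.

    A perceptual decision is excluded when its RT is below ``low_ms`` or
    above ``high_ms``.  Returns the kept decision rows and the exclusion
    rate per participant (fraction of decisions removed).  The exclusion
    applies to RT analyses only; psychometric and confidence analyses use
    the unfiltered decisions.
    """
    if len(decisions) == 0:
        return decisions.copy(), pd.Series(dtype=float, name="exclusion_rate")
    ok = (decisions["rt_ms"] >= low_ms) & (decisions["rt_ms"] <= high_ms)
    rate = (~ok).groupby(decisions["participant_id"]).mean()
    rate.name = "exclusion_rate"
    dropped = int((~ok).sum())
    if dropped:
        logger.info("RT filter removed %d of %d decisions", dropped, len(ok))
    return decisions[ok].copy(), rate


@dataclass
class ParticipantRecord:
    """Per-participant covariates (Table-1-style cognitive battery)."""

    participant_id: str
    age_group: str
    age: float
    dsst: float
    tmt_b_s: float
    vst_c_s: float
    lps3: float
    digit_span: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARTICIPANT_COLUMNS}
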