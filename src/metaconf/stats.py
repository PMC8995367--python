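"""Group statistics: EF composite, mixed ANOVA, t-family tests with a
Levene gate, effect sizes, percentile-bootstrap CIs and (partial)
correlations.

All tests are two-sided at alpha = 0.05.  Bootstrap CIs are 95% percentile
intervals from 2000 resamples with the participant as the resampling unit
(stratified by group for between-group contrasts), reproducible by seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

ALPHA = 0.05
N_BOOT = 2000


@dataclass(frozen=True)
class StatResult:
    """One inferential test: statistic, df, p, effect size, optional CI."""

    name: str
    statistic: float
    df: float
    p: float
    effect_size: float = np.nan
    effect_size_type: str = ""
    ci_low: float = np.nan
    ci_high: float = np.nan
    note: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "name", "statistic", "df", "p", "effect_size",
            "effect_size_type", "ci_low", "ci_high", "note")}


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# EF composite
# ---------------------------------------------------------------------------

def ef_composite(records: pd.DataFrame) -> pd.DataFrame:
    """Executive-function composite: mean of four oriented z-scores.

    DSST and LPS-3 are z-scored as-is; the timed measures TMT-B and VST-C
    are negated first so that higher always means better cognitive control.
    z-scores are computed over the pooled sample passed in.  Participants
    with a missing measure are excluded with a warning.
    """
    needed = ["dsst", "tmt_b_s", "vst_c_s", "lps3"]
    records = records.copy()
    complete = records[needed].notna().all(axis=1)
    if not complete.all():
        import warnings
        dropped = records.loc[~complete, "participant_id"].tolist()
        warnings.warn(f"participants with missing EF measures excluded: "
                      f"{dropped}", RuntimeWarning)
        records = records[complete]
    oriented = pd.DataFrame({
        "z_dsst": records["dsst"],
        "z_tmtb": -records["tmt_b_s"],
        "z_vstc": -records["vst_c_s"],
        "z_lps3": records["lps3"],
    })
    z = (oriented - oriented.mean()) / oriented.std(ddof=1)
    out = pd.DataFrame({"participant_id": records["participant_id"]})
    out = pd.concat([out.reset_index(drop=True), z.reset_index(drop=True)],
                    axis=1)
    out["ef"] = z.mean(axis=1).to_numpy()
    return out


# ---------------------------------------------------------------------------
# ANOVA and t-family
# ---------------------------------------------------------------------------

def mixed_anova(data: pd.DataFrame, dv: str, within: str, subject: str,
                between: str) -> list[StatResult]:
    """2 x 2 mixed-design ANOVA (classical sums of squares).

    Long-format input with one within-subject factor (2 levels) and one
    between-subject factor (2 levels), complete cells.  Returns the
    between main effect, the within main effect and their interaction,
    each with partial eta squared.
    """
    counts = data.groupby([subject, within]).size()
    if (counts != 1).any():
        raise ValueError("each subject needs exactly one value per "
                         "within-factor level")
    if data.groupby(subject)[within].nunique().nunique() != 1 or \
            data[within].nunique() != 2:
        raise ValueError("within factor must have exactly 2 complete levels")
    if data[dv].nunique() == 1:
        import warnings
        warnings.warn("degenerate data: dv constant, F undefined",
                      RuntimeWarning)
    aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                         between=between, correction=False)
    out = []
    for _, row in aov.iterrows():
        label = {between: f"main effect {between}",
                 within: f"main effect {within}",
                 "Interaction": f"interaction {between} x {within}"}.get(
                     row["Source"], row["Source"])
        out.append(StatResult(
            name=label, statistic=float(row["F"]),
            df=float(row["DF1"]), p=float(row["p_unc"]),
            effect_size=float(row["np2"]), effect_size_type="partial eta2",
            note=f"df = ({int(row['DF1'])}, {int(row['DF2'])})"))
    return out


def _boot_ci_mean_diff(a, b, paired, rng, n_boot):
    boots = np.empty(n_boot)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    for i in range(n_boot):
        if paired:
            idx = rng.integers(0, a.size, a.size)
            boots[i] = np.mean(a[idx] - b[idx])
        else:  # stratified: resample within each sample
            ia = rng.integers(0, a.size, a.size)
            ib = rng.integers(0, b.size, b.size)
            boots[i] = a[ia].mean() - b[ib].mean()
    return tuple(np.percentile(boots, [2.5, 97.5]))


def t_compare(a, b, paired: bool = False, name: str = "t-test",
              n_boot: int = N_BOOT, seed: int = 0) -> StatResult:
    """Two-sample comparison with a Levene gate.

    For independent samples, Levene's test (mean-centred) at alpha = 0.05
    decides between the Student and the Welch t-test (the latter with its
    fractional df).  Cohen's d uses the pooled SD (independent) or the SD
    of the differences (paired).  The CI is a percentile bootstrap of the
    mean difference (``n_boot = 0`` skips it).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both samples")
    note = ""
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        res = sps.ttest_rel(a, b)
        df = a.size - 1
        d = np.mean(a - b) / np.std(a - b, ddof=1)
    else:
        lev = sps.levene(a, b, center="mean")
        equal_var = lev.pvalue >= ALPHA
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        df = float(res.df)
        sp = np.sqrt(((a.size - 1) * np.var(a, ddof=1)
                      + (b.size - 1) * np.var(b, ddof=1))
                     / (a.size + b.size - 2))
        d = (a.mean() - b.mean()) / sp
        note = ("Welch (Levene p = %.3f)" % lev.pvalue) if not equal_var \
            else ("Student (Levene p = %.3f)" % lev.pvalue)
    ci = (np.nan, np.nan)
    if n_boot:
        ci = _boot_ci_mean_diff(a, b, paired, np.random.default_rng(seed),
                                n_boot)
    return StatResult(name=name, statistic=float(res.statistic), df=df,
                      p=float(res.pvalue), effect_size=float(d),
                      effect_size_type="cohen d", ci_low=ci[0], ci_high=ci[1],
                      note=note)


def one_sample_t(values, null_value: float = 0.0, name: str = "one-sample t",
                 n_boot: int = N_BOOT, seed: int = 0) -> StatResult:
    """One-sample t-test against ``null_value``; d = mean difference / SD."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.var(x) == 0:
        raise ValueError("zero variance")
    res = sps.ttest_1samp(x, null_value)
    d = (x.mean() - null_value) / np.std(x, ddof=1)
    ci = (np.nan, np.nan)
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = np.array([x[rng.integers(0, x.size, x.size)].mean()
                          for _ in range(n_boot)])
        ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return StatResult(name=name, statistic=float(res.statistic),
                      df=x.size - 1, p=float(res.pvalue),
                      effect_size=float(d), effect_size_type="cohen d",
                      ci_low=ci[0], ci_high=ci[1])


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _partial_r(x, y, z):
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))


def correlation(x, y, control=None, name: str = "correlation",
                n_boot: int = N_BOOT, seed: int = 0) -> StatResult:
    """Pearson correlation, optionally partialling out one covariate.

    With ``control`` (e.g. a binary age-group code) the first-order partial
    correlation is computed; its p-value uses the t approximation with
    n - 3 df.  The CI is a percentile bootstrap over paired resamples.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant input")
    n = x.size
    if control is None:
        r, p = sps.pearsonr(x, y)
        df = n - 2
    else:
        z = np.asarray(control, float)
        r = _partial_r(x, y, z)
        df = n - 3
        t = r * np.sqrt(df / (1 - r**2))
        p = 2 * sps.t.sf(abs(t), df)
    ci = (np.nan, np.nan)
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        z = None if control is None else np.asarray(control, float)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            if z is None:
                boots[i] = np.corrcoef(xb, yb)[0, 1]
            else:
                zb = z[idx]
                if np.var(zb) == 0 or np.var(xb) == 0 or np.var(yb) == 0:
                    boots[i] = np.nan
                else:
                    boots[i] = _partial_r(xb, yb, zb)
        ci = tuple(np.nanpercentile(boots, [2.5, 97.5]))
    return StatResult(name=name, statistic=float(r), df=df, p=float(p),
                      effect_size=float(r), effect_size_type="pearson r",
                      ci_low=ci[0], ci_high=ci[1],
                      note="partial" if control is not None else "")
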