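"""Generative signal-detection confidence observer and cohort simulator.

The observer follows the standard SDT account of the confidence
forced-choice task.  On each perceptual decision with signed contrast
difference ``delta`` it draws internal evidence

    e ~ Normal((delta - bias) / sigma_s, 1)

and reports "test higher" iff e > 0 (with probability ``lapse`` the report
is replaced by a fair coin).  Confidence evidence is the distance of the
evidence from the criterion, degraded by confidence noise:

    c = |e| + Normal(0, sigma_c)

and the decision with the larger c is selected in the confidence choice.
``sigma_c = 0`` is the idealized observer whose confidence is exactly as
good as its sensory noise allows; large ``sigma_c`` decouples confidence
from the evidence.  Response times follow the exponential RT model
``RT = alpha - beta * exp(-S^2/2) - gamma * C`` (S the normalized stimulus
intensity, C the realized 0/1 confidence code) plus Gaussian noise,
truncated at the 100 ms anticipation bound.

Besides sampling full sessions, the module computes the observer's
expected confidence-choice probability maps and expected CMI by Gaussian
quadrature (no sampling), and generates whole two-group cohorts whose
executive-function scores correlate with latent confidence efficiency via
a Gaussian-copula construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr
from scipy.stats import truncnorm

from .confidence import CONDITIONS, ConfidenceMap, cmi
from .design import DesignSpec, generate_design
from .psychometric import fit_cumulative_gaussian

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one observer.

    ``sigma_s``: sensory noise (SD of the discrimination channel, % contrast);
    ``bias``: PSE offset (% contrast); ``sigma_c``: confidence noise in
    evidence units (0 = ideal); ``lapse``: probability of a random perceptual
    report; ``rt_*``: exponential RT model parameters (ms).  ``rt_beta`` is
    negative when responses slow down near the PSE (the empirical pattern),
    ``rt_gamma`` positive when confident decisions are faster.
    """

    sigma_s: float = 6.0
    bias: float = 0.0
    sigma_c: float = 0.0
    lapse: float = 0.0
    rt_alpha: float = 524.0
    rt_beta: float = -80.0
    rt_gamma: float = 72.0
    rt_noise_sd: float = 150.0

    def validate(self) -> None:
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be non-negative")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        lo = self.rt_alpha - max(-self.rt_beta, 0.0) - max(self.rt_gamma, 0.0)
        if lo <= 0:
            raise ValueError("RT parameters allow non-positive RTs")


def idealized_observer(sigma_s: float, **kwargs) -> ObserverParams:
    """Observer whose confidence is exactly as reliable as the sensory noise
    permits (no confidence noise, no lapses)."""
    return ObserverParams(sigma_s=sigma_s, sigma_c=0.0, lapse=0.0, **kwargs)


# ---------------------------------------------------------------------------
# session sampling
# ---------------------------------------------------------------------------

def simulate_decisions(params: ObserverParams, d1, d2, rng):
    """Vectorised core: evidence, reports and confidence choices for paired
    contrast differences ``d1``, ``d2`` (arrays of equal length)."""
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    n = d1.size
    mu1 = (d1 - params.bias) / params.sigma_s
    mu2 = (d2 - params.bias) / params.sigma_s
    e1 = rng.standard_normal(n) + mu1
    e2 = rng.standard_normal(n) + mu2
    rep1 = e1 > 0
    rep2 = e2 > 0
    if params.lapse > 0:
        lap1 = rng.random(n) < params.lapse
        lap2 = rng.random(n) < params.lapse
        rep1 = np.where(lap1, rng.random(n) < 0.5, rep1)
        rep2 = np.where(lap2, rng.random(n) < 0.5, rep2)
    c1 = np.abs(e1) + params.sigma_c * rng.standard_normal(n)
    c2 = np.abs(e2) + params.sigma_c * rng.standard_normal(n)
    choose1 = np.where(c1 == c2, rng.random(n) < 0.5, c1 > c2)
    return rep1, rep2, choose1, mu1, mu2


def simulate_session(params: ObserverParams, spec: DesignSpec = DesignSpec(),
                     seed: int = 0, participant_id: str = "sim",
                     ) -> pd.DataFrame:
    """Simulate one full session as a trial table ready for the pipeline."""
    params.validate()
    rng = np.random.default_rng(seed)
    trials = generate_design(spec, seed=int(rng.integers(2**31)),
                             participant_id=participant_id)
    d1 = trials["task1_delta"].to_numpy()
    d2 = trials["task2_delta"].to_numpy()
    rep1, rep2, choose1, mu1, mu2 = simulate_decisions(params, d1, d2, rng)
    conf_choice = np.where(choose1, 1, 2)

    def rts(mu, confident):
        pred = (params.rt_alpha - params.rt_beta * np.exp(-0.5 * mu**2)
                - params.rt_gamma * confident)
        rt = pred + params.rt_noise_sd * rng.standard_normal(mu.size)
        return np.maximum(rt, 100.0)

    trials["decision1"] = np.where(rep1, "higher", "lower")
    trials["decision2"] = np.where(rep2, "higher", "lower")
    trials["rt1_ms"] = rts(mu1, (conf_choice == 1).astype(float))
    trials["rt2_ms"] = rts(mu2, (conf_choice == 2).astype(float))
    trials["conf_choice"] = conf_choice
    return trials


# ---------------------------------------------------------------------------
# expected (quadrature) quantities -- no sampling
# ---------------------------------------------------------------------------

def _axis(mu: float, n: int = 48, span: float = 8.5):
    """Gauss-Legendre nodes/weights for integrating f(e) phi(e - mu) de,
    with the axis split at e = 0 where |e| has a kink."""
    lo, hi = mu - span, mu + span
    cut = 0.0 if lo < 0.0 < hi else 0.5 * (lo + hi)
    x0, w0 = leggauss(n)
    nodes, weights = [], []
    for a, b in ((lo, cut), (cut, hi)):
        nodes.append(0.5 * (b - a) * x0 + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * w0)
    x = np.concatenate(nodes)
    w = np.concatenate(weights)
    return x, w * np.exp(-0.5 * (x - mu) ** 2) / np.sqrt(2 * np.pi)


def _report_weight(e, side, lapse):
    """P(report = side | evidence e): lapses are fair coins."""
    if side is None:
        return np.ones_like(e)
    ind = (e > 0) if side == "higher" else (e < 0)
    return lapse / 2.0 + (1.0 - lapse) * ind


def _p_report(mu, side, lapse):
    if side is None:
        return 1.0
    p_higher = (1.0 - lapse) * ndtr(mu) + lapse / 2.0
    return p_higher if side == "higher" else 1.0 - p_higher


def _p_choose1(mu1, mu2, side1, side2, sigma_c, lapse):
    """P(decision 1 chosen as more confident | reports side1, side2)."""
    denom = _p_report(mu1, side1, lapse) * _p_report(mu2, side2, lapse)
    if denom <= 1e-300:
        return np.nan
    if sigma_c == 0.0:
        # inner integral over e1 is analytic: P(|e1| > v, report side1)
        u, wu = _axis(mu2)
        v = np.abs(u)
        ip = ndtr(mu1 - v)      # mass of e1 above +v
        im = ndtr(-v - mu1)     # mass of e1 below -v
        if side1 is None:
            inner = ip + im
        elif side1 == "higher":
            inner = (1 - lapse / 2) * ip + (lapse / 2) * im
        else:
            inner = (lapse / 2) * ip + (1 - lapse / 2) * im
        joint = float(np.sum(wu * _report_weight(u, side2, lapse) * inner))
    else:
        e1, w1 = _axis(mu1)
        e2, w2 = _axis(mu2)
        kern = ndtr((np.abs(e1)[:, None] - np.abs(e2)[None, :])
                    / (_SQRT2 * sigma_c))
        a = w1 * _report_weight(e1, side1, lapse)
        b = w2 * _report_weight(e2, side2, lapse)
        joint = float(a @ kern @ b)
    return joint / denom


def expected_choice_map(params: ObserverParams,
                        spec: DesignSpec = DesignSpec(),
                        condition: str = "aggregate") -> ConfidenceMap:
    """Exact confidence-choice probability map of the observer.

    Computed by Gaussian quadrature over the bivariate evidence distribution
    (split at the evidence criterion where |e| is non-smooth); no sampling.
    """
    params.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {CONDITIONS}")
    side1 = side2 = None
    if condition != "aggregate":
        side1, side2 = condition.split("_")
    deltas = spec.deltas
    grid = np.empty((deltas.size, deltas.size))
    for i, a in enumerate(deltas):
        for j, b in enumerate(deltas):
            grid[i, j] = _p_choose1((a - params.bias) / params.sigma_s,
                                    (b - params.bias) / params.sigma_s,
                                    side1, side2, params.sigma_c, params.lapse)
    gdf = pd.DataFrame(grid, index=deltas, columns=deltas)
    counts = pd.DataFrame(np.nan, index=deltas, columns=deltas)
    return ConfidenceMap(grid=gdf, counts=counts, condition=condition)


def _expected_set_counts(params: ObserverParams, spec: DesignSpec):
    """Expected per-level (delta, n, k) counts of the unsorted and chosen
    decision sets, by quadrature over the evidence distribution."""
    deltas = spec.deltas
    mus = (deltas - params.bias) / params.sigma_s
    lapse = params.lapse
    n_dec = 2.0 * spec.reps_per_level  # decisions per level, both positions

    p_u = lapse / 2.0 + (1.0 - lapse) * ndtr(mus)
    counts_u = np.column_stack([deltas, np.full_like(mus, n_dec),
                                n_dec * p_u])

    # q(e) = P(this decision is chosen | evidence e), competitor level
    # uniform over the design levels
    rows = []
    for mu in mus:
        e, w = _axis(mu)
        if params.sigma_c == 0.0:
            v = np.abs(e)[:, None]
            q = np.mean(ndtr(v - mus[None, :]) - ndtr(-v - mus[None, :]),
                        axis=1)
        else:
            q = np.zeros_like(e)
            for mu_c in mus:
                ec, wc = _axis(mu_c)
                q += (ndtr((np.abs(e)[:, None] - np.abs(ec)[None, :])
                           / (_SQRT2 * params.sigma_c)) @ wc)
            q /= mus.size
        w_plus = _report_weight(e, "higher", lapse)
        p_chosen = float(np.sum(w * q))
        p_higher_chosen = float(np.sum(w * w_plus * q))
        rows.append((p_chosen, p_higher_chosen))
    p_chosen, p_hc = np.array(rows).T
    counts_c = np.column_stack([deltas, n_dec * p_chosen, n_dec * p_hc])
    return counts_c, counts_u


def expected_cmi(params: ObserverParams, spec: DesignSpec = DesignSpec(),
                 ) -> float:
    """Expected CMI of an observer: the large-sample limit of the pipeline
    estimate (expected set proportions fitted with the pipeline's own
    psychometric estimator)."""
    params.validate()
    counts_c, counts_u = _expected_set_counts(params, spec)
    fit_c = fit_cumulative_gaussian(counts_c)
    fit_u = fit_cumulative_gaussian(counts_u)
    return cmi(fit_c.sensitivity, fit_u.sensitivity)


# cached expected-CMI tables keyed by design and observer constants
_CMI_TABLES: dict = {}
_SIGMA_S_GRID = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 12.0])
_SIGMA_C_GRID = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.25, 1.5,
                          2.0, 2.5, 3.0, 4.0, 6.0, 10.0])


def _cmi_table(spec: DesignSpec, lapse: float, bias: float) -> np.ndarray:
    key = (spec.levels, spec.standard, spec.reps_per_level, lapse, bias)
    if key not in _CMI_TABLES:
        tab = np.empty((_SIGMA_S_GRID.size, _SIGMA_C_GRID.size))
        for i, ss in enumerate(_SIGMA_S_GRID):
            for j, sc in enumerate(_SIGMA_C_GRID):
                tab[i, j] = expected_cmi(
                    ObserverParams(sigma_s=ss, sigma_c=sc, lapse=lapse,
                                   bias=bias), spec)
        _CMI_TABLES[key] = tab
    return _CMI_TABLES[key]


def sigma_c_for_cmi(target_cmi, sigma_s, spec: DesignSpec = DesignSpec(),
                    lapse: float = 0.0, bias: float = 0.0) -> np.ndarray:
    """Invert the expected-CMI curve: confidence noise giving a target
    expected CMI at a given sensory noise (targets outside the achievable
    range are clipped to its borders)."""
    tab = _cmi_table(spec, lapse, bias)
    target_cmi = np.atleast_1d(np.asarray(target_cmi, float))
    sigma_s = np.atleast_1d(np.asarray(sigma_s, float))
    out = np.empty(target_cmi.size)
    for idx, (m, ss) in enumerate(zip(target_cmi, np.broadcast_to(
            sigma_s, target_cmi.shape))):
        ss = np.clip(ss, _SIGMA_S_GRID[0], _SIGMA_S_GRID[-1])
        # interpolate the table rows to this sigma_s
        curve = np.array([np.interp(ss, _SIGMA_S_GRID, tab[:, j])
                          for j in range(_SIGMA_C_GRID.size)])
        # curve is decreasing in sigma_c; negate to get an increasing xp
        m = np.clip(m, curve.min(), curve.max())
        out[idx] = np.interp(-m, -curve, _SIGMA_C_GRID)
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Cognitive battery marginals per group: (mean, sd, orientation, floor);
#: orientation +1 = higher raw score is better, -1 = timed score (lower is
#: better, negated before z-scoring downstream).
COGNITIVE_MARGINALS = {
    "older": {
        "dsst": (60.2, 11.3, +1, 0.0),
        "tmt_b_s": (77.4, 23.0, -1, 5.0),
        "vst_c_s": (69.1, 42.2, -1, 5.0),
        "lps3": (16.9, 3.4, +1, 0.0),
        "digit_span": (4.4, 0.9, +1, 1.0),
    },
    "younger": {
        "dsst": (82.3, 11.8, +1, 0.0),
        "tmt_b_s": (43.5, 13.2, -1, 5.0),
        "vst_c_s": (25.5, 5.4, -1, 5.0),
        "lps3": (22.1, 3.5, +1, 0.0),
        "digit_span": (5.0, 1.0, +1, 1.0),
    },
}

EF_MEASURES = ("dsst", "tmt_b_s", "vst_c_s", "lps3")


@dataclass(frozen=True)
class GroupParams:
    """Population distributions of one age group's observers."""

    sigma_s_mean: float
    sigma_s_sd: float
    sigma_s_range: tuple[float, float] = (2.0, 12.0)
    cmi_mean: float = 25.0
    cmi_sd: float = 12.0
    rt_alpha_mean: float = 500.0
    rt_alpha_sd: float = 150.0
    rt_alpha_min: float = 300.0
    rt_beta_mean: float = -80.0
    rt_beta_sd: float = 25.0
    rt_gamma_mean: float = 72.0
    rt_gamma_sd: float = 20.0
    rt_noise_sd: float = 150.0
    lapse: float = 0.02
    age_mean: float = 50.0
    age_sd: float = 5.0
    age_range: tuple[float, float] = (18.0, 80.0)


#: Study-like defaults: older adults have higher sensory noise, lower
#: confidence efficiency, slower generic RTs, and the cognitive marginals
#: of the older column of the battery table.
DEFAULT_GROUPS = {
    "older": GroupParams(sigma_s_mean=6.0, sigma_s_sd=1.5,
                         cmi_mean=23.04, cmi_sd=15.1,
                         rt_alpha_mean=524.0, rt_alpha_sd=165.0,
                         age_mean=68.8, age_sd=4.7, age_range=(60.0, 78.0)),
    "younger": GroupParams(sigma_s_mean=4.2, sigma_s_sd=1.0,
                           cmi_mean=31.21, cmi_sd=9.0,
                           rt_alpha_mean=438.0, rt_alpha_sd=135.0,
                           age_mean=24.6, age_sd=4.4, age_range=(19.0, 38.0)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated two-group cohort.

    ``ef_link`` is the target Pearson correlation, over the pooled sample,
    between the EF composite and the measured confidence efficiency (CMI);
    the construction inflates the latent link to offset the single-session
    estimation noise ``cmi_noise_sd`` (SD of a session's CMI estimate at
    the design's trial count).
    """

    n_per_group: int = 30
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    ef_link: float = 0.4
    ef_loading: float = 0.8
    cmi_noise_sd: float = 14.0
    design: DesignSpec = DesignSpec()
    seed: int = 0

    def validate(self) -> None:
        if not -1 < self.ef_link < 1:
            raise ValueError("ef_link must lie in (-1, 1)")
        if not 0 < self.ef_loading <= 1:
            raise ValueError("ef_loading must lie in (0, 1]")
        if set(self.groups) != {"older", "younger"}:
            raise ValueError("groups must be exactly older/younger")
        _solve_within_corr(self)  # raises if infeasible


def _ef_moments(spec: CohortSpec):
    """Pooled-sample moments of the oriented cognitive measures and of the
    latent CMI trait, for balanced groups."""
    g_o, g_y = spec.groups["older"], spec.groups["younger"]
    s_mo, s_my = g_o.cmi_sd, g_y.cmi_sd
    dmu_m = g_o.cmi_mean - g_y.cmi_mean
    var_m = 0.5 * (s_mo**2 + s_my**2) + 0.25 * dmu_m**2
    rows = {}
    for meas in EF_MEASURES:
        a_o, b_o, o, _ = COGNITIVE_MARGINALS["older"][meas]
        a_y, b_y, _, _ = COGNITIVE_MARGINALS["younger"][meas]
        gap = o * (a_o - a_y)            # oriented group gap
        var = 0.5 * (b_o**2 + b_y**2) + 0.25 * gap**2
        rows[meas] = (b_o, b_y, gap, var)
    return rows, (s_mo, s_my, dmu_m, var_m)


def _solve_within_corr(spec: CohortSpec) -> float:
    """Within-group correlation between the EF common factor and the latent
    CMI trait needed to hit ``ef_link`` on the measured-CMI scale."""
    lam = spec.ef_loading
    rows, (s_mo, s_my, dmu_m, var_m) = _ef_moments(spec)
    meas = list(rows)
    # Var of the EF composite (mean of pooled z-scores)
    total = 0.0
    for i, mi in enumerate(meas):
        for j, mj in enumerate(meas):
            if i == j:
                total += 1.0
                continue
            b_oi, b_yi, gi, vi = rows[mi]
            b_oj, b_yj, gj, vj = rows[mj]
            cov = (lam**2 * 0.5 * (b_oi * b_oj + b_yi * b_yj)
                   + 0.25 * gi * gj)
            total += cov / np.sqrt(vi * vj)
    var_ef = total / 16.0
    # Cov(EF, M) = rho * A + B
    a_term = b_term = 0.0
    for mi in meas:
        b_o, b_y, gap, var = rows[mi]
        a_term += lam * 0.5 * (b_o * s_mo + b_y * s_my) / np.sqrt(var)
        b_term += 0.25 * gap * dmu_m / np.sqrt(var)
    a_term /= 4.0
    b_term /= 4.0
    var_m_meas = var_m + spec.cmi_noise_sd**2
    need = spec.ef_link * np.sqrt(var_ef * var_m_meas)
    rho = (need - b_term) / a_term
    if not -0.999 < rho < 0.999:
        raise ValueError(
            f"infeasible correlation structure: ef_link={spec.ef_link} "
            f"requires a within-group factor correlation of {rho:.3f}")
    return float(rho)


@dataclass
class Cohort:
    """A simulated cohort: participant covariates, per-participant sessions,
    and the generative ground truth."""

    participants: pd.DataFrame
    sessions: dict
    truth: pd.DataFrame


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Generate a full two-group cohort, reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rho = _solve_within_corr(spec)
    lam = spec.ef_loading
    parts, truths, sessions = [], [], {}
    for group in ("older", "younger"):
        gp = spec.groups[group]
        n = spec.n_per_group
        prefix = group[0]
        sigma_s = _truncnorm(rng, gp.sigma_s_mean, gp.sigma_s_sd,
                             *gp.sigma_s_range, size=n)
        m_w = rng.standard_normal(n)
        target_cmi = gp.cmi_mean + gp.cmi_sd * m_w
        sigma_c = np.asarray(sigma_c_for_cmi(
            target_cmi, sigma_s, spec.design, lapse=gp.lapse))
        f_common = rho * m_w + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        alpha = _truncnorm(rng, gp.rt_alpha_mean, gp.rt_alpha_sd,
                           gp.rt_alpha_min, np.inf, size=n)
        beta = np.minimum(rng.normal(gp.rt_beta_mean, gp.rt_beta_sd, n), -5.0)
        gamma = np.maximum(rng.normal(gp.rt_gamma_mean, gp.rt_gamma_sd, n), 5.0)
        age = _truncnorm(rng, gp.age_mean, gp.age_sd, *gp.age_range, size=n)
        scores = {}
        for meas in ("dsst", "tmt_b_s", "vst_c_s", "lps3", "digit_span"):
            a, b, orient, floor = COGNITIVE_MARGINALS[group][meas]
            if meas in EF_MEASURES:
                z = lam * f_common + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            else:  # digit span independent of confidence efficiency
                z = rng.standard_normal(n)
            scores[meas] = np.maximum(a + orient * b * z, floor)
        for i in range(n):
            pid = f"{prefix}{i + 1:02d}"
            params = ObserverParams(
                sigma_s=float(sigma_s[i]), sigma_c=float(sigma_c[i]),
                lapse=gp.lapse, rt_alpha=float(alpha[i]),
                rt_beta=float(beta[i]), rt_gamma=float(gamma[i]),
                rt_noise_sd=gp.rt_noise_sd)
            sessions[pid] = simulate_session(
                params, spec.design, seed=int(rng.integers(2**31)),
                participant_id=pid)
            parts.append({
                "participant_id": pid, "age_group": group,
                "age": float(age[i]),
                **{m: float(scores[m][i]) for m in scores}})
            truths.append({
                "participant_id": pid, "age_group": group,
                "sigma_s": params.sigma_s, "sigma_c": params.sigma_c,
                "target_cmi": float(target_cmi[i]),
                "rt_alpha": params.rt_alpha, "rt_beta": params.rt_beta,
                "rt_gamma": params.rt_gamma})
    return Cohort(participants=pd.DataFrame(parts), sessions=sessions,
                  truth=pd.DataFrame(truths))
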