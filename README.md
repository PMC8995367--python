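# metaconf

Analysis pipeline for **confidence forced-choice** experiments on visual
metacognition, with a generative signal-detection observer for simulation
studies.

In the confidence forced-choice paradigm an observer makes two consecutive
perceptual decisions per trial — here, contrast discriminations between a
test Gabor patch (7 levels, 13–31% contrast) and a 22% standard — and then
indicates which of the two decisions they feel more confident about.  This
yields a bias-free, relative measure of confidence.  The package is aimed
at psychophysicists who want to quantify *confidence efficiency* (how well
confidence tracks decision quality) from such data, or to run calibrated
simulation studies of the design, including age-group comparisons and links
to executive-function (EF) covariates.

## The measures

Decisions are split into two *confidence sets*: **chosen** (the decision
selected as more confident on each trial) and **unsorted** (all decisions).
Each set is fitted with a cumulative Gaussian psychometric function

    p(Δ) = λ/2 + (1 − λ) Φ((Δ − μ) / σ)

by penalized maximum likelihood (PSE μ, slope σ, lapse rate λ; goodness of
fit via the deviance D).  Contrast sensitivity is 1/σ, and confidence
efficiency is the **Confidence Modulation Index**

    CMI = 100 × (Sensitivity_chosen − Sensitivity_unsorted) / Sensitivity_unsorted

A CMI near zero means confidence choices are uninformed; the tighter the
link between confidence and evidence quality, the larger the CMI.  Response
times are modelled per stimulus intensity S (signed distance from the PSE in
psychometric SD units) and mean confidence code C as

    RT(S) = α − β e^{−S²/2} − γ C

separating generic speed (α), difficulty effects (β) and confidence effects
(γ).  The statistics layer provides the EF composite (mean of oriented
z-scores of DSST, TMT-B, VST-C, LPS-3), 2×2 mixed ANOVAs, Levene-gated
t-tests with Cohen's d, percentile-bootstrap CIs and (partial) correlations.

The generative observer draws internal evidence e ~ N((Δ − bias)/σ_s, 1),
reports its sign, and bases confidence on |e| + N(0, σ_c); σ_c = 0 is the
idealized observer whose confidence is exactly as good as its sensory noise
allows.  Expected confidence-choice probability maps and expected CMIs are
computed by Gaussian quadrature, without sampling.

## Worked example

```python
import metaconf as mc

# one session of an observer with moderate sensory and confidence noise
params = mc.ObserverParams(sigma_s=5.0, sigma_c=0.8, lapse=0.02)
trials = mc.simulate_session(params, seed=2)          # 420-trial session

chosen, unsorted_set = mc.split_sets(trials)
fit_c = mc.fit_cumulative_gaussian(
    mc.aggregate_proportions(chosen["delta"], chosen["decision"]))
fit_u = mc.fit_cumulative_gaussian(
    mc.aggregate_proportions(unsorted_set["delta"], unsorted_set["decision"]))
print(round(fit_u.sigma, 2), round(fit_c.sigma, 2))
# 4.97 3.95   <- slope SDs: the chosen set is steeper (more sensitive)
print(round(mc.cmi(fit_c.sensitivity, fit_u.sensitivity), 1))
# 25.8        <- percent sensitivity gain from informative confidence
print(round(mc.expected_cmi(params), 1))
# 25.7        <- quadrature expectation for these generative parameters
```

The fitted unsorted slope (4.97) recovers the generative sensory noise
(5.0); the chosen set is reliably steeper, and the session-level CMI
estimate (25.8%) sits on top of its theoretical expectation (25.7%).

The same analysis runs end to end on a whole cohort (simulated here; a data
directory of session/participant CSVs works identically):

```sh
metaconf run --simulate --seed 5 --out report/
metaconf simulate --seed 5 --out data/          # emit raw session files
metaconf validate data/session_o01.csv
```

The report bundle contains per-participant psychometric fits, CMIs with
outlier flags, RT-model parameters, EF scores, confidence-choice maps and
the group statistics table, plus a provenance block sufficient to
regenerate every number.

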