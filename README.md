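# grmkit

Psychometric evaluation of polytomous item banks with Samejima's graded
response model (GRM): classical reliability, model-assumption checks,
marginal-maximum-likelihood calibration, item/test information, and
differential item functioning (DIF) — the full workflow used to validate
patient-reported outcome (PRO) item banks such as the PROMIS instruments.

The package ships the published Chinese calibration of the 23-item
PROMIS-Cancer-Anxiety bank (five-point Likert items, "Never"=1 … "Always"=5)
as a ready-to-use fixture, and a synthetic-data generator that reproduces the
statistical shape of that calibration study (1075 respondents, latent trait
θ ~ N(0,1), realistic demographic splits), so every stage of the pipeline is
testable without access to patient data.

## The model

For item *j* with discrimination *a<sub>j</sub>* and ordered thresholds
*b<sub>j1</sub> < … < b<sub>j,K−1</sub>*, the probability of responding
**above** category *k* at trait level θ is logistic (scaling constant D = 1):

> P\*<sub>jk</sub>(θ) = 1 / (1 + exp(−a<sub>j</sub>(θ − b<sub>jk</sub>)))

Category probabilities are the differences P<sub>jk</sub> = P\*<sub>j,k−1</sub> −
P\*<sub>jk</sub> (with P\*<sub>j0</sub> = 1, P\*<sub>jK</sub> = 0).  Item
information is Fisher information I<sub>j</sub>(θ) = Σ<sub>k</sub>
(P′<sub>jk</sub>)² / P<sub>jk</sub>; test information T(θ) = Σ<sub>j</sub>
I<sub>j</sub>(θ) gives the conditional standard error 1/√T(θ).  Calibration
integrates θ out over a fixed N(0,1) quadrature prior and maximizes the
marginal likelihood by EM.  DIF is tested per item by nested
proportional-odds regressions (matching variable, + group, + group ×
matching), with likelihood-ratio tests for detection and McFadden pseudo-R²
changes (gate 0.02) for practical salience.

## Worked example

```python
>>> import grmkit
>>> bank = grmkit.load_default_bank()          # 23 items, K = 5 categories
>>> bank["EDANX05"].a, bank["EDANX05"].b
(5.47, (-2.29, -1.17, 0.05, 1.46))

>>> grmkit.item_information(bank["EDANX05"], 0.0)   # information at theta = 0
7.359928607873681
>>> grmkit.max_information(bank["EDANX05"])         # (peak value, theta at peak)
(7.489176017731135, -2.3)
>>> grmkit.test_information(bank, 0.0)              # TIC maximum, at theta = 0
63.47645483380953
>>> grmkit.information_summary(bank)["n_high_information"]
10
>>> grmkit.screen_items(bank).flagged_intervals     # threshold-spacing screen
[('EDANX09', 'b2_b1', 0.74)]
```

The strongest item (EDANX05, *a* = 5.47) contributes information 7.36 at
average anxiety; the bank peaks at 63.5 total information (conditional SE
1/√63.5 ≈ 0.13); 10 of 23 items exceed maximum information 3.0; and the only
screening flag is EDANX09's first threshold interval (0.74 < 0.81), meaning
its "rarely" and "sometimes" categories sit unusually close.

Calibrating a study-shaped simulation recovers the generating bank:

```python
>>> responses, theta = grmkit.simulate_study(seed=1)   # 1075 x 23 + covariates
>>> grmkit.cronbach_alpha(responses)
0.979
>>> model = grmkit.GradedResponseModel().fit(responses)   # MML-EM, ~15 s
>>> model.converged_, model.n_cycles_
(True, 163)
>>> est = model.bank_["EDANX05"]
>>> round(est.a, 2), [round(b, 2) for b in est.b]
(5.49, [-2.32, -1.12, 0.08, 1.47])
>>> model.transform(responses.values[:3])   # EAP theta and posterior SD
array([[1.767, 0.136],
       [0.223, 0.125],
       [0.958, 0.131]])
```

`GradedResponseModel` and `DIFDetector` follow the scikit-learn estimator
protocol (`fit` / `transform`, `get_params`, trailing-underscore attributes)
and compose with sklearn tooling; module-level functions (`fit_grm`,
`dif_olr`, `kmo_statistic`, …) wrap them for script use.

## Command line

```bash
grmkit simulate --n 1075 --seed 1 --out sim/
grmkit run sim/responses.csv --out report/ \
       --covariate age_group --covariate gender --covariate education \
       --grouping gender --grouping age_group
grmkit information --out tables/        # packaged bank -> information tables
```

`run` executes the whole pipeline (descriptives → reliability → assumptions →
calibration → screening → fit indices → information/OCC/TIC → DIF) and writes
per-stage CSVs plus a machine-readable `summary.json`; criterion failures are
reported, never fatal.

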