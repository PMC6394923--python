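# pdacpath

Markov decision analysis comparing **surgery-first (SF)** and **neoadjuvant
therapy (NAT)** treatment pathways for potentially resectable pancreatic
cancer, built as a tested, reusable pipeline for clinical decision modellers
and methodologists: meta-analytic parameter synthesis from a trial pool, a
two-strategy decision tree evaluated over a monthly Markov cohort model,
deterministic threshold sensitivity analysis, and a seeded probabilistic
Monte Carlo sensitivity analysis — plus a synthetic trial-pool generator so
every stage can be exercised with known ground truth.

## The model

A patient entering either pathway follows a chance tree to one of several
treatment cohorts. SF: resection attempted with probability $p^{SF}_{res}$;
survivors of surgery (fatal grade-5 complications, probability $p_{poc5}$,
accrue zero months) split by margin status (R0 with conditional probability
$p_{R0}$) and by receipt of adjuvant therapy ($p_{adj}$). NAT: chemo/
chemoradiotherapy then restaging; resection with probability $p^{NAT}_{res}$,
exploratory surgery only with $p_{exp}$, and no surgery with the residual
$1 - p^{NAT}_{res} - p_{exp}$. Each terminal cohort then runs a three-state
monthly Markov model (alive disease-free, alive with disease, dead) for up to
60 cycles under a constant exponential hazard $\lambda = \ln 2 / m$, accruing
**life-months (LM)** and utility-weighted **quality-adjusted life-months
(QALMs)**. Grade 3–4 post-operative complications and grade 3+ adjuvant
toxicity degrade the quality weights but not survival.

Transition probabilities are pooled from trial reports with the
Freeman–Tukey double-arcsine transform
$t = \tfrac12\bigl(\arcsin\sqrt{r/(n+1)} + \arcsin\sqrt{(r+1)/(n+1)}\bigr)$,
$\operatorname{var}(t) = 1/(4n+2)$, under a DerSimonian–Laird random-effects
model; median survival is pooled on the hazard scale,
$m_p = \bigl(\sum_i w_i / m_i\bigr)^{-1}$ with $w_i = n_i / \sum_j n_j$.

## Worked example

```python
>>> from pdacpath import PathwayDecisionModel
>>> model = PathwayDecisionModel.from_config()   # bundled baseline inputs
>>> results = model.fit()
>>> print(results.summary())
Two-strategy Markov decision analysis (mode=direct, horizon=60 cycles)

Intention-to-treat expectations
strategy  life_months    qalms
      SF        23.72    18.51
     NAT        20.21    16.17

Incremental (SF - NAT): +3.50 months, +2.35 QALMs
...
>>> model.find_threshold("nat.resect", 0.01, 0.86).threshold
0.5158029174804688
>>> psa = model.run_psa(n_iter=10000, seed=1)
>>> round(psa.stats("sf")["mean"], 2), round(psa.stats("sf")["sd"], 2)
(19.8, 2.72)
```

Reading: on an intention-to-treat basis the surgery-first pathway expects
23.72 months (18.51 QALMs) against 20.21 months (16.17 QALMs) for
neoadjuvant therapy — but NAT becomes the superior strategy whenever its
resection probability exceeds ≈ 0.52 (baseline 0.41), and across the
probabilistic analysis the SF mean drops to ≈ 19.7 months with far wider
spread, so neither pathway dominates.

The same analyses are available from the shell:

```bash
pdacpath evaluate --out-dir out/
pdacpath dsa --param nat.resect --lo 0.05 --hi 0.85 --out-dir out/
pdacpath psa --iterations 10000 --seed 1 --out-dir out/
pdacpath simulate --seed 1 --replicates 200 --out-dir out/
```

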