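# Baseline transition probabilities, uncertainty descriptions, fitted
# distribution specifications, QALM utilities and per-cohort Markov payoffs
# for the two-pathway pancreatic-cancer decision model.
nat:
  tox3:
    point: 0.35
    ci: [0.28, 0.43]
    range: [0.0, 1.0]
    sd: 0.03799
    variance: 0.00144
    distribution:
      family: GeneralizedExtremeValue
      params: {k: 0.45856, sigma: 0.01111, mu: 0.00904}
      ad_stat: 0.55904
  resect:
    point: 0.41
    ci: [0.33, 0.49]
    range: [0.0, 0.86]
    sd: 0.00848
    variance: 7.1972e-5
    distribution:
      family: GeneralizedExtremeValue
      params: {k: 0.15727, sigma: 0.00545, mu: 0.00618}
      ad_stat: 0.36129
  explore:
    point: 0.10
    ci: [0.07, 0.13]
    range: [0.0, 0.36]
    sd: 0.00349
    variance: 1.2182e-5
    distribution:
      family: GeneralizedPareto
      params: {k: 0.06879, sigma: 0.00306, mu: -5.1223e-4}
      ad_stat: 1.3525
  r0:
    point: 0.29
    ci: [0.21, 0.36]
    range: [0.0, 0.74]
    sd: 0.0068
    variance: 4.6303e-5
    distribution:
      family: JohnsonSB
      params: {gamma: 1.7195, delta: 1.0417, lambda: 0.04849, xi: -0.00113}
      ad_stat: 0.35896
  poc34:
    point: 0.35
    ci: [0.19, 0.53]
    range: [0.11, 0.64]
    sd: 0.02702
    variance: 7.3021e-4
    distribution:
      family: GeneralizedExtremeValue
      params: {k: -0.45505, sigma: 0.03128, mu: 0.04101}
      ad_stat: 0.1996
  poc5:
    point: 0.02
    ci: [0.01, 0.03]
    range: [0.0, 0.36]
    sd: 0.00097
    variance: 9.4387e-7
    distribution:
      family: Pareto2
      params: {alpha: 0.34207, beta: 1.3899e-13}
      ad_stat: -13.983
sf:
  resect:
    point: 0.94
    ci: [0.90, 0.96]
    range: [0.70, 1.0]
    sd: 0.1219
    variance: 0.01486
    distribution:
      family: Burr
      params: {k: 0.0595, alpha: 10.327, beta: 0.00112}
      ad_stat: 0.12818
  r0:
    point: 0.56
    ci: [0.51, 0.62]
    range: [0.16, 0.86]
    sd: 0.09869
    variance: 0.00974
    distribution:
      family: Pearson5
      params: {alpha: 0.61636, beta: 7.0460e-4}
      ad_stat: 0.18259
  poc34:
    point: 0.22
    ci: [0.13, 0.33]
    range: [0.04, 0.54]
    sd: 0.01297
    variance: 0.0002
    distribution:
      family: LogPearson3
      params: {alpha: 66.845, beta: -0.09425, gamma: 2.0838}
      ad_stat: 0.29235
  poc5:
    point: 0.07
    ci: [0.02, 0.13]
    range: [0.0, 0.36]
    sd: 0.00948
    variance: 8.9795e-5
    distribution:
      family: Cauchy
      params: {sigma: 0.00373, mu: 0.00639}
      ad_stat: 0.38658
  adjuvant:
    point: 0.61
    ci: [0.57, 0.66]
    range: [0.26, 0.94]
    sd: 0.10088
    variance: 0.01018
    distribution:
      family: Burr
      params: {k: 0.26048, alpha: 2.145, beta: 9.2071e-4}
      ad_stat: 0.18949
  adj_tox3:
    point: 0.43
    ci: [0.25, 0.62]
    range: [0.09, 0.98]
    sd: 0.02753
    variance: 0.00076
    distribution:
      family: LogPearson3
      params: {alpha: 1916.0, beta: -0.02672, gamma: 47.081}
      ad_stat: 0.34508
utilities:
  stable_disease: 0.81
  on_chemoradiotherapy: 0.81
  chemo_toxicity: 0.53
  surgical_recovery: 0.59
  surgical_complication: 0.48
  unresectable: 0.65
cohort_payoffs:
  nat_r0:
    life_months: 35.05
    qalms: 29.87
    variants: {POC: 29.76}
  nat_r1:
    life_months: 34.08
    qalms: 29.87
    variants: {POC: 29.76}
  nat_explore:
    life_months: 10.86
    qalms: 7.22
  nat_no_surgery:
    life_months: 10.86
    qalms: 7.06
  sf_r0_adjuvant:
    life_months: 30.96
    qalms: 24.86
    variants: {POC: 24.75, AT: 21.82, POC+AT: 21.71}
  sf_r0_no_adjuvant:
    life_months: 24.03
    qalms: 20.12
    variants: {POC: 20.01}
  sf_r1_adjuvant:
    life_months: 25.85
    qalms: 20.72
    variants: {POC: 20.61, AT: 18.20, POC+AT: 18.09}
  sf_r1_no_adjuvant:
    life_months: 21.26
    qalms: 17.56
    variants: {POC: 17.45}
  sf_explore:
    life_months: 10.48
    qalms: 6.97
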