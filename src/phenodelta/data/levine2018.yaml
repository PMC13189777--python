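# Mortality-score model for phenotypic age (PhenoAge), Levine et al. 2018.
# The linear predictor xb is the intercept plus the weighted sum of marker
# values in the units listed here (CRP is entered as its natural log).
# The 120-month mortality risk is
#   M = 1 - exp(-exp(xb) * (exp(gamma*horizon) - 1) / gamma)
# and PhenoAge (years) inverts the risk through the affine-log-log map
#   PhenoAge = age_const + ln(-risk_const * ln(1 - M)) / age_rate
version: levine2018-v1
intercept: -19.907
gamma: 0.0076927        # per-month Gompertz rate
horizon: 120            # months
inversion:
  age_const: 141.50225
  risk_const: 0.00553
  age_rate: 0.09165
weights:
  albumin:        {weight: -0.0336, unit: g/L}
  creatinine:     {weight: 0.0095,  unit: umol/L}
  glucose:        {weight: 0.1953,  unit: mmol/L}
  crp:            {weight: 0.0954,  unit: mg/dL, transform: log}
  lymphocyte_pct: {weight: -0.0120, unit: "%"}
  mcv:            {weight: 0.0268,  unit: fL}
  rdw:            {weight: 0.3306,  unit: "%"}
  alp:            {weight: 0.00188, unit: U/L}
  wbc:            {weight: 0.0554,  unit: 10^3 cells/uL}
  chron_age:      {weight: 0.0804,  unit: years}
six_marker:
  # markers available in the Taiwan Biobank; the remaining four terms are
  # dropped while the intercept and all shared weights are kept verbatim
  markers: [mcv, wbc, albumin, creatinine, glucose, chron_age]
sex_mapping:
  # PhenoAge = offset + slope * 6-marker PhenoAge
  male:   {offset: 45.846752, slope: 1.068403}
  female: {offset: 46.527973, slope: 1.023272}
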