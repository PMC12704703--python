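# Canonical model inputs for the internet-based vs in-person low-intensity CBT
# cost-effectiveness model (university students with mild depressive symptoms,
# service-provider perspective, Hong Kong, US $).
#
# Every probability/proportion is stored as a fraction (source tables print
# event rates in percent).  `low`/`high` give the deterministic sensitivity
# range; `dist` names the sampling family used in probabilistic sensitivity
# analysis (beta and gamma are fitted by method of moments with mean = base
# and sd = (high - low)/3.92; triangular uses (low, base, high); fixed is
# degenerate at base).

parameters:
  # --- short-term decision tree: low-intensity CBT for mild symptoms -------
  recovery_low_cbt:
    {base: 0.639, low: 0.511, high: 0.767, dist: beta, scale: probability,
     units: probability per program, label: "Recovery to well with low-intensity CBT"}
  deterioration_low_cbt:
    {base: 0.053, low: 0.042, high: 0.064, dist: beta, scale: probability,
     units: probability per program, label: "Deterioration to moderate-severe with low-intensity CBT"}
  rel_effect_internet:
    {base: 1.00, low: 0.95, high: 1.05, dist: triangular, scale: multiplier,
     units: ratio, label: "Relative effectiveness of internet-based vs in-person CBT"}
  recovery_none:
    {base: 0.250, low: 0.200, high: 0.300, dist: beta, scale: probability,
     units: probability per program, label: "Spontaneous recovery without intervention"}
  deterioration_none:
    {base: 0.091, low: 0.073, high: 0.109, dist: beta, scale: probability,
     units: probability per program, label: "Deterioration without intervention"}
  accept_inperson:
    {base: 0.633, low: 0.601, high: 0.665, dist: beta, scale: probability,
     units: probability, label: "Acceptance of in-person CBT"}
  accept_internet:
    {base: 0.753, low: 0.715, high: 0.791, dist: beta, scale: probability,
     units: probability, label: "Acceptance of internet-based CBT"}
  comply_inperson:
    {base: 0.839, low: 0.757, high: 0.921, dist: beta, scale: probability,
     units: probability, label: "Compliance to in-person CBT"}
  comply_internet:
    {base: 0.808, low: 0.730, high: 0.887, dist: beta, scale: probability,
     units: probability, label: "Compliance to internet-based CBT"}

  # --- monthly Markov transition inputs ------------------------------------
  mortality_monthly:
    {base: 0.000025, low: 0.000020, high: 0.000030, dist: beta, scale: probability,
     units: probability per month, label: "Age-specific all-cause mortality"}
  rr_mortality_depressed:
    {base: 1.81, low: 1.58, high: 2.07, dist: triangular, scale: multiplier,
     units: ratio, label: "Relative risk of mortality with depressive symptoms"}
  remission_monthly:
    {base: 0.0054, low: 0.0043, high: 0.0065, dist: beta, scale: probability,
     units: probability per month, label: "Remission from depressive symptoms"}
  relapse_monthly:
    {base: 0.0244, low: 0.0195, high: 0.0293, dist: beta, scale: probability,
     units: probability per month, label: "Relapse from well/remission"}
  prop_mild_relapse:
    {base: 0.243, low: 0.192, high: 0.288, dist: beta, scale: proportion,
     units: proportion, label: "Proportion of mild symptoms among relapse"}
  prop_moderate_among_modsev:
    {base: 0.50, low: 0.40, high: 0.60, dist: beta, scale: proportion,
     units: proportion, label: "Proportion moderate among moderate-severe cases"}
  hosp_monthly_severe:
    {base: 0.0178, low: 0.0142, high: 0.0214, dist: beta, scale: probability,
     units: probability per month, label: "Psychiatric hospitalization among severe cases"}
  dropout_monthly_well:
    {base: 0.00124, low: 0.00099, high: 0.00149, dist: beta, scale: probability,
     units: probability per month, label: "University dropout while well/remission"}
  dropout_monthly_dep:
    {base: 0.00193, low: 0.00154, high: 0.00232, dist: beta, scale: probability,
     units: probability per month, label: "University dropout with depressive symptoms"}

  # --- utilities ------------------------------------------------------------
  age:
    {base: 21, low: 20, high: 22, dist: triangular, scale: count,
     units: years, label: "Cohort age at entry"}
  utility_age:
    {base: 0.92, low: null, high: null, dist: fixed, scale: utility,
     units: utility, label: "Age-specific population utility"}
  utility_remission:
    {base: 0.80, low: 0.72, high: 0.88, dist: triangular, scale: utility,
     units: utility, label: "Utility in remission"}
  utility_mild:
    {base: 0.62, low: 0.56, high: 0.68, dist: triangular, scale: utility,
     units: utility, label: "Utility with mild symptoms"}
  utility_moderate:
    {base: 0.48, low: 0.43, high: 0.53, dist: triangular, scale: utility,
     units: utility, label: "Utility with moderate symptoms"}
  utility_severe:
    {base: 0.33, low: 0.30, high: 0.36, dist: triangular, scale: utility,
     units: utility, label: "Utility with severe symptoms"}

  # --- costs (US $) ----------------------------------------------------------
  sessions_low:
    {base: 7, low: 6, high: 8, dist: triangular, scale: count,
     units: sessions, label: "Low-intensity CBT sessions"}
  minutes_low:
    {base: 30, low: null, high: null, dist: fixed, scale: count,
     units: minutes, label: "Low-intensity CBT session duration"}
  sessions_high:
    {base: 18, low: 16, high: 20, dist: triangular, scale: count,
     units: sessions, label: "High-intensity CBT sessions"}
  minutes_high:
    {base: 60, low: null, high: null, dist: fixed, scale: count,
     units: minutes, label: "High-intensity CBT session duration"}
  therapist_hourly:
    {base: 54, low: 43, high: 62, dist: triangular, scale: money,
     units: US$ per hour, label: "Psychotherapist service per hour"}
  platform_overhead:
    {base: 24, low: 20, high: 29, dist: triangular, scale: money,
     units: US$ per participant, label: "Internet platform overhead"}
  therapist_time_share_internet:
    {base: 0.0923, low: 0.0738, high: 0.111, dist: beta, scale: proportion,
     units: proportion, label: "Therapist time in guided internet CBT vs in-person"}
  outpatient_monthly:
    {base: 231, low: 160, high: 335, dist: gamma, scale: money,
     units: US$ per patient-month, label: "Psychiatric outpatient cost"}
  hosp_episode_cost:
    {base: 1500, low: 900, high: 2100, dist: gamma, scale: money,
     units: US$ per episode, label: "Psychiatric hospitalization cost"}

# Analysis constants (not varied in sensitivity analyses).
analysis:
  horizon_months: 60
  cycle_months: 1
  discount_annual: 0.03
  wtp: 48119
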