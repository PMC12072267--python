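# Romania 2008-2018 hip-fracture decomposition scenario.
#
# Transcribed from the published national tables. Prevalences are proportions
# in [0, 1] (the source prints percentages; divided by 100 here — the
# conversion is noted in every run log). Baseline rates per 10,000 are given
# as printed (6.5 women, 3.87 men) and override the recomputed count ratios
# (6.509, 3.878), because the published downstream numbers use the printed
# values. `reported` blocks carry the published per-row results (best
# estimate and extremes range, fracture counts; shares in percent) as
# annotations for the "published" aggregation track; they are outputs of the
# original analysis, not model inputs.
baseline_year: 2008
end_year: 2018
strata:
  - sex: women
    pop_by: 11541500
    observed_by: 7513
    pop_ey: 11371000
    observed_ey: 11512
    rate_by: 6.5
  - sex: men
    pop_by: 11000500
    observed_by: 4266
    pop_ey: 11838000
    observed_ey: 5220
    rate_by: 3.87
factors:
  - name: bmi_over_25
    category: risk_factor
    prevalence_by: {women: 0.552, men: 0.619}
    prevalence_ey: {women: 0.611, men: 0.751}
    relative_risk: {women: 0.66, men: 0.76}
    reported:
      nx: {women: 1028, men: 722, total: 1750}
      nx_range:
        women: [872, 1209]
        men: [614, 848]
        total: [1486, 2057]
      share: {women: 21.6, men: 15.2, total: 36.8}
  - name: physical_activity
    category: preventive
    prevalence_by: {women: 0.581, men: 0.543}
    prevalence_ey: {women: 0.770, men: 0.682}
    relative_risk: 0.87
    reported:
      nx: {women: 964, men: 432, total: 1396}
      nx_range:
        women: [821, 1134]
        men: [368, 508]
        total: [1189, 1642]
      share: {women: 20.3, men: 9.1, total: 29.4}
  - name: smoking
    category: risk_factor
    prevalence_by: {women: 0.168, men: 0.268}
    prevalence_ey: {women: 0.217, men: 0.404}
    relative_risk: {women: 1.30, men: 1.47}
    reported:
      nx: {women: 427, men: 960, total: 1387}
      nx_range:
        women: [401, 501]
        men: [815, 1128]
        total: [1216, 1629]
      share: {women: 9.0, men: 20.1, total: 29.1}
  - name: type2_diabetes
    category: risk_factor
    prevalence_by: {women: 0.042, men: 0.065}
    prevalence_ey: {women: 0.061, men: 0.098}
    relative_risk: 1.27
    reported:
      nx: {women: 162, men: 172, total: 334}
      nx_range:
        women: [134, 189]
        men: [144, 201]
        total: [278, 390]
      share: {women: 3.4, men: 3.6, total: 7.0}
  - name: total_hip_replacement
    category: preventive
    prevalence_by: {women: 0.051, men: 0.037}
    prevalence_ey: {women: 0.069, men: 0.053}
    relative_risk: 0.5
    reported:
      nx: {women: -316, men: -175, total: -491}
      nx_range:
        women: [-371, -268]
        men: [-204, -147]
        total: [-575, -415]
      share: {women: -6.6, men: -3.6, total: -10.2}
  - name: benzodiazepines
    category: drug_side_effect
    prevalence_by: {women: 0.131, men: 0.064}
    prevalence_ey: {women: 0.068, men: 0.037}
    relative_risk: 1.52
    reported:
      nx: {women: -437, men: -122, total: -559}
      nx_range:
        women: [-553, -369]
        men: [-142, -102]
        total: [-695, -471]
      share: {women: -9.2, men: -2.6, total: -11.8}
  - name: z_drugs
    category: drug_side_effect
    prevalence_by: {women: 0.215, men: 0.105}
    prevalence_ey: {women: 0.180, men: 0.091}
    relative_risk: 1.19
    reported:
      nx: {women: 295, men: 86, total: 381}
      nx_range:
        women: [249, 347]
        men: [72, 99]
        total: [321, 446]
      share: {women: 6.2, men: 1.8, total: 8.0}
  - name: glucocorticoids
    category: drug_side_effect
    prevalence_by: {women: 0.029, men: 0.021}
    prevalence_ey: {women: 0.047, men: 0.037}
    relative_risk: 1.37
    reported:
      nx: {women: 316, men: 175, total: 491}
      nx_range:
        women: [268, 369]
        men: [148, 173]
        total: [416, 542]
      share: {women: 6.6, men: 3.7, total: 10.3}
  - name: opioids
    category: drug_side_effect
    prevalence_by: {women: 0.164, men: 0.139}
    prevalence_ey: {women: 0.172, men: 0.150}
    relative_risk: 1.54
    reported:
      nx: {women: 177, men: 154, total: 331}
      nx_range:
        women: [149, 208]
        men: [129, 181]
        total: [278, 389]
      share: {women: 3.7, men: 3.2, total: 7.0}
medications:
  - name: bisphosphonate_group
    users_by: {women: 6586, men: 2092}
    users_ey: {women: 2443, men: 777}
    rrr: 0.53
    osteo_rr: {women: 6.4, men: 4.8}
    reported:
      nx: {women: -614, men: -119, total: -733}
      nx_range:
        women: [-722, -521]
        men: [-139, -101]
        total: [-861, -622]
      share: {women: -12.9, men: -2.5, total: -15.4}
options:
  interval_method: exact
  interval_level: 0.95
  adjustment_interpretation: delta_parf
  sign_convention: generated_positive
  rate_decimals: 2
  percent_decimals: 1
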