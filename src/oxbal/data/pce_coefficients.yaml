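# Pooled Cohort Equations coefficients for 10-year first hard ASCVD event risk.
# Transcribed from the 2013 ACC/AHA Guideline on the Assessment of
# Cardiovascular Risk (Goff DC Jr et al., Circulation 2014;129:S49-S73),
# Appendix 7, Table A.  Risk = 1 - S10 ^ exp(LP - mean_lp), where LP is the
# sum of coefficient * term over the group's term list.
#
# Term vocabulary (each term is a deterministic transform of the risk profile):
#   ln_age                    natural log of age in years
#   ln_age_sq                 (ln age)^2
#   ln_tc                     ln total cholesterol (mg/dL)
#   ln_age_x_ln_tc            ln age * ln TC
#   ln_hdl                    ln HDL cholesterol (mg/dL)
#   ln_age_x_ln_hdl           ln age * ln HDL
#   ln_sbp_treated            ln systolic BP (mmHg) if on antihypertensive treatment, else 0
#   ln_age_x_ln_sbp_treated   ln age * ln treated SBP
#   ln_sbp_untreated          ln systolic BP if untreated, else 0
#   ln_age_x_ln_sbp_untreated ln age * ln untreated SBP
#   smoker                    1 if current smoker
#   ln_age_x_smoker           ln age * smoker
#   diabetes                  1 if diabetic
provenance: "Goff et al. 2014, 2013 ACC/AHA risk assessment guideline, Appendix 7 Table A"
groups:
  white_or_other_female:
    terms:
      ln_age: -29.799
      ln_age_sq: 4.884
      ln_tc: 13.540
      ln_age_x_ln_tc: -3.114
      ln_hdl: -13.578
      ln_age_x_ln_hdl: 3.149
      ln_sbp_treated: 2.019
      ln_sbp_untreated: 1.957
      smoker: 7.574
      ln_age_x_smoker: -1.665
      diabetes: 0.661
    mean_lp: -29.18
    s10: 0.9665
  black_female:
    terms:
      ln_age: 17.114
      ln_tc: 0.940
      ln_hdl: -18.920
      ln_age_x_ln_hdl: 4.475
      ln_sbp_treated: 29.291
      ln_age_x_ln_sbp_treated: -6.432
      ln_sbp_untreated: 27.820
      ln_age_x_ln_sbp_untreated: -6.087
      smoker: 0.691
      diabetes: 0.874
    mean_lp: 86.61
    s10: 0.9533
  white_or_other_male:
    terms:
      ln_age: 12.344
      ln_tc: 11.853
      ln_age_x_ln_tc: -2.664
      ln_hdl: -7.990
      ln_age_x_ln_hdl: 1.769
      ln_sbp_treated: 1.797
      ln_sbp_untreated: 1.764
      smoker: 7.837
      ln_age_x_smoker: -1.795
      diabetes: 0.658
    mean_lp: 61.18
    s10: 0.9144
  black_male:
    terms:
      ln_age: 2.469
      ln_tc: 0.302
      ln_hdl: -0.307
      ln_sbp_treated: 1.916
      ln_sbp_untreated: 1.809
      smoker: 0.549
      diabetes: 0.645
    mean_lp: 19.54
    s10: 0.8954
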