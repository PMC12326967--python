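# Final neonatal amikacin population model.
# CL (L/h) = theta_cl * (WT/1000)^exp_wt_cl * (PMA/30)^exp_pma_cl * exp(eta),
#   eta ~ N(0, omega2_cl)
# V (L)    = theta_v * (WT/1000)^exp_wt_v
# Residual-error magnitudes are simulation defaults (combined
# proportional + additive model); between-subject variability on V is
# not retained in the final model.
theta_cl: 0.0487
exp_wt_cl: 0.919
exp_pma_cl: 1.53
theta_v: 0.497
exp_wt_v: 0.851
omega2_cl: 0.0188
omega2_v: 0.0
sigma_prop: 0.15
sigma_add: 0.5
ka_im: null
f_im: 1.0
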