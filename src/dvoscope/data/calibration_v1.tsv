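# dvoscope cohort calibration table, version 1
# Group-level moments and proportions used by the synthetic cohort sampler.
# Feature moments: mean and SD of the four hemodynamic parameters per
# occlusion pressure and group. Units: delta_hbo umol/L, hf umol/L/s,
# vo2 mL O2/100 mL tissue/min, tp s.
# Covariate moments: age yr, bmi kg/m2, durations yr, abi dimensionless.
# Proportions are fractions of the group (count / group size of 118).
# section	group	key	value
features	nonpad	delta_hbo_60_mean	6.81
features	nonpad	delta_hbo_60_sd	4.11
features	nonpad	hf_60_mean	2.48
features	nonpad	hf_60_sd	0.85
features	nonpad	vo2_60_mean	0.066
features	nonpad	vo2_60_sd	0.035
features	nonpad	tp_60_mean	23.44
features	nonpad	tp_60_sd	9.04
features	nonpad	delta_hbo_100_mean	9.44
features	nonpad	delta_hbo_100_sd	5.93
features	nonpad	hf_100_mean	2.90
features	nonpad	hf_100_sd	1.33
features	nonpad	vo2_100_mean	0.079
features	nonpad	vo2_100_sd	0.050
features	nonpad	tp_100_mean	20.86
features	nonpad	tp_100_sd	7.09
features	pad	delta_hbo_60_mean	2.01
features	pad	delta_hbo_60_sd	1.74
features	pad	hf_60_mean	0.86
features	pad	hf_60_sd	0.49
features	pad	vo2_60_mean	0.040
features	pad	vo2_60_sd	0.022
features	pad	tp_60_mean	20.70
features	pad	tp_60_sd	9.54
features	pad	delta_hbo_100_mean	3.90
features	pad	delta_hbo_100_sd	3.55
features	pad	hf_100_mean	1.35
features	pad	hf_100_sd	0.90
features	pad	vo2_100_mean	0.052
features	pad	vo2_100_sd	0.029
features	pad	tp_100_mean	17.12
features	pad	tp_100_sd	4.98
covariates	nonpad	age_mean	54.8
covariates	nonpad	age_sd	13.7
covariates	nonpad	bmi_mean	30.3
covariates	nonpad	bmi_sd	5.9
covariates	nonpad	dm_duration_mean	10.8
covariates	nonpad	dm_duration_sd	9.5
covariates	nonpad	htn_duration_mean	5.4
covariates	nonpad	htn_duration_sd	6.9
covariates	nonpad	abi_left_mean	1.09
covariates	nonpad	abi_left_sd	0.08
covariates	nonpad	abi_right_mean	1.10
covariates	nonpad	abi_right_sd	0.07
covariates	nonpad	male_prop	0.440678
covariates	nonpad	smoking_prop	0.296610
covariates	nonpad	statin_prop	0.593220
covariates	nonpad	antiplatelet_prop	0.677966
covariates	nonpad	antihypertensive_prop	0.550847
covariates	pad	age_mean	59.1
covariates	pad	age_sd	7.9
covariates	pad	bmi_mean	31.7
covariates	pad	bmi_sd	5.5
covariates	pad	dm_duration_mean	13.5
covariates	pad	dm_duration_sd	8.4
covariates	pad	htn_duration_mean	8.0
covariates	pad	htn_duration_sd	8.5
covariates	pad	abi_left_mean	0.88
covariates	pad	abi_left_sd	0.14
covariates	pad	abi_right_mean	0.92
covariates	pad	abi_right_sd	0.11
covariates	pad	male_prop	0.423729
covariates	pad	smoking_prop	0.186441
covariates	pad	statin_prop	0.635593
covariates	pad	antiplatelet_prop	0.889831
covariates	pad	antihypertensive_prop	0.711864
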