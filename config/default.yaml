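age_max: 11
age_min: 8
amplitude.cycle.ankle: 0.6
amplitude.cycle.dom_wrist: 0.05
amplitude.cycle.nondom_wrist: 0.05
amplitude.cycle.waist: 0.05
amplitude.instep_pass.ankle: 1.5
amplitude.instep_pass.dom_wrist: 0.6
amplitude.instep_pass.nondom_wrist: 0.55
amplitude.instep_pass.waist: 0.35
amplitude.lego.ankle: 0.005
amplitude.lego.dom_wrist: 0.06
amplitude.lego.nondom_wrist: 0.05
amplitude.lego.waist: 0.008
amplitude.medium_walk.ankle: 0.55
amplitude.medium_walk.dom_wrist: 0.24
amplitude.medium_walk.nondom_wrist: 0.24
amplitude.medium_walk.waist: 0.2
amplitude.run.ankle: 1.1
amplitude.run.dom_wrist: 0.5
amplitude.run.nondom_wrist: 0.5
amplitude.run.waist: 0.42
amplitude.slow_walk.ankle: 0.3
amplitude.slow_walk.dom_wrist: 0.14
amplitude.slow_walk.nondom_wrist: 0.14
amplitude.slow_walk.waist: 0.12
amplitude.supine.ankle: 0.003
amplitude.supine.dom_wrist: 0.004
amplitude.supine.nondom_wrist: 0.004
amplitude.supine.waist: 0.003
amplitude.throw_catch.ankle: 0.08
amplitude.throw_catch.dom_wrist: 1.0
amplitude.throw_catch.nondom_wrist: 0.8
amplitude.throw_catch.waist: 0.1
bout_duration_s: 300.0
breath_interval_max_s: 4.0
breath_interval_min_s: 2.0
burst_baseline: 0.25
burst_duration_s: 0.9
cadence_s: 3.0
ci_method: hanley-mcneil
display_resolution: 0.1
epoch_length_s: 1.0
exclude_activities: []
height_mean_m: 1.4
height_sd_m: 0.1
light_max_met: 3.0
locations:
- nondom_wrist
- dom_wrist
- waist
- ankle
mass_mean_kg: 34.6
mass_min_kg: 15.0
mass_sd_kg: 8.6
master_seed: 1234
met_mean.cycle: 3.5
met_mean.instep_pass: 3.3
met_mean.lego: 1.25
met_mean.medium_walk: 2.7
met_mean.run: 4.4
met_mean.slow_walk: 2.2
met_mean.supine: 1.1
met_mean.throw_catch: 2.5
met_sd.cycle: 0.3
met_sd.instep_pass: 0.3
met_sd.lego: 0.12
met_sd.medium_walk: 0.25
met_sd.run: 0.4
met_sd.slow_walk: 0.25
met_sd.supine: 0.12
met_sd.throw_catch: 0.25
min_se_sp: 0.6
modulation_depth: 0.3
movement_freq_hz.cycle: 1.0
movement_freq_hz.instep_pass: 2.0
movement_freq_hz.lego: 0.8
movement_freq_hz.medium_walk: 1.9
movement_freq_hz.run: 2.6
movement_freq_hz.slow_walk: 1.6
movement_freq_hz.supine: 0.25
movement_freq_hz.throw_catch: 2.2
n_participants: 30
noise_sd_g: 0.01
participant_cv: 0.25
rest_amplitude_g: 0.02
rest_duration_s: 300.0
rest_met: 1.1
rest_movement_freq_hz: 0.5
resting_vo2_by_age.10: 5.8
resting_vo2_by_age.11: 5.8
resting_vo2_by_age.8: 5.8
resting_vo2_by_age.9: 5.8
sampling_rate_hz: 80.0
sed_max_met: 1.5
trim_s: 60.0
vig_min_met: 6.0
vo2_noise_sd: 0.07
vo2_tau_s: 30.0
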