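# Default cohort configuration: the published swine study conditions.
# Group means/SDs are the printed Table 1 / Table 2 values; waveform,
# time-course and pressure-diameter parameters emulate the tracing and
# ex vivo figures. Units ride in the `unit` fields.

n_per_group: 6
mu_cP: 1.0            # lymph viscosity, water-like default
lambda_range: [1.0, 1.6]   # axial stretch ratio draw range
split_factor: null    # systolic/diastolic split; null = derive from the triple

cohort:
  control:
    D_o:     {mean: 3.35,  sd: 0.37,  unit: mm,     lower: 0.0}
    h:       {mean: 0.06,  sd: 0.01,  unit: mm,     lower: 0.0}
    D_i:     {mean: 3.23,  sd: 0.29,  unit: mm,     lower: 0.0, derived: true}
    TDQ:     {mean: 0.78,  sd: 1.06,  unit: ml/min, lower: 0.0}
    TDP:     {mean: 8.2,   sd: 3.2,   unit: mmHg,   lower: 0.0}
    CC:      {mean: 12.2,  sd: 4.3,   unit: mmHg,   lower: 0.0}
    RV_mass: {mean: 49.8,  sd: 8.6,   unit: g,      lower: 0.0}
    LV_mass: {mean: 154.1, sd: 24.1,  unit: g,      lower: 0.0}
  tr:
    D_o:     {mean: 4.32,  sd: 0.57,  unit: mm,     lower: 0.0}
    h:       {mean: 0.26,  sd: 0.02,  unit: mm,     lower: 0.0}
    D_i:     {mean: 3.81,  sd: 0.52,  unit: mm,     lower: 0.0, derived: true}
    TDQ:     {mean: 9.34,  sd: 3.54,  unit: ml/min, lower: 0.0}
    TDP:     {mean: 14.6,  sd: 5.7,   unit: mmHg,   lower: 0.0}
    CC:      {mean: 18.9,  sd: 5.7,   unit: mmHg,   lower: 0.0}
    RV_mass: {mean: 87.1,  sd: 13.5,  unit: g,      lower: 0.0}
    LV_mass: {mean: 153.7, sd: 18.9,  unit: g,      lower: 0.0}

# per-animal day-28/baseline lymph-flow fold (drives the paired baseline draws)
tdq_fold: {mean: 11.7, sd: 4.7, unit: dimensionless, lower: 1.5}

# Systolic/diastolic/mean pressure triples (mmHg) per site and epoch.
pressure_triples:
  baseline:
    artery:          {sys: [107.0, 16.0], dia: [61.0, 11.0], mean: [73.0, 16.0]}
    jugular_vein:    {sys: [7.4, 4.7],    dia: [2.3, 2.1],   mean: [4.2, 2.6]}
    right_atrium:    {sys: [8.8, 5.8],    dia: [2.5, 2.7],   mean: [5.6, 4.7]}
    right_ventricle: {sys: [26.8, 5.7],   dia: [1.8, 3.5],   mean: [11.2, 5.7]}
  tr_10min:
    artery:          {sys: [101.0, 19.0], dia: [60.0, 10.0], mean: [75.0, 13.0]}
    jugular_vein:    {sys: [16.6, 5.5],   dia: [2.2, 1.7],   mean: [8.4, 3.6]}
    right_atrium:    {sys: [16.6, 5.1],   dia: [4.2, 3.9],   mean: [9.8, 4.9]}
    right_ventricle: {sys: [20.2, 4.8],   dia: [2.5, 3.3],   mean: [10.8, 4.9]}
  tr_4wk:
    artery:          {sys: [97.0, 12.0],  dia: [62.0, 8.0],  mean: [74.0, 10.0]}
    jugular_vein:    {sys: [19.3, 5.4],   dia: [3.7, 2.9],   mean: [10.1, 4.3]}
    right_atrium:    {sys: [22.7, 7.5],   dia: [3.7, 5.1],   mean: [12.0, 5.2]}
    right_ventricle: {sys: [22.2, 7.6],   dia: [4.8, 4.5],   mean: [11.8, 5.1]}

waveform:
  heart_rate_hz: 1.5        # ~90 bpm
  resp_rate_hz: 0.25        # ~15 breaths/min
  sample_rate_hz: 100.0
  duration_s: 30.0
  pressure_noise_sd: 0.3    # mmHg
  resp_fraction: 0.05       # respiratory modulation as fraction of pulse amplitude
  flow_baseline:  {cardiac_amp: 0.3, resp_amp: 0.2, noise_sd: 0.05, amp_ref: 0.78}
  flow_post_tr:   {cardiac_amp: 4.0, resp_amp: 1.0, noise_sd: 0.3, amp_ref: 9.34,
                   trough_depth: 14.0, trough_width_s: 0.08, trough_prob: 0.7}

timecourse:
  fold_1h: 3.0          # ~3-fold one hour after induction
  plateau_fold: 10.0    # ~10-times baseline
  plateau_day: 2.0      # plateau reached by day 2
  jitter_sd: 0.12       # lognormal day-to-day jitter (plateau wanders ~8-11 fold)
  days: [0.0, 0.0416667, 1.0, 2.0, 3.0, 7.0, 14.0, 28.0]

pd_curve:
  heights_cm: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 20, 30]
  control: {d0_mm: 2.0, dmax_mm: 3.6, k_mmhg: 4.0}
  tr:      {d0_mm: 2.6, dmax_mm: 4.4, k_mmhg: 5.0}
  noise_sd_mm: 0.02
  animal_cv: 0.05       # per-animal jitter of d0/dmax

# Printed biomechanical columns and ratio row, used as reference anchors
# for internal-consistency checks (not sampled; stresses are recomputed
# per animal from geometry, flow and pressure).
reference:
  WSS:   {control: [0.004, 0.005], tr: [0.032, 0.009], unit: dyn/cm2}
  sigma: {control: [19.5, 3.5],    tr: [10.3, 1.9],    unit: kPa}
  ratio_row:
    D_o:   [1.3, 0.14]
    D_i:   [1.2, 0.15]
    h:     [4.4, 0.52]
    TDQ:   [11.7, 4.7]
    TDP:   [1.8, 0.5]
    WSS:   [8.4, 5.6]
    sigma: [0.53, 0.11]
  rv_ra_gradient_pre_mmHg: 6.0
  rv_ra_endpoint_mmHg: 2.0
  tdq_fold_lower_bound: 8.0    # "approximately 8-11 fold its baseline"
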