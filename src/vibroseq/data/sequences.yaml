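# Stimulus library: pulse kinematics and pulse orders for the two
# discrimination tasks.  Rise/fall times in ms, amplitudes in mm; the nominal
# peak velocities (mm/s) are the quoted hardware values and are informational.
pulses:
  F:  {rise_ms: 8.0,  fall_ms: 8.0,  amplitude_mm: 1.03, nominal_peak_velocity_mm_s: 220.0}
  M:  {rise_ms: 11.0, fall_ms: 11.0, amplitude_mm: 1.15, nominal_peak_velocity_mm_s: 170.0}
  S:  {rise_ms: 14.0, fall_ms: 14.0, amplitude_mm: 1.14, nominal_peak_velocity_mm_s: 110.0}
  # four-pulse task pulse set
  F4: {rise_ms: 9.0,  fall_ms: 9.0,  amplitude_mm: 1.2,  nominal_peak_velocity_mm_s: 216.0}
  S4: {rise_ms: 12.5, fall_ms: 12.5, amplitude_mm: 0.7,  nominal_peak_velocity_mm_s: 120.0}

sequences:
  FFF:  {pulses: [F, F, F],      gap_ms: 34.0, reward_side: right}
  FMS:  {pulses: [F, M, S],      gap_ms: 34.0, reward_side: right}
  SMF:  {pulses: [S, M, F],      gap_ms: 34.0, reward_side: left}
  SSS:  {pulses: [S, S, S],      gap_ms: 34.0, reward_side: left}
  # same-intensity four-pulse set (matched mean speed)
  FSFS: {pulses: [F4, S4, F4, S4], gap_ms: 34.0, reward_side: right}
  SFFS: {pulses: [S4, F4, F4, S4], gap_ms: 34.0, reward_side: left}
  # different-intensity variants: amplitudes rescaled so the two trains
  # differ strongly in mean speed (scale ratios follow the quoted
  # 27.8/25.7 and 8.7/26.4 mm/s mean-speed targets)
  FSFS_diff: {pulses: [F4, S4, F4, S4], gap_ms: 34.0, reward_side: right, amplitude_scale: 1.0817}
  SFFS_diff: {pulses: [S4, F4, F4, S4], gap_ms: 34.0, reward_side: left,  amplitude_scale: 0.3295}
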