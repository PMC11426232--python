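# Ultrasound stimulation protocol registry (one entry per parameter set).
# Fields: fundamental frequency (kHz), pulse repetition frequency (Hz),
# duty cycle (%), sonication duration (s), inter-stimulus interval (s),
# insonation time (min), acoustic pressure (MPa), spatial-peak
# temporal-average intensity (mW/cm^2).
row1:
  fundamental_khz: 250
  prf_hz: 20
  duty_pct: 10
  sd_s: 5
  isi_s: 5
  insonation_min: 1
  pressure_mpa: 0.9
  ispta_mw_cm2: 328.7
row2:
  fundamental_khz: 250
  prf_hz: 20
  duty_pct: 10
  sd_s: 5
  isi_s: 5
  insonation_min: 1
  pressure_mpa: 1.8
  ispta_mw_cm2: 1314.9
row3:
  fundamental_khz: 250
  prf_hz: 20
  duty_pct: 10
  sd_s: 5
  isi_s: 5
  insonation_min: 15
  pressure_mpa: 0.9
  ispta_mw_cm2: 328.7
row4:
  fundamental_khz: 250
  prf_hz: 20
  duty_pct: 10
  sd_s: 5
  isi_s: 5
  insonation_min: 15
  pressure_mpa: 0.45
  ispta_mw_cm2: 82.2
row5:
  fundamental_khz: 250
  prf_hz: 20
  duty_pct: 10
  sd_s: 5
  isi_s: 5
  insonation_min: 30
  pressure_mpa: 0.9
  ispta_mw_cm2: 328.7
row6:
  fundamental_khz: 250
  prf_hz: 1
  duty_pct: 10
  sd_s: 5
  isi_s: 5
  insonation_min: 15
  pressure_mpa: 0.9
  ispta_mw_cm2: 328.7
row7:
  fundamental_khz: 250
  prf_hz: 1000
  duty_pct: 10
  sd_s: 5
  isi_s: 5
  insonation_min: 15
  pressure_mpa: 0.9
  ispta_mw_cm2: 328.7
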