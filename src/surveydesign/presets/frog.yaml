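# Stream-frog repeat-survey scenario: nightly visits to stream transects,
# roughly an hour of search per visit, strong night-to-night variability.
name: frog
kind: repeat_surveys
time_unit: hour
rate:
  mu: 0.67        # detections per hour at abundance 1
  theta: 2.5      # coefficient of variation (same at every abundance)
abundance_levels: [1, 3]
mu_by_abundance:
  1: 0.67
  3: 2.2
design:
  B: 10.0         # season time budget per site, hours
  c: 1.0          # fixed travel/setup time per survey, hours
  Q_c: 0.05       # acceptable failed-detection probability
correlation:
  r: 0.3          # night-to-night log-rate correlation
  structure: ar1
  T: 90.0         # season length, nights
layout:
  n_sites: 29
  visits_min: 2
  visits_max: 9
  search_time: 1.0
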