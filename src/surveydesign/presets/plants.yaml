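# Timed plant-search scenario: a grid of observers by quadrats, 15-minute
# sessions, time to first detection recorded (censored at session end).
name: plants
kind: quadrat_experiment
time_unit: minute
species:
  atriplex:
    mu: 0.55      # detections per minute
    sigma: 0.60
  lomandra:
    mu: 0.56
    sigma: 0.64
design:
  budgets: [5.0, 10.0, 15.0]     # minutes of total search budget
  fixed_costs: [0.25, 0.5, 1.0]  # minutes of travel between quadrats
  Q_c: 0.05
layout:
  n_observers: 14
  n_quadrats: 9
  session_length: 15.0
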