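# Default analysis configuration: deterministic fit to the qualitative
# endpoint data at a = 60 percent membrane damage.
schedule:
  on_intervals: [[0.0, 10.0], [30.0, 40.0]]
  t_end: 40.0
  t1: 10.0
  t2: 30.0
endpoint:
  a: 60.0
tr1_law: mass_action_im
unit_mode: counts
framework: deterministic
n_particles: 100
seed: 11
prior:
  lower: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  upper: [1.0, 100.0, 1.0, 1.0, 0.05, 0.01, 0.01, 1.0, 1.0, 5.0]
tolerances:
  - [100.0, 13.0, 100.0, 100.0, 1.5]
  - [80.0, 10.0, 100.0, 100.0, 1.3]
  - [60.0, 8.0, 70.0, 70.0, 1.2]
  - [50.0, 7.0, 60.0, 60.0, 1.1]
  - [40.0, 6.0, 50.0, 50.0, 1.0]
  - [30.0, 5.0, 40.0, 40.0, 0.9]
  - [20.0, 4.0, 30.0, 30.0, 0.8]
  - [10.0, 3.0, 20.0, 20.0, 0.7]
# optional fixed parameters for `pspabc simulate`
params:
  k1: 0.0916
  k2: 50.0
  k3: 0.3
  k4: 0.2
  k5: 0.02
  k6: 0.005
  k7: 0.005
  k8: 0.3
  k9: 0.3
  k10: 1.0
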