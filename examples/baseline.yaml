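AL: 18.0
EL: 19.0
THK: 0.35
t_post: 0.6
t_cornea: 0.4
cornea_angle: 120.0
apex_offset: 1.0
include_cornea: true
mu: 0.083
mu_post: null
mu_post_ratio: null
alpha: 40.0
mu_cornea: null
kappa_ratio: 1000.0
IOP: 18.0
airpuff:
  peak_kpa: 15.4
  steps: 6
  total_time_ms: 20.0
  kernel: gaussian
  fwhm_mm: 3.38
solver:
  newton_tol: 1.0e-06
  max_newton_iters: 25
  max_cutbacks: 8
  min_substep: 0.00390625
  face_quad_order: 3
stress_free:
  iterations: 3
  mode: per_iop
  reference_iop: 10.0
resolution: 400
seed: 0
outdir: results
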