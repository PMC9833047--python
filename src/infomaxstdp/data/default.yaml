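# Default parameter set of the infomax / slow-wave model.
# Times in ms, voltages in mV, rates in Hz unless noted.

simulation:
  dt: 1.0                    # integration step
  burn_in: 10000.0           # discarded before any measurement
  burn_in_sleep: 200000.0    # plasticity-free prefix of sleep sessions
  initial_last_spike: -10000.0

activation:
  E: {r0: 1.5, u0: -69.4, delta_u: 0.5}
  I: {r0: 6.0, u0: -62.5, delta_u: 0.5}

refractory:
  tau_R: 30.0

kernel:
  tau_m_E: 25.0
  tau_m_I: 5.0
  u_r: -70.0

adaptation:
  tau_a: 1500.0
  beta: 0.0077               # mV/ms per spike

plasticity:
  alpha: 0.01                # (mV)^2
  lam: 0.32                  # 1/(mV)^2
  tau_C: 100.0

single_neuron:
  n_stim: 20
  n_background: 100
  w_stim: 0.5
  w_background: 0.5
  background_rate_up: 2.0
  background_rate_down: 0.1

network:
  n_E: 800
  n_I: 200
  n_local: 4
  w_EE: 0.16
  w_EI: -0.14
  w_IE: 0.66
  p_EE_long: 0.05
  p_IE_long: 0.3

classification:
  theta_up: -68.25
  theta_down: -69.75

sleep:
  n_G: 40
  n_L: 40
  w_init: 0.09
  rate_start: 7.5
  rate_end: 5.0
  blocking_margin: 50.0
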