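# Excitatory/inhibitory LIF network (units: mV, ms; rates in spikes/s).
# gamma = 0.25, p = 0.1, J = 0.1 mV, g = 5.  The default drive reproduces
# a Gaussian input with mean 10 mV and SD 5 mV.
netscale-spec: v1
populations: [e, i]
N: [8000, 2000]
p: 0.1
J: [[0.1, -0.5], [0.1, -0.5]]
delays: 3
neuron:
  model: lif
  tau_m: 20
  tau_s: 2
  tau_ref: 2
  theta: 15
  V_r: 0
drive:
  kind: gaussian
  mu_ext: 10
  sigma_ext: 5
  J_ext: 0.1
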