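# Two-population binary network with population-specific connectivity.
# Drive units are dimensionless (same scale as the synaptic weights).
netscale-spec: v1
populations: [e, i]
N: [5000, 5000]
p: [[0.1, 0.2], [0.3, 0.4]]
J: [[3, -5], [3, -6]]
delays: 0.1
neuron:
  model: binary
  tau_m: 10
  theta: 0
drive:
  - {kind: gaussian, mu_ext: 50, sigma_ext: 60}
  - {kind: gaussian, mu_ext: 40, sigma_ext: 50}
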