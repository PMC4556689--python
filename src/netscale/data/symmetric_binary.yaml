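# Self-sustaining symmetric binary network (gamma = 1, g = 3, theta = -3):
# spontaneously active without external drive.  J = 1/sqrt(N).
netscale-spec: v1
populations: [e, i]
N: [1000, 1000]
p: 0.2
J: [[0.03162277660168379, -0.09486832980505137], [0.03162277660168379, -0.09486832980505137]]
delays: 0.1
neuron:
  model: binary
  tau_m: 10
  theta: -3
drive:
  kind: dc
  I_dc: 0
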