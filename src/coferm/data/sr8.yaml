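# Fitted kinetics: xylose fermentation by S. cerevisiae SR8
# Ki and Kip are structurally absent (no substrate-inhibition terms).
name: SR8
mu_m: 0.154    # /h
Ks: 1.31       # g/L
Pm: 25.33      # g/L
beta: 0.742
m: 0.01        # /h
Yps: 0.4       # g/g
Yxs: 0.35      # g/g
b1: 1.12
b2: 1.32
vm: 0.401      # /h
Ksp: 13.32     # g/L
Pmp: 27        # g/L
gamma: 1.04
a_s0: 0.0
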