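# Fitted kinetics: cellobiose fermentation by S. cerevisiae EJ2
name: EJ2
mu_m: 0.154    # /h
Ks: 0.568      # g/L
Ki: 204        # g/L
Pm: 69         # g/L
beta: 1.1
m: 0.01        # /h
Yps: 0.5       # g/g
Yxs: 0.48      # g/g
b1: 1.0
b2: 1.0
vm: 0.416      # /h
Ksp: 5         # g/L
Kip: 52        # g/L
Pmp: 100       # g/L
gamma: 1.1
a_s0: 0.011    # /(g/L), initial-substrate production boost
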