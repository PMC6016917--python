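# coferm

Kinetic modelling of batch ethanol fermentation by engineered
*Saccharomyces cerevisiae* specialist strains — the cellobiose-consuming
strain EJ2, the xylose-consuming strain SR8 — and of their co-culture, for
designing consortium compositions that ferment mixed cellulosic sugars
simultaneously.

The package is aimed at bioprocess modellers working on mixed-sugar
fermentation: it provides the rate laws and ODE systems, a least-squares
parameter-estimation workflow, a synthetic-data generator emulating the
underlying experimental design, and an inoculum-design scan, all usable
from Python or from the `coferm` command line.

## The model

Single-strain batch fermentation is described by Monod-type kinetics with
substrate and product inhibition (concentrations in g/L, biomass in
g DCW/L, time in h):

```
growth        μ = (1/X) dX/dt = μ_m S / (K_s + S + S²/K_i) · {1 − (P/P_m)^β}
production    ν = (1/X) dP/dt = exp(a_S0·S0) · v_m S / (K_s' + S + S²/K_i') · {1 − (P/P_m')^γ}
consumption   −dS/dt = (1/(b1·Y_P/S)) dP/dt + (1/(b2·Y_X/S)) dX/dt + m·X
```

The `S²/K_i` terms (Haldane substrate inhibition, rate maximum at
`√(K_s·K_i)`) are structurally optional: they are present for EJ2 and
absent for SR8.  The Luong factors `{1 − (P/P_m)^β}` drive rates to zero
exactly at the critical ethanol concentrations and are clamped at zero
beyond them.  `exp(a_S0·S0)` is an empirical boost of specific
productivity with the initial sugar load (EJ2 only, `a_S0 = 0.011`), and
`b1`, `b2` amend the SR8 yields for unmodelled ethanol re-assimilation.

The co-culture couples the two models through the shared ethanol pool and
six fitted weighing factors `r1..r6`: `r1`/`r2` amend the ethanol
inhibition felt by each strain (growth Luong factors evaluated at `r1·P`,
`r2·P`), `r3`/`r4` weight biomass accumulation, and `r5`/`r6` — together
with share factors built from the initial sugar and inoculum ratios —
weight each strain's contribution to the observable ethanol pool.  There
is no substrate competition: each strain consumes only its own sugar.
See `docs/methods.md` for the full system, its assumptions, and the one
calibrated constant.

Packaged parameter sets (`ej2.yaml`, `sr8.yaml`, `coculture_default.yaml`)
carry the fitted constants, e.g. for EJ2: μ_m = 0.154 /h, K_s = 0.568 g/L,
K_i = 204 g/L, P_m = 69 g/L, β = 1.1, Y_P/S = 0.5 g/g, v_m = 0.416 /h.

## Worked example

Design the inoculum for a 60 g/L cellobiose + 20 g/L xylose feed:

```python
import coferm as cf

p = cf.default_coculture(S0_c=60.0, S0_x=20.0)
best, table = cf.find_inoculum_ratio(
    p, candidates=[(0.45, 0.45), (0.9, 0.45), (1.35, 0.45)],
    selection="productivity")
print(f"best EJ2:SR8 = {best.X0_E}:{best.X0_S}  "
      f"depletion {best.t_deplete_c:.1f} / {best.t_deplete_x:.1f} h  "
      f"productivity {best.productivity:.2f} g/L/h")
```

prints

```
best EJ2:SR8 = 0.9:0.45  depletion 19.0 / 13.1 h  productivity 1.27 g/L/h
```

i.e. doubling the cellobiose-strain inoculum (2:1) empties both sugars
within 20 h — cellobiose by 19.0 h, xylose by 13.1 h — at the highest
overall ethanol production rate among the candidates.  The same scan is
available as `coferm design --scenario coculture_default ...`; the other
subcommands are `simulate`, `fit`, `synth` and `variants`.

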