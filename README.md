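# podofp

Multiscale stability analysis of the actin cytoskeleton in kidney podocyte
foot processes.

Podocytes wrap glomerular capillaries with hundreds of fingerlike foot
processes (FPs) whose shape is maintained by crosslinked actin bundles.
Loss of those bundles — foot process effacement — is a hallmark of chronic
kidney disease.  This package implements a minimal kinetic model of the FP
actin cytoskeleton and asks how its stability depends on the regulatory
balance (Rac1-like polymerisation feedback vs RhoA-like bundling) and on
the cell's extreme geometry, where a shared, diffusion-limited G-actin pool
feeds hundreds of competing FPs.  It is aimed at systems biologists and
modellers studying cytoskeletal stability and podocytopathies.

## Model

Three actin pools are tracked per foot process: monomer `Ga`, filaments
`Fa`, bundles `Bu` (all non-dimensional):

    dFa/dt = α_f·Ga·Fa²/(Fa² + k²) + γ_f·Ga·(Fa + 2·Ga)
             − α_b·Fa·(2·Fa + Bu) − β_f·Fa
    dBu/dt = α_b·Fa·(2·Fa + Bu) + γ_b·Ga·Bu − β_b·Bu

with mass conservation over the cell closing the system:
`total actin = ∫cell Ga dV + ∫FP (Fa + Bu) dV`.  `α_f` is the
filament-dependent positive feedback (nephrin/Rac1 signalling, FP-local),
`α_b` the bundling coefficient (RhoA), and `β_f`, `β_b` turnover rates.
Depending on these rates the system is monostable-healthy, bistable
(a collapsed state coexists), oscillatory, or collapses outright.

The same kinetics are solved in three settings:

1. **Whole cell ODE** (`podofp.kinetics`) — phase plane, nullclines,
   equilibria with stability, regime classification.
2. **Two compartments with a shared monomer pool** (`podofp.twocomp`) —
   tristability under localized transient stimuli: depending on pulse
   strength both FP groups recover, the unstimulated group collapses, or
   the stimulated group overshoots and collapses.
3. **Reaction–diffusion on an idealised podocyte** (`podofp.geometry`,
   `podofp.spatial`) — a procedurally generated quarter-cell (cell body,
   36 branch paths whole-cell, 233 FPs, matched surface-to-volume ratios
   and process lengths) discretised as a finite-volume network.  G-actin
   diffuses everywhere; filament/bundle reactions run in FP cells.  After a
   uniform bundling increase the FPs desynchronise and an irregular,
   perturbation-sensitive subset effaces permanently while survivors build
   stronger bundles — deterministic spatiotemporal chaos — and
   compensatory interventions spare more FPs the earlier they arrive.

## Worked example

Equilibrium structure when the polymerisation feedback is weakened
(α_f = 0.32 → 0.1):

    $ podofp ode equilibria --params fig2D
    Fa=0.01685 Bu=0.00199 stable  effacement=True
    Fa=0.06202 Bu=0.03192 saddle  effacement=True
    Fa=0.15293 Bu=0.30204 stable  effacement=False
    regime: bistable

Two stable states now coexist: the healthy branch (Bu ≈ 0.30) and a
collapsed state inside the effacement region (Bu ≈ 0.002), separated by a
saddle — a weakened podocyte can be flipped into effacement by a transient
insult.  The four regimes at the calibrated anchors:

    $ podofp reproduce fig2
    {"fig2C": "monostable_healthy", "fig2D": "bistable",
     "fig2E": "oscillatory", "fig2F": "collapse"}

A spatially uniform bundling increase (α_b 0.03 → 0.05 at t = 40) on the
idealised geometry produces partial, asynchronous effacement:

    $ podofp spatial run --scenario fig3_global_ab
    {"n_fp": 233, "effaced": 113, "survived": 120, "threshold": 0.1107}

113 of 233 FPs lose their bundles permanently even though every FP has
identical parameters; the survivors end with mean bundle concentration
above the healthy value (~1.2 vs 1.11), having absorbed the released
monomer.

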