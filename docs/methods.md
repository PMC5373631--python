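# Methods

## The kinetic model

The actin cytoskeleton of a foot process (FP) is reduced to three pools:
diffusible monomer `Ga`, filaments `Fa`, and crosslinked bundles `Bu`, all
non-dimensional.  Filaments grow by elongation (`γ_f·Ga·Fa`), spontaneous
dimer nucleation (`2·n·Ga²`, with the factor 2 keeping the actin count of a
dimer correct; `n = γ_f` by default), and a filament-dependent positive
feedback `α_f·Ga·Fa^h/(Fa^h + k^h)` standing in for Arp2/3-branched
nucleation downstream of nephrin/Nck/Rac1 signalling — a saturating Hill
form (`h = 2`, `k = 0.22`) so the effective rate is bounded and only
engages once `Fa ~ k`.  Bundles form and grow by filament merging and
addition (`α_b·Fa·(2Fa + Bu)`, RhoA/crosslinker-driven) plus direct
monomer addition (`γ_b·Ga·Bu`); filaments and bundles turn over linearly
(`β_f`, `β_b`), lumping depolymerisation and mechanical rupture.  Every
reaction moves actin between pools, so the local rates sum to zero and the
whole-cell pool

    total_actin = Ga + φ_fp·(Fa + Bu)      (reference cell volume ≡ 1)

is conserved; `φ_fp = 0.2` is the FP share of cell volume.  Bundles below
an effacement threshold cannot support FP morphology; the threshold is
10% of the healthy bundle concentration (0.1107) and is configurable.

## Parameter provenance and calibration

Fixed anchors: `k = 0.22`, `α_f ∈ {0.32, 0.1}` (healthy vs weakened
feedback), `α_b ∈ {0.03, 0.05}` (basal vs hyperactive bundling), `h = 2`,
`φ_fp = 0.2`, and the observation that healthy podocytes hold monomeric to
polymerised actin at 1:2.  The remaining rates are calibrated once, by a
regime search, and shipped as the `fig2C` preset:

| parameter | value | origin |
|---|---|---|
| total_actin | 0.4 | free concentration scale; chosen so all four regimes appear at the printed anchors |
| γ_f = γ_b | 0.002 | calibrated (weak background nucleation/annealing) |
| filament share of healthy polymer | 0.17 | calibrated |
| β_f | 0.050707 | closed form: healthy state is an exact equilibrium |
| β_b | 0.009852 | closed form, as above |

With these values the healthy state `(Ga, Fa, Bu) = (0.1333, 0.2267,
1.1067)` is an exact equilibrium, and the four parameter sets behave as:
`fig2C` single stable equilibrium; `fig2D` (α_f = 0.1) three equilibria,
two stable, the lower one in the effacement region; `fig2E` (α_b = 0.05)
no stable equilibrium, a relaxation cycle of period ≈ 370; `fig2F`
(α_f = 0.1, α_b = 0.05) collapse.  Shrinking the actin pool to 70% makes
the `fig2E` set collapse; 115% gives stronger but still cycling bundles.

Because the printed anchor pairs (0.32→0.1, 0.03→0.05) must each cross a
bifurcation, the calibrated set necessarily sits near those boundaries.  A
consequence: steepening the feedback to `h = 4` (with turnover rates
re-solved) Hopf-destabilises the healthy root, so regime labels are *not*
invariant to the Hill exponent here, although a moderate split of the
nucleation coefficient from the elongation rate (25%) preserves them.
Parameter sets with more margin may exist but are not derivable from the
available anchors.

## Equilibria, nullclines, regimes

Conservation eliminates `Ga`, leaving a planar system in `(Fa, Bu)` on the
feasible triangle `Fa + Bu ≤ total/φ`.  Equilibria are found by a dense
sign-change scan seeding a Newton polisher, deduplicated and classified by
the eigenvalues of a finite-difference Jacobian; the test suite
cross-checks root counts against an independent sign-partition oracle on
grids up to 2000².  Regime classification: monostable-healthy (one stable
root outside the effacement region), bistable (≥2 stable, one inside),
oscillatory (no stable root, sustained bounded cycle detected by peak
analysis over a horizon of 50 slow time constants), collapse (all standard
initial conditions end below threshold).

## Two-compartment model

The FP pool is split in fractions `1−f₂` (nominal `α_f`) and `f₂`
(`α_f + Δα_f(t)`); `Ga` mixes infinitely fast, so both compartments share
one monomer concentration fixed by conservation.  The transient stimulus
is a trapezoid on `α_f` in compartment 2: onset t = 40, rise 10, hold 30,
fall 10 (model time units), amplitude quoted as peak `Δα_f/α_f`.  A
rise-plus-exponential-decay pulse was tried first but leaves the
FP1-collapse amplitude band about four-fold wide, incompatible with the
canonical outcome amplitudes; the trapezoid places the switching
amplitudes at ≈0.57 and ≈1.65, so 0.5 → both recover, 1 → FP1 collapses,
2 → FP2 overshoots then collapses (tristability).  Steady-state surfaces
integrate to `max|dy/dt| < 1e-8`; oscillatory grid points are flagged, not
reported as steady.

## Idealised geometry

The quarter-cell (reflective symmetry about two planes, symmetry factor 4)
is built from closed-form primitives: a quarter-sphere cell body, nine
straight radial branch paths of primary (radius solved) and secondary
(taper 0.75) cylinders, and 233 FP cylinders of radius 2/9 μm (fixing the
FP surface-to-volume ratio at exactly 9 μm⁻¹) and length 3.04 μm (chosen
to match the reconstructed per-FP volume ≈ 0.472 μm³).  The cell-body
radius and primary radius are solved so the FP-free body hits 420 μm³ and
695 μm² exactly; branch points sit at 18 μm arclength and endpoint
distances are spread 25–40 μm with the three furthest averaging 39 μm.
FPs are evenly spaced along the pooled process arclength (optional seeded
jitter).  Resulting totals: 529.9 μm³, 1684 μm², A/V = 3.18 μm⁻¹,
V_FP/V = 20.7%, area gain 142%.

`to_network` discretises this tree as a finite-volume graph: four
equal-volume concentric cell-body shells, axial process cells ≤ 2 μm
(default), one well-mixed cell per FP joined through its neck
cross-section.  Volume is conserved exactly; the 2 μm default keeps
intra-FP gradients (FP length ≈ 3 μm) negligible against the
process-scale gradients that drive the spatial dynamics.

The cell body is identified by a stratification filter: uniform volumetric
synthesis, diffusion through the network, and membrane export proportional
to local concentration and exposed area.  Only the export/diffusivity
ratio matters; defaults (D = 30 μm²/t.u., export velocity 0.05 μm/t.u.)
give a clean split — cell-body cells retain ≥ 98% of the maximum steady
concentration, processes and FPs fall below 87% — against the 90%
threshold.  The profile changes by < 2% at matched positions between 2 μm
and 1 μm meshes.

## Spatial reaction–diffusion model

State: `Ga` in every cell, `Fa`/`Bu` in FP cells only (filament and bundle
reactions, and the feedback `α_f`, are FP-local; bundles elsewhere are
neglected).  Method of lines with the conservative finite-volume exchange
operator `A_ij·D/(d_ij·V_i)`, no-flux outer boundary, stiff BDF
integration with an analytic sparsity pattern, outputs on a fixed grid;
identical inputs give bit-identical reports.  Protocols restart the
integrator at their breakpoints so parameter discontinuities do not
corrupt step-size control.  `D_Ga = 4 μm²/t.u.` by default: monomer
redistribution across the ~40 μm tree then competes with the bundle-cycle
timescale, which is the regime that desynchronises the FPs after a global
perturbation (at very large `D_Ga` the model provably collapses onto the
single- or two-compartment ODEs, a limit the tests assert at < 1%
sup-norm deviation, with `φ_fp` matched to the generated geometry's actual
FP volume share of 0.2074).

Effacement is detected per FP from its bundle time course.  Two rules are
provided: the *persistent* rule (below threshold from some `t*` through
`t* + window` and through the end of the record; window defaults to 10% of
the record) and the *irreversible* rule used by the scenario runners, in
which any sub-threshold stretch of at least the window marks the FP as
effaced even if bundle concentration later regrows — sustained bundle loss
means the FP is morphologically resorbed, and the model carries no
mechanics that could rebuild it.  The distinction matters under strong
compensatory stimuli, which can regrow bundles in already-lost FPs and
would otherwise inflate survivor counts.  Terminal stretches shorter than
the window are flagged unresolved, never silently classified.

Scenario defaults (all configurable): global bundling step `α_b` +2/3 at
t = 40 (horizon 2400); localized `α_f` pulse ×(1+2) with rise 10/hold
100/fall 50 on the distal 20–34 μm band of the five longest paths
(horizon 2000); `β_b` halved at t = 0 with compensation at `t₁`
(restore `β_b`, lower `α_b` by 40%, or raise `α_f` by 50%; horizon 2500).
Under the bundling step, 113/233 FPs efface by t = 2400 with the
asynchrony index (1 − mean pairwise bundle-course correlation, rescaled to
[0,1]) rising from 0 to ≈ 0.4, survivors strengthen, and a 0.1% change of
the step amplitude changes the effacement pattern (divergence ≈ 0.06) —
the deterministic sensitivity diagnostic.  Earlier compensation spares
more FPs in every mode.

## Numerical choices

LSODA for the small ODE systems (rtol 1e-8/atol 1e-11 defaults; tighter in
oracle comparisons), BDF with Jacobian sparsity for the network system
(rtol 1e-6/atol 1e-9).  Total actin drifts < 1e-9 (ODE) and < 1e-6
relative (spatial) over every scenario.  Root polishing accepts residuals
< 1e-10.  Degenerate inputs: zero export in the stratification solve,
over-full actin pools, negative states and empty grids raise explicit
errors; constant bundle records define asynchrony 0.

## What the synthetic geometry does and does not capture

The generator reproduces the aggregate morphometrics (volumes, areas,
surface-to-volume ratios, branch counts, length scales) of the
reconstructed cell, which set the diffusion lengths and source/sink
topology the mechanism depends on, but not its irregular 3-D branching,
curvature, or FP-to-FP contact geometry, and the network discretisation
replaces the full 3-D mesh with a 1-D tree — the largest deviation from
the source pipeline.  Chaotic pattern identity is therefore meaningless
across discretisations (survivor *counts* are mesh-robust to < 10% of the
FP population; patterns are not asserted).  Passing tests show the
mechanism — resource-competition-driven desynchronisation and partial
irreversible effacement — not voxel-level agreement with any particular
reconstruction.

## Known limitations

- The full published rate table is not available in the extracted source;
  rates beyond the printed anchors are calibrated, so quantitative time
  courses (e.g. the cycle period) are calibration-dependent; the regime
  structure, ratios and morphometrics are the reproduced claims.
- Regime labels are sensitive to the Hill exponent (see above).
- No mechanics: effacement is a bundle-concentration surrogate; membrane
  retraction, adhesion and stress redistribution are out of scope, as are
  stochastic kinetics (the chaos is deterministic).
- The spatial model carries `Fa`/`Bu` only in FPs; cell-body F-actin is
  treated as decoupled from the monomer budget.
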