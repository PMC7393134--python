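# epishell

An active 3D vertex model of closed, single-cell-thick epithelial shells
— the minimal mechanical setting in which organoid-like morphologies
(spherical, stomatocyte/cup, budded, branched) emerge from identical
cells.

## The model

Each of the `N_c` cells is an incompressible prism with a polygonal
apical side facing an incompressible fluid lumen, a basal side facing
outward, and lateral sides shared with its neighbours.  With lengths in
units of the cell-volume scale and tensions in units of the lateral
tension, the shell energy is

    w = Σ_cells [ α a_a + β a_b + ½ a_l ]
        + (K/2) Σ_cells (V_i − 1)² + (K/2) (V_lumen − v_lumen)²
        + Σ_junctions γ_i (l_a,i + l_b,i)

where `α`, `β` are the apical and basal tensions, the stiff harmonic
terms (K = 100) enforce the volumes, and the `γ_i` are fluctuating
junctional line tensions (zero unless the fluctuating-tension activity
scheme is on).  Vertices relax by overdamped gradient descent
`dr/dt = −∇w` (forward Euler, `δt = 10⁻⁴`), while cells exchange
neighbours through T1 transitions: always when a junction collapses
below the threshold length `δl = 0.15`, and additionally at an active
rate `k_T1(t)` (or, in the alternative scheme, whenever
Ornstein–Uhlenbeck tension noise of magnitude `σ` squeezes a junction
shut).  Shells can also grow: cells stochastically double their target
volume and divide, with the preferred lumen volume tracking tissue size.

Two dimensionless tensions organize the phase diagram: the tissue
tension `α + β` sets the preferred cell height
`h₀ = (2^{1/3}/3^{1/6})(α+β)^{2/3}` and through it the reduced volume
`v = 6√π V/A^{3/2}` of the shell (spherical above `α + β ≈ 1.9`), while
the differential tension `α − β` acts as a spontaneous curvature
`c₀ = 2√h(α−β)` that selects buds (`α > β`) or invaginations (`α < β`).
Branched shapes are out-of-equilibrium: they require a sufficiently high
active T1 rate, which lets topological defects (pentagons at tips,
heptagons at saddles) aggregate and lock in Gaussian curvature.

## A worked example

`examples/02_active_t1_branching.py` relaxes the same low-tension shell
(`α = 0.7`, `β = 0.5`, 64 cells, lumen from the size-matching rule)
passively and with an active T1 schedule decaying from
`k_T1^{(0)} = 200`:

```
passive : v = 0.889  energy = 197.47  T1 events = 0     polygon classes = {5: 12, 6: 52}
active  : v = 0.633  energy = 206.06  T1 events = 3180  polygon classes = {4: 4, 5: 26, 6: 21, 7: 7, 8: 3, 9: 3}
active - passive final energy: +8.59 (positive: the active shape is an out-of-equilibrium trap)
```

The passive shell keeps the pristine 12-pentagon packing and a compact
shape; junctional activity scrambles the packing, drives the reduced
volume far below the passive value (protrusions cost area) and leaves
the shell trapped above the passive energy — the signature of
activity-enabled branching.  The other scripts in `examples/` cover
spherical relaxation against the continuum theory, the
fluctuating-tension scheme, growth with division, and the morphometric
toolbox (pair correlations, anisometry, theory tables).

A thin CLI wraps the same library:

```
epishell seed --ncells 64 --seed 1 --out shell/
epishell simulate --alpha 0.7 --beta 0.5 --ncells 64 --kt1 200 --out run/
epishell analyze run/ --prefix final
epishell theory --alpha 1.2 --beta 1.2
epishell sweep --alphas 0.7,1.2 --betas 0.5,1.2 --ncells 64 --out sweep.csv
epishell grow --alpha 0.7 --beta 0.5 --n-start 100 --n-end 300 --out growth/
```

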