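# Methods

## The process and the two control architectures

Isopropanol (IPA) production in engineered *E. coli* competes with cell
growth for intracellular acetyl-CoA. Both modeled strains carry a
metabolic toggle switch (MTS): once flipped, it stops citrate-synthase
expression (halting TCA-cycle-driven growth) and switches flux into the
IPA pathway. The control problem is *when* to flip it — too early and the
culture is too small, too late and the medium is spent before the pathway
enzymes accumulate.

* **TA1415** (open loop): the MTS is flipped by adding IPTG at a chosen
  time. The process input is the addition time `t_add` (h); the normalized
  input `u(t)` steps 0 → 1 at `t_add`.
* **TA2445** (in-cell feedback): an AHL-based quorum-sensing circuit flips
  the MTS autonomously when cell density is high enough. The constant IPTG
  concentration `u` (mM), present from inoculation, tunes the circuit's
  sensitivity and is the process input.

## Model structure

Both strains use a three-compartment structured growth model: extracellular
resources `S` (dimensionless, pooling nutrients, waste accumulation and pH
shifts), active biomass `X_A` (RNA, ribosomes, precursors), inactive
biomass `X_G` (DNA, protein, membranes — proportional to measured OD600),
and IPA-pathway enzymes `E`; product `B` is the medium IPA concentration
(mM). Three mass-action reactions:

    v1 = k1 · S · (X_A + X_G + E) · (1 − (1 − r_leak)·u)
    v2 = k2 · X_A · (X_G + E)
    v3 = k3 · E/(E + K_E) · X_G

with balances dS/dt = −v1, dX_A/dt = v1 − v2, dX_G/dt = v2(1 − a_E·u),
dE/dt = v2·a_E·u, dB/dt = v3. The sum S + X_A + X_G + E is conserved
(exactly, by construction) at its initial value 1. `r_leak` is the promoter
leak that lets growth continue slowly after induction; `a_E` is the flux
fraction diverted to enzyme synthesis when the MTS is on. Observations are
y1 = N_m·X_G (OD600) and y2 = B.

For TA2445 the activation `u` is replaced by the promoter output

    z(A, u) = [A^n_A / (A^n_A + K_A^n_A)] · [u^n_u / (u^n_u + K_u^n_u)]

a product of Hill functions in AHL (`A`, nM) and IPTG (`u`, mM), and AHL
has its own balance dA/dt = k_A·X_G·z − d_A·A (positive feedback: the
sender device uses the same promoter). Units are native per species — A
against K_A in nM, u against K_u in mM — with no conversion inside the
equations; `0^n` at zero ligand is taken as its continuous limit 0.

Initial values: X_G(0) = 0.02 (TA1415) / 0.005 (TA2445), fitted X_A(0),
S(0) = 1 − X_A(0) − X_G(0), E = B = 0, A(0) = 0.01 nM; culture durations
69 h and 51.5 h. The default parameter sets in `hisicc.params` are the
published all-data fits. The two-column table they come from runs the k2
and k3 cells together; we read the TA2445 values as k2 = 1 /h and
k3 = 2 mM/h, the parse that reproduces the published optimal inputs
(9.3 h, 0.044 mM). The alternative reading (0.9089…1 → 0.9089 and 1,
1.2418…2 → 1.2418 and 2 swapped across strains) can be run by constructing
the model with those values; nothing is hard-coded.

## Numerics

Integration uses LSODA (`scipy.integrate.solve_ivp`) with rtol 1e-8 /
atol 1e-10 (configurable). The TA1415 step input is handled by splitting
the integration at `t_add`, so the solver never evaluates a discontinuous
right-hand side; `t_add ≥ duration` means "never induced" and is simulated,
not rejected. Output grids are evaluated through the solver's dense output.
Final yields are stable to ≥ 6 significant digits under tolerance
tightening and agree with an independent fixed-step RK4 re-integration at
dt = 1e-3 h to better than 4 significant digits (tested on random models).
Fitting uses a looser rtol (1e-7) since residuals only need resolving well
below measurement noise.

## Synthetic data

`hisicc.datasets` generates flask datasets with the study's design: five
input conditions per strain (t_add ∈ {0, 6, 9, 12, 15} h; u ∈ {0.01, 0.03,
0.05, 0.1, 1.0} mM), three flasks each, sampled every 3 h plus the
endpoint (~24 points/flask). Noise is mean-one lognormal multiplicative
with 5% CV per channel plus an additive Gaussian floor (SD 0.01 OD600 /
0.02 mM), then clipping at 0 — chosen to mimic OD/HPLC measurement
behavior; the source study reports no error model, so these levels are a
field-typical choice, configurable via `NoiseSpec`. The promoter grid
spans 1.5 decades either side of each dissociation constant (9 × 9 wells)
with proportional noise.

What the generator does **not** emulate: substrate-depletion slowdown of
IPA production late in culture (absent from the model family itself),
evaporation/sampling-volume loss, plate-reader artifacts, or
replicate-level batch effects (replicates are i.i.d. around the same
truth). Passing recovery and hold-out tests on these data therefore show
the estimation machinery is correct and the models identifiable under
realistic noise — not that the model family fits real flask data; the
published fits establish that separately.

## Estimation

The objective normalizes each residual by the per-flask, per-channel
maximum measurement and sums squares over channels, flasks and timepoints.
Minimization is trust-region-reflective bounded least squares
(`scipy.optimize.least_squares`), the same trust-region family as the
original toolbox fit, with per-parameter scaling `x_scale` set to the
start-point magnitudes (the published account names scaling factors but
not values). Bounds: rates positive and wide, r_leak and a_E in [0, 1],
X_A(0) ≤ 10·X_G(0). Default start strategy is seeded Latin-hypercube
multi-start (8 starts, log-spaced on positive axes) taking the best final
objective; recovery tests run single-start near the truth. The TA2445
protocol holds the Hill constants (K_A, K_u, n_A, n_u) fixed at their
dose-response fit and, by default, also k2 and k3 (their printed values
are round numbers suggesting they were pinned); the `free` argument runs
either protocol. Non-convergence is reported in the result, not raised.

The promoter Hill fit estimates log10 K_A, log10 K_u, n_A, n_u and a free
amplitude (fluorescence data carry arbitrary units; the amplitude is
discarded). Grids with fewer than two positive levels on either axis are
rejected as unidentifiable.

Identifiability, measured by recovery on synthetic data: noiseless fits
recover every free parameter to optimizer precision; at 5% noise k1, k2
and N_m come back within ~10%, while K_E, X_A(0) (and for TA2445 a_E) are
weakly identified (tens of percent) — they trade off against each other
through the early-culture lag and the enzyme saturation.

## Hold-out validation

One flask under the three middle input conditions is held out per round
(extreme conditions always stay in training, so validation stays inside
the input range): 9 rounds per strain, each refitting on the remaining 12
flasks and scoring the held-out flask with R² per channel — 18 R² values
per strain. Refits warm-start from the all-data fit for speed; a cold
multi-start mode exists. The generalization criterion is R² ≥ 0.5 for
every held-out flask and channel.

## Input optimization and the PMM experiment

The input optimum maximizes predicted final IPA over the feasible region
(0–15 h for TA1415; 0.01–1.0 mM, log-spaced, for TA2445) by exhaustive
sweep (150 / 100 points — enough to resolve the single-peaked curves)
followed by bounded scalar refinement (xatol 1e-4), derivative-free to
respect the step-input discontinuity.

The process-model-mismatch (PMM) experiment freezes each strain's input at
that optimum, then simulates a "plant" whose growth parameters are
k1* = r1·k1, k2* = r2·k2 over an 11 × 11 grid of ratios 0.5–1.5 (the grid
brackets the published figure's axes; range and density are configurable).
Only k1 and k2 are perturbed — they jointly set the growth rate — and a
ratio of exactly 1 reuses the controller model bit-for-bit. Yields are
reported normalized by IPA_opt, the matched-model yield. On the default
grid the quorum-sensing strain's normalized yield dominates the open-loop
strain's at every point of the faster-growth quadrant, and both strains
lose yield in the slower-growth quadrant.

Two known artifacts of the model family, reproduced deliberately rather
than corrected: because substrate depletion does not slow IPA synthesis,
(1) TA2445's surface can exceed 1 when growth is faster than predicted,
and (2) even TA1415's yield rises ~1% just beyond the matched point along
the k2* = k2 slice before the delayed induction costs real yield.

## Reproducibility

All stochastic steps take explicit seeds; the pipeline splits one global
seed into fixed per-stage substreams so rerunning or adding a stage never
shifts another stage's draws. Stage artifacts are CSVs with a provenance
header line (stage, strain, seed, config hash). Test-suite and acceptance
problem sizes (10 recovery seeds, 9 hold-out rounds per strain, 11 × 11
PMM grid, 150/100-point sweeps) are the package's default study
conditions.
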