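# Methods

## The neuron model behind the synthetic recordings

The current-clamp generator integrates a single-compartment
conductance-based membrane:

C dV/dt = I_inj − g_L(V−E_L) − g_Na m³h(V−E_Na) − g_K n⁴(V−E_K) − g_M z(V−E_K) + ξ

with Traub-Miles-style kinetics for the transient Na⁺ and
delayed-rectifier K⁺ gates (a voltage shift `vt` positions the spike
threshold) and one slow M-type K⁺ conductance (`adaptation_strength`,
gate z with a voltage-dependent time constant peaking at
`adaptation_tau_max`) that produces the afterhyperpolarization and
spike-frequency adaptation. ξ is Ornstein-Uhlenbeck membrane noise with
correlation time C/g_L and stationary SD `noise_sd`. This is
deliberately the smallest model that yields overshooting APs, AHPs,
adaptation, and a stable rheobase; it is calibration infrastructure for
the extractors, not a biophysical fit to any cell.

Units everywhere: mV, ms, pA, nS, pF, µm; sampling rates in kHz.

Integration is fixed-step forward Euler for V and exponential Euler for
the gates, with an internal sub-step of dt_out/⌈dt_out/0.01⌉ ≤ 10 µs
(5 sub-steps per sample at 20 kHz), decimated to the protocol sampling
rate. All step amplitudes of a protocol are integrated in lockstep
(state vectorized over sweeps); a numba-compiled kernel and a pure
numpy loop implement the same arithmetic, and agree to ~1e-8 over a
200 ms spiking trace. Fixed (preset, protocol, seed) gives bit-identical
traces within one code path. Non-finite state aborts with the offending
step amplitude named.

### Presets

| preset | g_L (nS) | g_Na | E_Na (mV) | g_K | g_M | vt | noise SD (mV) |
|---|---|---|---|---|---|---|---|
| mouse | 10 | 6 000 | 48.5 | 1 500 | 15 | −60 | 0.3 |
| naked_mole_rat | 10 | 12 000 | 80 | 1 600 | 12 | −60 | 0.3 |
| naked_mole_rat_young | 6 | 9 000 | 80 | 1 400 | 10 | −58 | 0.9 |
| naked_mole_rat_aged | 12 | 14 000 | 80 | 1 700 | 16 | −61 | 0.15 |

All share C = 150 pF, E_L = −70 mV, E_K = −90 mV,
adaptation_tau_max = 600–800 ms. The mouse preset puts AP peaks in the
+40–45 mV band; the naked-mole-rat presets put peaks just under +80 mV
and the 2×-rheobase rate inside 11–16 Hz for a 750 ms step. The age
variants encode the maturation trends the analysis layer is exercised
on — young: higher input resistance, larger membrane noise (hence
looser spike thresholds), weaker spike currents; aged: the converse.
These were calibrated once against the extractors' output bands and
then frozen; they are registry entries, not tunables of the analysis.

The rheobase search grid is a protocol parameter (default 25 pA steps
from 25 to 450 pA). The reported "2× rheobase" sweep requires an exact
protocol match (every multiple of the increment has a double on the
grid); a coarser grid systematically overshoots the physiological
doubling point and is flagged as non-exact.

## Voltage-clamp generator and PSC detector

Simulated synaptic traces are a baseline plus biexponential kernels
(rise/decay 0.5/5 ms excitatory, 1/10 ms inhibitory; peak-normalized)
at Poisson event times, log-normal amplitude magnitudes (median 20 pA
at a 60 mV reference driving force, σ_log = 0.4), scaled and signed by
the driving force (holding − reversal), plus white Gaussian recording
noise (2 pA SD). Ground truth records every injected event.

Detection correlates the median-subtracted trace with the template,
normalized by template energy so the filter output is in amplitude
units. Candidates are local extrema of either polarity exceeding
4× the MAD-derived SD of the filtered trace; a prominence floor at the
same threshold rejects noise bumps riding on the decay shoulder of a
large preceding event (without it, large events are double-counted);
deduplication uses a 5 ms minimum inter-event interval. Measured
operating characteristics at these defaults (100 seeds, 10 s traces,
5 Hz events at 5× the noise SD): ~98% recovery, detected rate within
2% of the generating rate, ~0.6 false positives per 10 s of pure noise.

## Reversal potentials and classification

E_GABA is the chloride Nernst potential of the recording solutions.
Free chloride counts only fully dissociating salts (NaCl, KCl, CaCl₂ —
HEPES, gluconate, EGTA, phosphate and sulfate salts contribute none):
pipette 10 mM, bath 130.5 mM, giving −65.6 mV at 23 °C. The
glutamatergic reversal is fixed at 0 mV by configuration (mixed-cation
convention) rather than computed. Temperature defaults to 23 °C (room
temperature midpoint) and is configurable.

Classification follows the experimental convention: at holdings above
both reversals (+40 mV) all synaptic currents are outward and outward
events are labelled inhibitory; below both (−80 mV) currents are inward
and inward events are labelled excitatory; between the reversals,
polarity decides. Events whose polarity contradicts every driving force
are labelled ambiguous. Note the asymmetry at −80 mV: the GABAergic
driving force is only ≈ −14 mV there, so small inhibitory events are
inward too and are subsumed into the excitatory-dominant record — the
classifier reports what the holding-potential convention can support,
not a per-event transmitter identity.

## Morphometry

The morphometric unit is the segment: a maximal unbranched path between
the soma, a branch point, or a terminal (Imaris-like filament
semantics; the edge from the soma to the first neurite node belongs to
the stem segment). "Maximal dendrite length" is read as the longest
soma-to-tip path length — not Euclidean reach and not the longest
single segment; this is the most common convention and is configurable
in the code. Axonal nodes (SWC type 2) are excluded from dendritic
summaries by default. Metrics are invariant under node re-indexing,
rigid isometries and collinear subdivision; zero-length edges are
collapsed with a warning.

The tree generator grows segments as ~10 µm internodes with a wandering
direction; branching is Bernoulli per segment with probability
1 − exp(−rate · length), capped at `max_depth` orders. The first
segment of each stem has deterministic length so degenerate
configurations stay exactly analyzable. Ground truth (total length,
segment count, longest path, max order) is accumulated from the actual
coordinates during growth, so the morphometry module must agree to
float round-off, and does (tested at 1e-6 µm).

The depth correlate uses Spearman rank correlation with an exact
permutation p-value for n ≤ 10 (chunked enumeration of all n!
orderings) and the large-sample approximation above.

## Statistics

Group summaries are mean ± sample SD (n−1) with n; missing feature
values are excluded before testing and never imputed as zeros. The
Mann-Whitney U uses midranks for ties. The two-sided p-value is exact —
P(min(U₁,U₂) ≤ min(u, n₁n₂−u)) over the full null distribution of rank
splits, computed by a rank-sum dynamic program — whenever the combined
sample is ≤ 20 and tie-free; otherwise a normal approximation with tie
and continuity corrections (identical to the standard asymptotic
formula to machine precision). The exact branch deliberately covers all
group sizes a 5–10-cells-per-group study can produce: a smaller cutoff
would silently push 8v8 or 9v9 comparisons onto the approximation,
whose continuity correction makes it measurably conservative there
(empirical type-I ≈ 0.034 at 8v8 versus ≈ 0.05 for the exact branch).
All-identical data returns p = 1. No multiplicity adjustment is applied
by default, matching the single-test-per-feature reporting style this
pipeline mirrors; Holm step-down is available behind a flag.

## Pipeline and reproducibility

The demo cohort is 3 age groups × 5 cells. Somatic depth is drawn
uniformly per cell and scales the leak conductance
(g_L′ = g_L·(1 − 0.4·(depth − 0.5))), so deeper cells have higher input
resistance — the positional-maturity covariate the depth correlation is
exercised on. Access-resistance sessions are synthesized per cell; one
cell per group drifts 25–35% and is discarded by the QC rule.
Every stochastic call derives a sub-seed (< 2³¹) from the run seed and
is logged in the manifest together with the config hash, output list
and per-stage runtimes; re-running an identical config reproduces every
table byte-identically. The full default cohort completes in well under
a minute on one CPU.

## Interpretation choices left open by the conventions

- "Delay to the first AP" is measured to the first AP's threshold
  (switchable to peak).
- "AHP decay time" is the peak→AHP-minimum interval, not a recovery
  time constant.
- The AHP search window for the last spike of a train is 100 ms past
  the peak or the end of the step, whichever comes first.
- Thresholds are reported on the sample grid (no sub-sample
  interpolation) for determinism; linear interpolation of the exact
  criterion crossing is available via a flag.
- Onset "kink" is operationalized as the least-squares slope of dV/dt
  vs V in a ±1 mV window at the threshold crossing, flagged at a
  10 ms⁻¹ cutoff; both are configurable. This is an interpretation: a
  kink is qualitative in the source convention.

## What the synthetic data does and does not show

The generators emulate regular-spiking trains with overshooting APs,
AHPs, adaptation, Poisson synaptic bombardment and branched trees of
controllable size — enough to validate every extractor against known
truth. They do not emulate electrode artifacts, bridge-balance errors,
channel stochasticity, dendritic filtering (the model is a single
compartment, so genuine axon-initial-segment "kink" onset dynamics are
absent and simulated onset rapidness stays below the kink cutoff),
correlated synaptic input, or reconstruction errors in real SWC files.
Passing tests therefore certify the analysis code, not the biology of
any particular recording. Cells are treated as independent observations
within groups (the design this mirrors pools cells across animals);
the statistics layer documents rather than corrects that nesting.

## Problem sizes used by the tests and the acceptance script

Unit and property tests run on single sweeps or small families
(typically ≤ 18 sweeps × 900 ms at 20 kHz), 100-250-seed Monte-Carlo
loops for detector and distributional checks, and 1000-replicate error
calibrations for the statistics layer; the acceptance script uses 10
seeded recordings per species preset. These sizes make the suite
complete in well under a minute of simulation time while leaving every
check at its stated statistical resolution.
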