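# Methods

`hfnet` measures directed phase-to-phase coupling within and across
frequencies in multichannel oscillatory recordings, builds hyper-frequency
networks (HFNs) from those couplings, characterizes their weighted-directed
topology and its dynamics, and quantifies stimulus-locked topology dynamics
with a small feed-forward classifier. This note documents the model, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Phase extraction

Signals are transformed with the analytic Morlet (Gabor) wavelet

    psi(t) = (sigma^2 pi)^(-1/4) exp(-t^2 / 2 sigma^2) exp(j 2 pi f t),

a unit-energy Gaussian envelope around the central frequency `f`. The
envelope SD follows a constant-cycles rule, `sigma = n_cycles / (2 pi f)`
with `n_cycles = 5` by default; a fixed `sigma` in seconds is available for
users who prefer constant temporal resolution across frequencies. The cycle
count is a genuine tunable: smaller values sharpen time resolution and
broaden frequency resolution. Results that depend on it are treated as
tunable, not as reproducible constants.

Coefficients are evaluated every `time_step` raw samples (5 at 250 Hz, i.e.
a 20-ms phase grid); the instantaneous phase is the complex argument wrapped
to (-pi, pi]. Kernels are truncated at 4 sigma and applied by
zero-padded convolution; phase samples whose kernel support crosses the
signal edge are flagged per frequency, and downstream sliding windows carry
a validity flag rather than being dropped, so the canonical 81-window grid
of a 10-s segment is always produced. Zero-magnitude coefficients have no
defined argument; they are emitted as phase 0 and flagged.

## Coupling indices

For channels X, Y at frequencies f_m, f_n with n f_m = m f_n (n = m = 1
within frequency), the generalized phase difference is
`dPhi = n Phi_X - m Phi_Y`, wrapped to (-pi, pi]. Five indices are computed
in sliding windows (2000 ms width, 100 ms step by default; 81 windows per
10-s segment):

* **PSI** — modulus of the window-averaged unit phasor of dPhi. Measures
  phase stability at *any* angle (anti-phase locking also scores 1).
* **Ternary code** — +1 for dPhi in (0, +pi/4), -1 for (-pi/4, 0), 0
  otherwise. Intervals are open: exact 0 and +-pi/4 code 0.
* **Cleaning** — maximal runs of consecutive nonzero codes strictly shorter
  than one oscillation period are recoded to 0, suppressing accidental
  synchronization. The comparison is strict (`duration < period`); a run of
  exactly one period survives. For cross-frequency pairs the period of the
  slower oscillation is used by default (`max`; `min` and `mean` are
  options). Cleaning runs on the full series before windowing.
* **PCI / NCI / ACI** — fractions of window samples coded +1, -1, and
  either; `ACI = PCI + NCI` exactly.
* **ICI** — `((PCI + ACI) / (2 ACI)) * PCI`, with `ICI = 0` when `ACI = 0`
  (continuity with the all-negative limit; avoids 0/0). ICI is 1 when every
  sample is locked positively and tends to 0 when all locked samples are
  negative, which makes it directional: the edge i -> j carries the ICI of
  dPhi(i, j), and `PCI(i->j) = NCI(j->i)` holds exactly.

## Network construction

HFN nodes are (electrode, frequency-of-interest) combinations ordered
frequency-major; with 58 channels and FOIs 2–20 Hz in 2-Hz steps this gives
580 nodes, within-frequency blocks on the diagonal, cross-frequency blocks
off it. Same-electrode cross-frequency pairs are included; self-pairs are
not (zero diagonal). The directed adjacency holds windowed ICI values and is
sparsified at a fixed threshold of 0.26, *keeping* the surviving weights
(all topology metrics are weighted). The threshold is validated, not fitted:
on noise recordings the bootstrap critical value of the mean surrogate
coupling (1000 resamples, alpha = 1e-4, percentile construction; a
normal-approximation mode exists) lies far below 0.26. Two surrogate
constructions are available: per-channel sample permutation and phase
shuffling (permutation of the positive-frequency phase spectrum with
conjugate symmetry), which preserves the amplitude spectrum exactly. ICI,
the quantity the networks are built from, is what enters the bootstrap.

## Topology metrics

On nonnegative weighted digraphs with weights in [0, 1]:

* strengths: `s_in(i) = sum_j w_ji`, `s_out(i) = sum_j w_ij`;
* clustering: Fagiolo's weighted-directed coefficient (cube-root weight
  products over all triangle orientations, normalized by
  `(k_in + k_out)(k_in + k_out - 1) - 2 k_bilateral`);
* distances: directed Dijkstra on edge lengths `1/w` (convention exposed;
  `1 - w` available). `cpl_i` averages over *reachable* targets and the
  number of unreachable ordered pairs is reported; `eglob_i` averages `1/d`
  with unreachable pairs contributing 0 — efficiency is the robust choice
  in disconnected graphs;
* local efficiency: weighted-directed neighborhood efficiency (cube-root
  weights, inverse neighbor-subgraph distances computed on cube-root
  lengths, normalized by the neighbor count with edge multiplicity).

Reference ensembles preserve node count, edge count and the weight multiset
exactly. The random reference repositions the weighted edges uniformly at
random over off-diagonal slots (the degree sequence is deliberately *not*
preserved; degree-preserving rewiring is not what the construction
describes). The lattice reference additionally sorts each column's weights
by descending size toward the diagonal. Two placements are offered: the
default orders positions by *circular* distance from the diagonal, so the
band wraps at the matrix corners and the result is a true ring lattice
(nearest-neighbor connectivity); `wrap=False` splits each column at the
diagonal element without wraparound, which leaves corner columns one-sided
and systematically lowers the reference clustering (~0.50 vs ~0.60 on a
100-node, k=6 ring fixture). The ring placement is the default because the
construction's purpose is a ring-topology null; the coefficients below are
sensitive to this choice. Ties between equal weights are broken by a stable
sort for determinism. Reference metrics are averaged over 10 realizations
by default.

Small-world coefficients, from graph-mean metrics:

    gamma = CC / CC_rand        lambda  = CPL / CPL_rand
    sigma = gamma / lambda      omega   = CPL_rand / CPL - CC / CC_latt
    sigma_E = (Eloc / Eloc_rand) / (Eglob_rand / Eglob)
    omega_E = Eglob / Eglob_rand - Eloc / Eloc_latt

sigma > 1 and omega near 0 indicate small-world structure; omega > 0 leans
random, omega < 0 leans lattice-like. On rewired-ring fixtures
(n=100, k=6, rewiring probability 0.1) sigma is ~5 and omega straddles 0
seed by seed (measured about -0.04 to +0.17, mean ~ +0.03): at that
rewiring rate the coefficient genuinely sits at the small-world boundary,
so only ensemble means, not single realizations, have a stable sign.

## Topology dynamics

Each nodal metric over the window sequence forms a nodes x windows matrix
(580 x 81 at full geometry). Row/column Pearson correlations give the nodal
(nodes x nodes) and temporal (windows x windows) similarity matrices;
zero-variance elements are excluded with a warning rather than erroring.
Modularity of any partition is always evaluated exactly as
`Q = (1/l) sum_ij (w_ij - k_i k_j / l) delta(m_i, m_j)` with the diagonal
zeroed; the single-module partition scores 0 by construction. The temporal
matrix is clipped to its positive part (clipped mass logged) and partitioned
by modularity optimization; the nodal matrix keeps its signs and is
partitioned with a two-layer signed objective in which positive weights
reward and negative weights penalize co-assignment (Louvain-family local
moving with Leiden refinement via igraph/leidenalg; 10 restarts, best-Q kept,
seeded). Temporal modules are *dynamic states* and nodal modules *node
communities*; both module-size extremes and, for states, contiguous-run
statistics are reported, since modularity does not force states to occupy
contiguous windows. Observed Q is compared against a null of matrices with
the off-diagonal similarity values permuted symmetrically (same size, value
multiset and symmetry; 100 draws by default).

## Stimulus-locked dynamics

Windows are labeled by the inter-stimulus interval (ISI) containing their
onset (ISIs indexed in temporal order; the last ISI extends to the segment
end; a window starting exactly at a stimulus belongs to the ISI beginning
there). The classifier is a three-layer tanh network (inputs = channels at
one FOI, 8 hidden units, one output per class), trained by full-batch
back-propagation on squared error with one-hot targets at +-1, learning rate
0.01, momentum 0.9, at most 500 epochs with early stopping on a loss
plateau; features are z-scored on the training split. The loss, learning
rate, epoch count and scaling are package choices exposed in `FNNConfig`;
none is claimed to reproduce an external setting. Splits are 75/25 at
random (61/20 for 81 windows), unstratified; splits missing a class in
training are re-drawn and counted. Accuracy is percent correct on held-out
windows, averaged over 100 repetitions.

Two statistical caveats of this protocol are worth stating plainly, because
the synthetic tests surface both. First, consecutive 2000-ms windows
stepped by 100 ms share 95 % of their samples, so any slowly varying
feature — even one unrelated to the stimuli — lets the network generalize
from a training window to its temporal neighbors and inflates accuracy far
above chance. Second, when features carry no information at all the trained
network degenerates to predicting the training-split majority class, whose
share of the *held-out* windows is depleted by sampling without
replacement; expected accuracy then falls a few points *below* the nominal
1/K. Chance-level behavior of this protocol is therefore the label-
permutation null of the protocol itself, not the binomial 1/K.

## Synthetic data

The generator emulates the default recording geometry (58 channels, 250 Hz, 10-s
segments; all knobs configurable, unit tests use 2–12 channels): sums of
sinusoidal oscillators with optional n:m phase locking
(`n Phi_A - m Phi_B = lag`, with optional smooth wrapped jitter on the lag
as the coupling-strength knob), additive white Gaussian noise at a stated
SNR, optional smooth phase diffusion for uncoupled oscillators, and oddball
schedules (ISIs uniform on 1.2–1.5 s, deviant probability 0.2). The
stimulus-locked fixture plants driver/follower pairs at one FOI whose
phase-lag *sign* follows a per-ISI Hadamard codeword, so edge direction
carries the class; `effect_size` mixes the locked component with an
unlocked alternative that drifts steadily (pairwise relative detuning
>= 0.8 Hz plus a mild phase walk). The steady drift is deliberate: it sweeps
the phase difference uniformly through the +-pi/4 locking band so that
unlocked pairs never hold a windowed ICI above the 0.26 threshold —
stationary lag jitter or a slowly hovering random walk instead leaves
above-threshold, time-autocorrelated edges that the classifier exploits
through window overlap. The schedule used for classification fixtures
places the first stimulus at the segment start so that six ISIs tile the
labeled window range with roughly equal class counts.

What passing tests show: the analytic constants of the pipeline, the index
algebra, oracle-exact graph metrics, calibrated small-world and surrogate
behavior, and end-to-end recovery of a planted, strongly locked effect
(mean CA ~ 91 % under the fixture's conditions: 6 pairs, SNR 20, full
effect). What they do not show: behavior on physiological signals — there
is no 1/f background, no volume conduction, no artifacts — nor classifier
performance at realistic effect sizes, nor chance-level accuracy of the
split protocol at exactly 1/K (see the caveats above; with the effect off
the measured accuracy is the majority-guessing level of ~11 %, below 1/K).

## Problem sizes in the test suite

Unit tests run on 2–12 channel fixtures, one or two FOIs, 10-s segments;
the metric-oracle battery uses digraphs of up to 10 nodes; small-world
calibration uses 100-node rings with 10 reference realizations; the
end-to-end classification fixture uses 6 pairs (12 channels) at one FOI
with 100 split repetitions. These sizes were chosen so the full suite
exercises every code path at comfortable speed while remaining statistically
decisive for the planted effects.
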