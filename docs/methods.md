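# Methods

`neurochip` treats a digital circuit as a model organism: a system whose
"connectome" (the transistor netlist), "spiking" (transistor conduction
transitions), and "behavior" (stimulus-driven output streams) are all fully
known, so that the standard analysis battery of systems neuroscience can be
scored against ground truth instead of intuition.  This note documents the
models, the conventions the field's descriptions leave open, and what the
synthetic fixtures do and do not establish about real data.

## Switch-level circuit model

A netlist contains wires and three-terminal enhancement-mode transistors; a
transistor conducts between its channel terminals `c1` and `c2` exactly when
its gate wire is high.  Depletion-mode pullup loads are modelled as a wire
attribute (`pullup=True`), not as devices: they are static loads that pull a
wire high whenever nothing conducts it to ground.  Layout coordinates are
abstract micrometres with the origin at the lower left; fixtures lay out
their functional modules on well-separated grid regions so that spatial
analyses (field potentials, component maps) are meaningful.

### Settling semantics

After each stimulus assignment the circuit relaxes to a fixed point by
synchronous passes.  Each pass (i) recomputes conduction states from the
current wire values (lesions override), (ii) partitions wires into groups —
connected components through conducting channels — and (iii) assigns each
group one value by source precedence:

1. contains the ground rail → low (ground dominates power, so accidental
   shorts resolve deterministically and are logged);
2. contains the power rail → high;
3. contains an externally driven input wire → the driven value, with high
   winning if differently driven inputs are shorted together.  This clause
   is needed as soon as a pass transistor channels directly to an input
   (e.g. a shift register's data pin);
4. contains a pullup wire → high;
5. contained a member that was high on the previous pass → high
   (charge retention — this is what makes dynamic pass-transistor latches
   hold state);
6. otherwise low.

Iteration stops when no wire changes; exceeding the cap of
`100 × n_wires` passes raises an "unstable" error naming the oscillating
wires rather than silently truncating.  Free-running oscillators are
therefore unsupported by construction; all periodic activity in the
fixtures is clock-derived, which still reproduces region-specific rhythms
with exactly known frequencies.  One timestep = one stimulus assignment
followed by settling; the initial state is all-low (power high), and every
clocked fixture begins with a two-step reset prefix in which both clock
phases are held low so that no latch samples the power-up transient.

The production `resolve` is a vectorized implementation of exactly these
passes (sparse connected components per pass); the test suite checks it
against an independently written plain-Python implementation of the same
declared semantics on hundreds of random circuits.

### Lesions

`stuck_on` forces a transistor to conduct permanently — the in-silico
version of tying its gate high — and is the default screening mode;
`stuck_off` (severing the device) is provided as an extension.  The lesion
screen simulates each behavior's stimulus prefix under each single-transistor
lesion and asks whether the success predicate (does the expected output
stream prefix still appear — the analogue of "does the game still draw its
first frame") holds; a lesioned circuit that fails to settle counts as a
behavioral failure.

## Spiking conventions

A spike is the off→on transition of a transistor's *conduction state*;
analysing wire voltages instead would be the analogue of intracellular
recording.  "Switching" for field-potential purposes counts both edges
(off→on and on→off), which matters: a symmetric square wave of state period
P produces switching events with period P/2 but spikes with period P.
Binned counts conserve the total event count; a trailing partial bin is
dropped with a log message.  Z-scoring uses the population (1/N) variance
convention, and constant rows map to all zeros — both choices are
conventions, stated here because nothing in the data forces them.

## Tuning curves

The stimulus is the fixture's scalar output-bus value (the luminance
analogue).  A unit's rate is its trailing 100-timestep event count, and the
tuning curve is the occupancy-normalized mean rate per stimulus value.
Classification is deliberately algorithmic where human judgement is often
used: least-squares fit of a Gaussian plus baseline, *simple* if R² ≥ 0.8
with an interior peak, else *complex* if the stimulus explains ≥ 10% of
rate variance (η² ≥ 0.1), else *untuned*.  The two thresholds are
configuration parameters with no empirical derivation; the planted-tuning
generator is the oracle that shows the defaults behave sensibly.

## Spike words and the shuffle control

Spike words are binary population vectors per time bin over a unit subset
(default: the 64 units whose mean rates are nearest the population mean,
ties broken by unit id).  The shuffle control applies an independent uniform
circular time shift per unit — preserving each unit's marginal count and
autocorrelation exactly while destroying cross-unit alignment; per-bin label
permutation is available as an alternative.  For independent units the raw
and shuffled word-weight histograms agree to sampling error
(total-variation distance < 0.02 at 10⁴ bins); a common driver pushes the
divergence far above that.

## Field potentials and spectra

An LFP channel is the Gaussian-weighted (σ = 500 µm) sum of switching
events around a recording point, low-passed with a centered width-4 boxcar
(edge windows truncated).  The boxcar has exact spectral nulls at 0.25 and
0.5 cycles/timestep, so rhythms at those frequencies vanish from the
filtered channel — a concrete reminder that preprocessing shapes which
"oscillations" are observable.  Spectra use Welch's method: 256-sample
segments, Hann window, no overlap, constant detrend.  Frequencies are in
cycles/timestep (Nyquist 0.5); a user-supplied clock rate converts them to
physical units.

## Conditional Granger causality

Channels are segmented into equal non-overlapping trials (default 100).
VAR models are least-squares fits with lagged regressors stacked across
trials, so no lag crosses a trial boundary; the residual covariance is the
pooled maximum-likelihood estimate.  Model order is chosen by
`BIC(p) = ln det Σ_p + ln(N)·p·m²/N` with argmin as the default rule; the
"plateau" rule (smallest order within a stated tolerance of the minimum,
default 1% of the BIC range) is available because plateau judgements are
otherwise irreproducible.  Conditional GC from X to Y given Z is
`ln(σ²_reduced / σ²_full)` for Y's equation, clipped at zero.

Edge significance uses a trial-permutation null — the source channel's
trials are permuted relative to all others — with Bonferroni correction
within a behavior.  The permutation loop uses the Frisch–Waugh projection
(QR-factor the reduced design once, regress the projected source block per
permutation), which is algebraically identical to refitting the full model.
Note the resolution limit: with N permutations the smallest achievable
p-value is 1/(N+1), so the permutation count must exceed
(number of tests)/α for any edge to reach Bonferroni significance; the
graph routine warns when it cannot.  In the bivariate system
y_t = 0.9·x_{t−1} + ε with unit-variance white inputs the forward magnitude
is ln(1.81) ≈ 0.593 in closed form, which the implementation reproduces.

Deterministic clock-driven channels make lagged designs exactly collinear;
the end-to-end pipeline therefore adds 5% seeded Gaussian sensor noise to
LFP channels before VAR fitting, as any physical recording would contain.
Rank-deficient candidate orders score BIC = ∞ during order selection.

## Non-negative matrix factorization

The whole-circuit activity matrix is the binary transistor-state record
(units × timesteps): each row is a transistor's conduction state over time,
which is inherently non-negative.  (Binned switching counts are also
accepted; z-scored data are rejected with an error.)  Factorization
minimizes ‖X − WH‖²_F by multiplicative updates — monotone non-increasing
by construction — from an NNDSVDa initialization; a fixed seed yields
identical factors.  Components are interpreted by signed Pearson
correlation of H rows against the registry's known signals, and units map
to their dominant component (argmax of the W row).  Recovery is scored
after Hungarian matching on absolute correlations, which absorbs NMF's
permutation and scale ambiguity.  Planted-factor recovery above r = 0.95
is demonstrated for well-separated (identifiable) factors; strongly
correlated planted time courses are not identifiable by any factorization
and are not claimed.

## Connectomic block model

The wiring graph is expressed as six binary relations over transistors, one
per ordered terminal pair (G→C1, G→C2, C1→C2, C2→C1, C1→G, C2→G): an edge
means the two terminals share a wire.  Power and ground are excluded — they
touch nearly everything and would swamp the signal topology; a terminal
pulled to a rail is instead captured by the wire's role/pullup flags.  The
model is a deliberate simplification of nonparametric distance-dependent
block modelling: fixed K, one shared assignment across the six relations,
Beta(1,1)–Bernoulli edge probabilities per (relation, block pair), and a
symmetric Dirichlet(1) size prior, inferred by collapsed Gibbs sampling.
Because the posterior over partitions is sharply peaked, single chains can
lock into merged or split configurations; the fitter runs several restarts
(default 8) and returns the best-posterior labelling visited, which by
construction never falls below the initialization's posterior.  The
distance-decay factor of the full model is not implemented.

## Synthetic fixtures: what they emulate, and what they don't

All fixtures are two-phase clocked NMOS circuits (one cycle = two
timesteps: phase 0 samples into first latch stages, phase 1 transfers), with
module annotations, named control signals, spatially separated regions, and
behaviors whose expected outputs come from independent clock-level
behavioral models — the registry self-check compares the switch-level
simulation against that model at build time and aborts on any mismatch.

* `adder4` — combinational 4-bit ripple-carry adder (74 transistors,
  9-NAND full adders); the scalar output is the 5-bit sum, so the
  exhaustive behavior's expected stream is literally a + b.
* `shiftreg8` — 8 dynamic two-phase latch stages; tests charge retention
  and pipeline delay.
* `counter3_decoder` — 3-bit synchronous counter (bit state periods 2, 4, 8
  cycles = 4, 8, 16 timesteps) plus a one-hot decoder, each counter bit in
  its own layout region 5 mm apart, giving region-specific rhythms of known
  frequency.
* `microfsm` — a 199-transistor accumulator machine: 3-bit program counter,
  one-hot decoder, ripple adder, accumulator, output register.  The
  counter's top bit is buffered as a read/write-style control line `RW`
  (period 16 timesteps), gating the machine between fetch cycles (the
  accumulator adds the 4-bit input bus mod 16) and write cycles (the output
  register latches the accumulator).  Three behaviors (`hold`, `ramp`,
  `toggle`, 1024 cycles each) drive distinct input programs.  Registers
  gated by a control line sample through two *series* pass transistors —
  data → enable gate → clock gate → storage — because a derived ANDed clock
  wire decays two relaxation passes after the clock phase falls and can
  capture the transfer-phase transient (the registry self-check caught
  exactly this failure mode during development).

Because every transistor's conduction state equals its gate wire's value,
the state matrix contains exact duplicates of the clock and control traces
in the units they gate; NMF on the microfsm reliably dedicates components
to the clock phases and the RW line (|r| > 0.9), reproducing on known
ground truth the finding that population components track global control
signals.  That is also the fixtures' main limitation: they are small, fully
deterministic, noiseless, and perfectly observed.  Passing this battery
shows an analysis implementation is *correct and calibrated against known
truth*; it does not show the analysis will be informative on noisy,
stochastic, partially observed biological recordings.

## Problem sizes and numerical choices

Default study sizes were chosen so the whole battery runs comfortably on a
single CPU: microfsm traces of 2 050 timesteps, 100 trials for VAR
analyses, 10⁴ bins for spike words, 200 random 12-transistor circuits for
the settling cross-check, 20 seeded repetitions for stochastic recovery
rates, 1 000 permutations (500 where only a 0.01-level decision on a single
pre-specified pair is needed).  Numerical guards: multiplicative-update
denominators floored at 1e-12; Gaussian tuning fits bounded (non-negative
amplitude, width ≤ 10× the stimulus span) with the highest-rate stimulus as
the initial peak; BIC of a non-positive-definite residual covariance is ∞;
GC magnitudes are clipped at zero.  Ties in unit selection break toward
lower unit ids; all stochastic stages consume named substreams spawned from
one global seed, so stages can be rerun independently and identically.
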