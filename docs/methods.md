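# Model and methods

## The model

Two Potts attractor networks are coupled in one direction. Each unit stands
for a patch of cortex with `S = 7` local active states plus a quiescent
state; its activation is a softmax over the `S+1` options,

    sigma_ik = exp(beta r_ik) / ( sum_l exp(beta r_il) + exp(beta (theta_i0 + U_eff)) ),

so every unit's activation lives on the simplex. Memories `xi^mu` (random
assignments of active states to a fraction `a = 0.25` of units, exact count)
are stored once in a simil-Hebbian tensor on a diluted connectivity of `C_m`
inputs per unit,

    J_ij^kl = c_ij / (C_m a (1 - a/S)) * sum_mu (d(xi_i^mu,k) - a/S)(d(xi_j^mu,l) - a/S).

The **lexicon network** (N=600, C_m=90, w=0.45, tau2=33.3) stores 200 word
forms; a brief external cue retrieves one of them. The **buffer network**
(N=200, C_m=150, w=0.5) stores 200 candidate syllables; heteroassociative
couplings (C_het=150 inputs per buffer unit) built from an instruction matrix
`G` convey each word's three syllables with the graded cascade
`G = 1.0 / 0.9 / 0.8` for first/second/third position, scaled by a coupling
gain `lambda` and read from the lexicon's activations (a sigma-sigma
interaction). The buffer must convert this *constant, parallel* drive into a
*temporal sequence* — the core operation modelled here.

Four mechanisms shape the buffer's dynamics (explicit Euler, `dt = 0.5`,
time in units of one network update; tau1 = 3.33 for the inputs):

* **dual-timescale adaptation** — state-specific thresholds theta_ik split
  into a fast (tau = 11.1) and a slow (tau = 33.3) component, mixed by
  gamma2_fast = 0.5; the fast part terminates the current syllable, the slow
  part keeps already-uttered syllables suppressed (repetition control);
* **fast local inhibition** — a unit-level threshold theta_A tracking the
  unit's total activity with tau_A = 2 and weight gamma_A = 0.3;
* **slow local inhibition** — theta_B integrating the complementary weight
  (1 - gamma_A) with tau_B = 106 updates; at this timescale it acts as a
  tonic activity-tracking floor (see "Numerical choices");
* **a dynamic global threshold** U_hat driven by the buffer's total active
  fraction (tau = tau_A), added to the constant U = 0.1. While a syllable is
  retrieved U_hat rises enough to suppress every competitor (winner-take-all);
  when adaptation extinguishes the syllable U_hat collapses within a few
  updates and the next-most-driven syllable ignites. This cycle is the
  serializer.

A trial cues one word, co-simulates both networks to `T_max = 500` (with
early stopping once both networks are quiet), extracts utterances from the
overlap trajectories by hysteresis (open at 0.5 while the maximal pattern,
close at 0.35, minimum duration 10 units), and classifies the first three
utterances into one of five mutually exclusive categories: correct, wrong
order (transposition), repetition (perseveration), shorter sequence
(omission), wrong syllable (insertion). Production beyond the third
utterance is recorded as a diagnostic, not an error.

The **sign buffer** variant splits the 201 buffer units into three clusters
of 67 (handshape / movement / location). Gesture elements are stored inside
one cluster each (31 of 67 units active); syllables are distributed
(51 of 201). Signs receive flat instruction values (G = 1 on all three
elements) with a stronger gain lambda_sign, the dynamic threshold becomes
cluster-wise, and adaptation is heterogeneous: gamma2_fast(i,k) is 0 where
only sign elements recruit the pair (signs are sustained, not latched
through), 0.5 n_syll/(n_sign+n_syll) where both classes do, 0.5 elsewhere;
the inverse adaptation timescales are drawn per (unit, state) from normal
distributions centred on 0.09 and 0.03 with SD 0.0075, truncated positive.
A sign counts as retrieved when all three element activities exceed 0.5
simultaneously for at least 50 units while each dominates its cluster.

## Synthetic inputs

All inputs are generated internally: uncorrelated Potts patterns with
exact-count sparsity, a 50-word lexicon in which every syllable appears in
exactly three words, once per serial position (three random permutations,
resampled until no word repeats a syllable), and a mixed lexicon of 25 signs
(one element per cluster, sampled without replacement from the 125
combinations) and 25 words (ordered triples of distinct syllables from a
pool of 15). These are the study conditions; they emulate none of the
statistical structure of real phonologies (no phonotactics, no frequency
effects, no correlated patterns), so passing tests speak to the network
mechanism, not to fits of human data.

## Numerical and design choices

* **dt = 0.5.** At dt = 1 the dynamic-threshold loop (tau = 2) rings with a
  period-2 Euler oscillation; at 0.5 trajectories are smooth and halving dt
  again changes the retrieval trajectory by well under 5%. All tau values
  keep their update-unit readings.
* **Initial state.** sigma_i0 = 1 - 1e-3 with the inputs r set at the level
  that actually produces that quiescent activation under the softmax
  (r0 = U + ln(eps/S)/beta, approximately); starting from r = 0 emits a
  network-wide activity burst on the first update that spuriously adapts the
  buffer exactly when the cue arrives.
* **Slow inhibition tau_B = 106 updates** for the production networks. Read
  literally from the parameter listing, this also agrees with the stated
  biological hierarchy (tau_B of order one second, with one update of order
  3 ms). The alternative reading (10^6, i.e. theta_B frozen at zero) leaves
  the lexicon network with no unit-level inhibition whatsoever; it then
  condenses into a glassy high-activity state and cannot hold a word for more
  than ~1 tau2 — verified by simulation. The free-latching profile keeps
  10^6, where freezing the slow component is explicitly the point.
* **Dynamic-threshold gain.** The drive of U_hat is Sigma_i(1-sigma_i0)
  divided by `a_U * N_scope`, with a_U a profile parameter. The printed form
  corresponds to a_U = a = 0.25, which puts the buffer's resting threshold
  (U + U_hat ~ 0.36) above any printed-scale cascade drive: no syllable can
  ever ignite. a_U = 1 makes the retrieval-time threshold too weak to
  terminate a syllable. The production profiles use a_U = 0.5, which yields
  a resting U + U_hat of about 0.21 — matching the published thermal-state
  value (0.216) quoted for the static-threshold ablation — together with
  deep suppression of competitors during retrieval and ~20-unit utterances.
* **Coupling gain.** lambda_word = 0.55. The printed 0.2 produces a cascade
  drive (~0.19) below the buffer's resting threshold under this
  implementation's (brute-force-verified) storage normalization, so the full
  model would produce no utterances at all. The gain was calibrated inside
  the mechanistic window bounded below by reliable first-syllable ignition
  and above by the return of perseverations (0.45-0.6 at a_U = 0.5).
  lambda_sign keeps its printed value 1.4 (signs need roughly 2.5x the word
  gain for full simultaneous activation, which is the published rationale
  for a larger sign gain).
* **Cue protocol.** An additive field of strength 4.0 on the cued word's
  (unit, state) pairs for 100 units. The word attractor survives its own
  adaptation only ~1 tau2 beyond cue offset, and three ~25-unit buffer
  cycles must fit inside the word's active window, as the 3:1 ratio between
  lexicon and buffer adaptation timescales is designed to allow.
* **Extraction thresholds** 0.5/0.35 with 10-unit minimum duration;
  classifications are invariant to the opening threshold across 0.45-0.6 on
  reference traces.
* **Overlap normalization** uses each pattern's own active-unit count, so a
  perfectly retrieved cluster pattern (31 active units) also reads m = 1.
* **Seeding.** One master seed fans out to named RNG streams per concern
  (patterns, connectivity, lexicon, timescales) and per batch, so changing
  the batch count never perturbs earlier batches.

## Problem sizes

The batch protocol is 3 batches x 50 cued words (150 trials), each batch
with fresh patterns, connectivity and lexicon; trials of a batch share
weights and are integrated as one vectorized sweep. The test suite reuses
session-scoped batch results and runs reduced scans (N = 400 for the
free-latching sweep, 8-10 trajectories per condition).

## Known limitations

* With every printed parameter in place, the published operating point could
  not be reproduced exactly: the implementation needs a roughly 2.5x larger
  word-coupling gain before the buffer ignites at all, and at that gain the
  error mix shifts. The full model reaches ~60-65% correct sequences
  (published: ~72%) with transpositions the dominant error (as published).
  The intermediate (constant-threshold) model scores lower than published
  (~25% vs ~55%), with perseverations its dominant error, and removing fast
  local inhibition barely degrades production here (the slow inhibition
  keeps serializing), where the publication reports omissions dominating.
  These residuals are consistent with the source operating in a regime where
  the cascade drive sits within a few hundredths of the resting threshold —
  a regime this implementation's storage and threshold normalizations place
  out of reach of the printed gain; the discrepancy is documented rather
  than hidden by per-statistic re-tuning.
* The serial-position profile of first errors peaks at position 2 here
  (second-versus-third syllable races), rather than increasing monotonically
  to position 3.
* Euler integration with synchronous updates; no spiking, no learning
  dynamics, no feedback from buffer to lexicon, no phonotactics.
* At the calibrated coupling gain, an idle buffer coupled to a resting
  lexicon can eventually retrieve its most favourably wired pattern
  spontaneously (the lexicon's resting activity leaks a weak field through
  the couplings). Cued production is unaffected, and a fully decoupled
  buffer stays in the null state.
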