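# pottsbuffer

A Potts attractor-network model of the phonological output buffer — the
working-memory stage that turns a stored word form into an ordered sequence
of phonological units — and of its sign-language counterpart, where the three
components of a sign (handshape, movement, location) must instead be produced
simultaneously. The package is aimed at computational neuroscientists and
neurolinguists who want to simulate, perturb, and score this two-network
model: it reproduces the production experiments (batches of cued words scored
against an aphasiological error taxonomy), the component ablations, and the
mixed sign/word buffer.

## The model in brief

Two networks of Potts units (cortical patches with `S` active states and a
quiescent state, activation given by a softmax over states) are coupled one
way. Memories are stored in simil-Hebbian tensor weights on diluted
connectivity,

    J_ij^kl ∝ (1 / C_m a (1−a/S)) Σ_μ (δ_{ξ_i^μ,k} − a/S)(δ_{ξ_j^μ,l} − a/S),

and retrieval is measured by the overlap order parameter `m^μ`. A cued word
in the lexicon network drives its three syllables in the buffer network
through heteroassociative couplings with the graded instruction cascade
`G = 1.0 / 0.9 / 0.8`. The buffer serializes this constant parallel drive by
latching: firing-rate adaptation on two timescales (τ₂ = 11.1 and 33.3),
fast and slow local inhibition (τ_A = 2, τ_B), and an activity-dependent
global threshold `U(t) = U + Û(t)` that enforces winner-take-all competition
and cycles the buffer from one syllable to the next. Each trial's utterance
sequence is read off the overlap trajectories and classified as correct,
wrong order (transposition), repetition (perseveration), shorter sequence
(omission), or wrong syllable (insertion).

See `docs/methods.md` for the full model description, parameter table
rationale, and known limitations.

## Worked example

Cue item 0 of a freshly generated 50-word lexicon in the full model and look
at what the buffer produces:

```python
from pottsbuffer import load_profile, run_production

record = run_production(load_profile("pob_step4"), item_index=0, seed=1)
print(record.target)
print([(u.pattern_id, u.onset, u.offset, round(u.peak_overlap, 2))
       for u in record.utterances])
print(record.label)
```

prints (times in integration steps of 0.5 update-units):

```
(117, 160, 108)
[(117, 9, 75, 0.99), (160, 81, 132, 0.99), (108, 136, 177, 0.95), (117, 182, 216, 0.98)]
ErrorLabel(category='correct', first_error_position=None)
```

The buffer produced the word's three syllables (buffer patterns 117, 160,
108) in the instructed order as three clean, non-overlapping retrieval
episodes of near-unit overlap — a correct trial — and then, with the word
still active in the lexicon, started the sequence again (the fourth episode),
which is tracked as a diagnostic rather than an error. The same workflow runs
from the shell:

```
pottsbuffer batch  --profile pob_step4 --seed 1 --out runs   # 3x50 cued words
pottsbuffer ablate --profile pob_step4 --flag no_slow_adaptation --seed 1 --out runs
pottsbuffer sob    --seed 1 --out runs                       # 25 signs + 25 words
pottsbuffer phase  --loads 50,90,200 --n-units 400 --out runs
```

`batch` writes an error-distribution table (category, percent, SEM,
first-error-position breakdown), per-trial labels, and a JSON summary whose
numbers are bitwise reproducible from the same seed.

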