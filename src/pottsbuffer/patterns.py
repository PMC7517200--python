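"""Random Potts memory patterns and the structured lexica built on top of them.

A memory pattern assigns to each of the ``N`` Potts units either the quiescent
state 0 or one of ``S`` active states.  Word/syllable patterns are distributed
over the whole network with exact-count sparsity ``a`` (exactly ``round(a*N)``
active units per pattern, uniform states); gesture-element patterns live inside
one of several non-overlapping unit clusters and are quiescent elsewhere.

Composite items (spoken words, signs) are described by a :class:`Lexicon`:
each item points to one pattern in the lexicon network and to three component
patterns in the buffer network, together with the instruction matrix ``G``
whose graded entries (1.0/0.9/0.8 for the three syllables of a word, 1.0 for
each simultaneous element of a sign) drive the heteroassociative coupling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Literal

import numpy as np

__all__ = [
    "PatternSet",
    "LexiconItem",
    "Lexicon",
    "generate_random_patterns",
    "generate_cluster_patterns",
    "build_word_lexicon",
    "compose_mixed_lexicon",
]

# Cascade of instruction strengths for the 1st/2nd/3rd syllable of a word.
WORD_CASCADE = (1.0, 0.9, 0.8)


@dataclass
class PatternSet:
    """Integer state assignments for ``p`` memories over ``N`` units."""

    states: np.ndarray  # (p, N) int, entries in {0, .., S}
    S: int
    a: float
    cluster_bounds: list[tuple[int, int]] | None = None

    @property
    def p(self) -> int:
        return int(self.states.shape[0])

    @property
    def N(self) -> int:
        return int(self.states.shape[1])

    def active_counts(self) -> np.ndarray:
        return (self.states > 0).sum(axis=1)

    def to_json(self) -> str:
        payload = {
            "S": self.S,
            "a": self.a,
            "cluster_bounds": self.cluster_bounds,
            "states": self.states.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PatternSet":
        d = json.loads(text)
        bounds = d["cluster_bounds"]
        return cls(
            states=np.asarray(d["states"], dtype=np.int64),
            S=int(d["S"]),
            a=float(d["a"]),
            cluster_bounds=[tuple(b) for b in bounds] if bounds else None,
        )


@dataclass
class LexiconItem:
    item_kind: Literal["word", "sign"]
    lexicon_pattern: int
    component_ids: tuple[int, int, int]
    mode: Literal["sequential", "simultaneous"]


@dataclass
class Lexicon:
    """Composite items plus the instruction matrix G [p_lexicon x p_buffer]."""

    items: list[LexiconItem]
    G: np.ndarray
    lambda_by_kind: dict[str, float] = field(
        default_factory=lambda: {"word": 0.2, "sign": 1.4}
    )

    def __len__(self) -> int:
        return len(self.items)

    def component_ids(self) -> np.ndarray:
        return np.array([it.component_ids for it in self.items], dtype=np.int64)

    def to_json(self) -> str:
        payload = {
            "lambda_by_kind": self.lambda_by_kind,
            "G_shape": list(self.G.shape),
            "items": [
                {
                    "item_kind": it.item_kind,
                    "lexicon_pattern": it.lexicon_pattern,
                    "component_ids": list(it.component_ids),
                    "mode": it.mode,
                }
                for it in self.items
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Lexicon":
        d = json.loads(text)
        items = [
            LexiconItem(
                item_kind=rec["item_kind"],
                lexicon_pattern=int(rec["lexicon_pattern"]),
                component_ids=tuple(rec["component_ids"]),
                mode=rec["mode"],
            )
            for rec in d["items"]
        ]
        lex = cls(items=items, G=np.zeros(tuple(d["G_shape"])),
                  lambda_by_kind=d["lambda_by_kind"])
        _fill_G(lex)
        return lex


def _fill_G(lex: Lexicon) -> None:
    """(Re)build G from the item records (G is fully determined by them)."""
    lex.G[:] = 0.0
    for it in lex.items:
        if it.item_kind == "word":
            for pos, comp in enumerate(it.component_ids):
                lex.G[it.lexicon_pattern, comp] = WORD_CASCADE[pos]
        else:
            for comp in it.component_ids:
                lex.G[it.lexicon_pattern, comp] = 1.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_random_patterns(
    N: int, S: int, a: float, p: int, seed=None
) -> PatternSet:
    """Draw ``p`` uncorrelated patterns with exact-count sparsity.

    Each pattern activates exactly ``round(a*N)`` units (chosen uniformly
    without replacement) and assigns each an independent uniform state in
    ``{1, .., S}``.
    """
    if not (0.0 < a <= 1.0):
        raise ValueError(f"sparsity a must be in (0, 1], got {a}")
    n_active = int(round(a * N))
    if N < 1 or n_active < 1:
        raise ValueError(f"round(a*N) must be >= 1 (N={N}, a={a})")
    rng = _as_rng(seed)
    states = np.zeros((p, N), dtype=np.int64)
    for mu in range(p):
        active = rng.choice(N, size=n_active, replace=False)
        states[mu, active] = rng.integers(1, S + 1, size=n_active)
    return PatternSet(states=states, S=S, a=a)


def generate_cluster_patterns(
    N: int, n_clusters: int, a_sign: float, n_elements: int, S: int = 7, seed=None
) -> PatternSet:
    """Gesture-element patterns confined each to one unit cluster.

    The network is split into ``n_clusters`` equal contiguous ranges; elements
    are dealt round-robin so they are equally divided among clusters.  Inside
    its cluster an element activates exactly ``round(a_sign * cluster_size)``
    units and is quiescent everywhere else.
    """
    if N % n_clusters != 0:
        raise ValueError(f"N={N} not divisible into {n_clusters} equal clusters")
    if n_elements % n_clusters != 0:
        raise ValueError(
            f"n_elements={n_elements} not divisible among {n_clusters} clusters"
        )
    size = N // n_clusters
    bounds = [(c * size, (c + 1) * size) for c in range(n_clusters)]
    n_active = int(round(a_sign * size))
    rng = _as_rng(seed)
    states = np.zeros((n_elements, N), dtype=np.int64)
    per_cluster = n_elements // n_clusters
    for e in range(n_elements):
        lo, hi = bounds[e // per_cluster]
        active = lo + rng.choice(size, size=n_active, replace=False)
        states[e, active] = rng.integers(1, S + 1, size=n_active)
    return PatternSet(states=states, S=S, a=a_sign, cluster_bounds=bounds)


def build_word_lexicon(
    n_words: int,
    lexicon_patterns: PatternSet,
    buffer_patterns: PatternSet,
    seed=None,
    enforce_balance: bool = True,
) -> Lexicon:
    """Assign three ordered syllables to each word under positional balance.

    In the balanced design ``n_words`` syllables are used, each appearing in
    exactly three words, once per serial position.  The assignment is built
    from three independent random permutations of the syllable indices (one
    per position), resampled until no word repeats a syllable internally.
    """
    rng = _as_rng(seed)
    if enforce_balance:
        if n_words < 3:
            raise ValueError("balanced design needs n_words >= 3")
        n_sylls = n_words
        for _ in range(10_000):
            perms = [rng.permutation(n_words) for _ in range(3)]
            triples = np.stack(perms, axis=1)
            if all(len(set(t)) == 3 for t in triples):
                break
        else:  # pragma: no cover - probability of failure is astronomically small
            raise RuntimeError("could not satisfy the positional balance constraint")
    else:
        # small unconstrained lexicon: a pool of 3 syllables per word
        n_sylls = 3 * n_words
        triples = np.array(
            [rng.choice(n_sylls, size=3, replace=False) for _ in range(n_words)]
        )

    if buffer_patterns.p < n_sylls:
        raise ValueError("buffer stores fewer patterns than syllables required")
    if lexicon_patterns.p < n_words:
        raise ValueError("lexicon stores fewer patterns than words required")
    # the syllables (and word forms) occupy a random subset of the stored
    # patterns; the remaining stored patterns act as distractor memories
    syll_ids = rng.choice(buffer_patterns.p, size=n_sylls, replace=False)
    word_ids = rng.choice(lexicon_patterns.p, size=n_words, replace=False)

    items = []
    for word in range(n_words):
        comps = tuple(int(syll_ids[c]) for c in triples[word])
        items.append(
            LexiconItem(
                item_kind="word",
                lexicon_pattern=int(word_ids[word]),
                component_ids=comps,
                mode="sequential",
            )
        )
    lex = Lexicon(items=items, G=np.zeros((lexicon_patterns.p, buffer_patterns.p)))
    _fill_G(lex)
    return lex


def compose_mixed_lexicon(
    gestures: PatternSet,
    syllables_offset: int,
    n_syllables: int,
    lexicon_patterns: PatternSet,
    buffer_p: int,
    n_signs: int,
    n_words: int,
    seed=None,
    lambda_word: float = 0.2,
    lambda_sign: float = 1.4,
) -> Lexicon:
    """Mix signs (one gesture element per cluster) and words (3 distinct syllables).

    Gesture elements are assumed stored as buffer patterns ``0..n_gestures-1``
    and syllables as ``syllables_offset..syllables_offset+n_syllables-1``.
    Sign combinations are sampled without replacement from the full product of
    one element per cluster; word combinations are ordered triples of distinct
    syllables, sampled without replacement from the combination space.
    """
    rng = _as_rng(seed)
    n_clusters = len(gestures.cluster_bounds or [])
    if n_clusters == 0:
        raise ValueError("gesture PatternSet must carry cluster_bounds")
    per_cluster = gestures.p // n_clusters
    sign_space = list(
        product(*[range(c * per_cluster, (c + 1) * per_cluster) for c in range(n_clusters)])
    )
    if n_signs > len(sign_space):
        raise ValueError(f"requested {n_signs} signs from a space of {len(sign_space)}")
    n_word_combos = n_syllables * (n_syllables - 1) * (n_syllables - 2)
    if n_words > n_word_combos:
        raise ValueError(f"requested {n_words} words from a space of {n_word_combos}")

    sign_choice = rng.choice(len(sign_space), size=n_signs, replace=False)
    word_triples: set[tuple[int, int, int]] = set()
    while len(word_triples) < n_words:
        t = tuple(rng.choice(n_syllables, size=3, replace=False) + syllables_offset)
        word_triples.add(t)

    n_items = n_signs + n_words
    if lexicon_patterns.p < n_items:
        raise ValueError("lexicon stores fewer patterns than items required")
    lex_ids = rng.choice(lexicon_patterns.p, size=n_items, replace=False)

    items = []
    for s, idx in enumerate(sign_choice):
        items.append(
            LexiconItem(
                item_kind="sign",
                lexicon_pattern=int(lex_ids[s]),
                component_ids=tuple(int(c) for c in sign_space[idx]),
                mode="simultaneous",
            )
        )
    for w, triple in enumerate(sorted(word_triples)):
        items.append(
            LexiconItem(
                item_kind="word",
                lexicon_pattern=int(lex_ids[n_signs + w]),
                component_ids=tuple(int(c) for c in triple),
                mode="sequential",
            )
        )
    lex = Lexicon(
        items=items,
        G=np.zeros((lexicon_patterns.p, buffer_p)),
        lambda_by_kind={"word": lambda_word, "sign": lambda_sign},
    )
    _fill_G(lex)
    return lex
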