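"""Stimulus construction: edit distance and closest-variant pseudowords.

Reading-experiment stimuli are built from real base words by replacing
k letters (k = 1, 2, 3), under the constraint that the pseudoword stays
closer to its base word than to every other word in the lexicon, with
closeness measured by Damerau-Levenshtein distance. The distance variant
implemented is the restricted form (optimal string alignment): insertions,
deletions, substitutions, and adjacent transpositions, with no substring
edited twice. Comparison is case- and diacritic-sensitive (A != Ä).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np

__all__ = [
    "Lexicon",
    "StimulusItem",
    "PseudowordError",
    "damerau_levenshtein",
    "generate_pseudoword",
    "validate_stimulus_set",
    "read_lexicon",
    "write_stimulus_set",
]

CONDITION_BY_K = {0: "RW", 1: "RL1", 2: "RL2", 3: "RL3"}


class PseudowordError(ValueError):
    """No string satisfies the distance/uniqueness constraints."""


@dataclass
class Lexicon:
    words: set[str]
    frequency: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.words = set(self.words)
        if not self.words:
            raise ValueError("lexicon must be nonempty")

    @property
    def alphabet(self) -> list[str]:
        """Sorted letters occurring in the lexicon (handles Ä/Ö naturally)."""
        return sorted({ch for w in self.words for ch in w})


@dataclass
class StimulusItem:
    stimulus: str
    base: str
    condition: str
    distance: int


def damerau_levenshtein(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Minimal number of insertions, deletions, substitutions and adjacent
    transpositions turning ``a`` into ``b``, under the restriction that no
    substring is edited more than once.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    # two/three rolling rows of the DP table
    prev2 = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[lb]


def _substitution_variants(base: str, k: int, alphabet: list[str], rng: np.random.Generator):
    """Yield length-preserving variants with letters replaced at exactly k
    positions, in a seed-randomized order over (positions, letters) tuples."""
    positions = list(combinations(range(len(base)), k))
    rng.shuffle(positions)
    for pos in positions:
        letter_sets = [[c for c in alphabet if c != base[p]] for p in pos]
        choices = list(product(*letter_sets))
        idx = rng.permutation(len(choices))
        for i in idx:
            letters = choices[i]
            chars = list(base)
            for p, c in zip(pos, letters):
                chars[p] = c
            yield "".join(chars)


def generate_pseudoword(
    base: str,
    k: int,
    lexicon: Lexicon,
    seed: int,
    alphabet: list[str] | None = None,
) -> StimulusItem:
    """Closest orthographic variant of ``base`` at distance exactly ``k``.

    Candidates are letter substitutions at exactly k positions (length
    preserved). A candidate is accepted only if its distance to the base is
    exactly k (substitutions of adjacent letters can collapse into a cheaper
    transposition, which disqualifies the candidate) and every *other*
    lexicon word is at distance > k. Raises :class:`PseudowordError` naming
    the blocking words when no candidate qualifies — word-like conditions
    with dense lexical neighborhoods genuinely admit no solution at times.
    """
    if base not in lexicon.words:
        raise ValueError(f"base {base!r} not in lexicon")
    if k < 0 or k > len(base):
        raise ValueError(f"k={k} out of range for base of length {len(base)}")
    if k == 0:
        return StimulusItem(base, base, "RW", 0)
    if alphabet is None:
        alphabet = lexicon.alphabet
    rng = np.random.default_rng(seed)
    others = lexicon.words - {base}
    blockers: set[str] = set()
    for cand in _substitution_variants(base, k, alphabet, rng):
        if damerau_levenshtein(cand, base) != k:
            continue
        block = next((w for w in others if damerau_levenshtein(cand, w) <= k), None)
        if block is None:
            cond = CONDITION_BY_K.get(k, f"RL{k}")
            return StimulusItem(cand, base, cond, k)
        blockers.add(block)
    raise PseudowordError(
        f"no variant of {base!r} at distance {k} clears the lexicon; "
        f"blocking words include: {sorted(blockers)[:10]}"
    )


def validate_stimulus_set(items: list[StimulusItem], lexicon: Lexicon) -> list[dict]:
    """Recompute distances and constraints; return one report row per item.

    Violations are report content (``ok`` flag + messages), not exceptions.
    """
    report = []
    for item in items:
        messages = []
        d = damerau_levenshtein(item.stimulus, item.base)
        if d != item.distance:
            messages.append(f"recorded distance {item.distance} but recomputed {d}")
        expected_cond = CONDITION_BY_K.get(d)
        if expected_cond is not None and item.condition != expected_cond:
            messages.append(
                f"condition {item.condition} inconsistent with distance {d} "
                f"(expected {expected_cond})"
            )
        if item.base not in lexicon.words:
            messages.append(f"base {item.base!r} not in lexicon")
        if d > 0:
            closer = sorted(
                w
                for w in lexicon.words - {item.base}
                if damerau_levenshtein(item.stimulus, w) <= d
            )
            if closer:
                messages.append(f"uniqueness violated by: {closer[:10]}")
        report.append(
            {
                "stimulus": item.stimulus,
                "base": item.base,
                "condition": item.condition,
                "distance": d,
                "ok": not messages,
                "messages": messages,
            }
        )
    return report


def read_lexicon(path: str | Path) -> Lexicon:
    """Plain-text word list, one word per line, UTF-8."""
    words = {
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }
    return Lexicon(words)


def write_stimulus_set(path: str | Path, items: list[StimulusItem]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stimulus\tbase\tcondition\tdistance\n")
        for it in items:
            fh.write(f"{it.stimulus}\t{it.base}\t{it.condition}\t{it.distance}\n")
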