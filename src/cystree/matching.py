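"""Resolve the connectivity graph into a disulfide pattern.

The most likely pattern is the maximum-weight perfect matching of the
connectivity graph. The production solver runs the blossom algorithm
(networkx) on an offset graph so that perfect matchings always dominate,
then canonicalizes ties to the lexicographically smallest optimal
matching; a brute-force enumerator serves as the oracle at desk scale,
and a seeded uniform random matching implements the fallback used when no
informative family is available.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

_WEIGHT_TOL = 1e-9
BRUTE_FORCE_MAX = 16


@dataclass(frozen=True)
class BondPattern:
    """A perfect matching on the |C| oxidized cysteines: d disjoint pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        canon = tuple(sorted(tuple(sorted(map(int, p))) for p in self.pairs))
        object.__setattr__(self, "pairs", canon)
        seen: set[int] = set()
        for a, b in canon:
            if a == b:
                raise ValueError(f"self-pair ({a},{b})")
            if a in seen or b in seen:
                raise ValueError("pairs are not disjoint")
            seen.update((a, b))
        if seen and seen != set(range(max(seen) + 1)):
            raise ValueError("pairs do not cover cysteines 0..n-1 exactly")

    @property
    def n(self) -> int:
        return 2 * len(self.pairs)

    @property
    def d(self) -> int:
        return len(self.pairs)

    def weight(self, W: np.ndarray) -> float:
        return float(sum(W[a, b] for a, b in self.pairs))

    def to_tsv(self, oxidized_positions: tuple[int, ...] | None = None) -> str:
        """One bond per line, 1-based residue positions when given."""
        lines = []
        for a, b in self.pairs:
            if oxidized_positions is not None:
                a, b = oxidized_positions[a] + 1, oxidized_positions[b] + 1
            lines.append(f"{a}\t{b}")
        return "\n".join(lines) + "\n"


def _check_even(n: int) -> None:
    if n < 2 or n % 2 != 0:
        raise ValueError(f"oxidized cysteine count must be even and >= 2, got {n}")


def _iter_matchings(vertices: tuple[int, ...]):
    """All perfect matchings, in lexicographic order of their sorted pair list."""
    if not vertices:
        yield ()
        return
    a, rest = vertices[0], vertices[1:]
    for k, b in enumerate(rest):
        remaining = rest[:k] + rest[k + 1:]
        for sub in _iter_matchings(remaining):
            yield ((a, b),) + sub


def brute_force_matching(W: np.ndarray) -> BondPattern:
    """Exhaustive maximum-weight perfect matching, (n-1)!! candidates.

    Keeps the first matching achieving the maximum, which by enumeration
    order is the lexicographically smallest one.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    _check_even(n)
    if n > BRUTE_FORCE_MAX:
        raise ValueError(f"brute force limited to n <= {BRUTE_FORCE_MAX}, got {n}")
    best: tuple[tuple[int, int], ...] | None = None
    best_w = -np.inf
    for pairs in _iter_matchings(tuple(range(n))):
        w = sum(W[a, b] for a, b in pairs)
        if w > best_w + _WEIGHT_TOL:
            best, best_w = pairs, w
    assert best is not None
    return BondPattern(pairs=best)


def _blossom_weight(W: np.ndarray, vertices: tuple[int, ...]) -> float:
    """Optimal perfect-matching weight on the induced complete subgraph.

    A constant offset of (1 + max weight) per edge makes every perfect
    matching outweigh any deficient one, so blossom with max-cardinality
    returns a perfect matching maximizing the original weight.
    """
    if not vertices:
        return 0.0
    offset = 1.0 + float(W.max())
    G = nx.Graph()
    G.add_nodes_from(vertices)
    for a, b in combinations(vertices, 2):
        G.add_edge(a, b, weight=W[a, b] + offset)
    mate = nx.max_weight_matching(G, maxcardinality=True)
    if 2 * len(mate) != len(vertices):
        raise RuntimeError("no perfect matching found on complete graph")
    return float(sum(W[a, b] for a, b in mate))


def max_weight_perfect_matching(W: np.ndarray) -> BondPattern:
    """Maximum-weight perfect matching with deterministic tie-breaking.

    After the blossom solver establishes the optimal total weight, pairs
    are fixed greedily — smallest free cysteine first, smallest partner
    that keeps the optimum attainable — which selects the
    lexicographically smallest optimal matching (the same convention as
    :func:`brute_force_matching`).
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    _check_even(n)
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    free = tuple(range(n))
    target = _blossom_weight(W, free)
    chosen: list[tuple[int, int]] = []
    acc = 0.0
    while free:
        a, rest = free[0], free[1:]
        for b in rest:
            remaining = tuple(v for v in rest if v != b)
            if acc + W[a, b] + _blossom_weight(W, remaining) >= target - _WEIGHT_TOL:
                chosen.append((a, b))
                acc += W[a, b]
                free = remaining
                break
        else:  # numerically unreachable; guard against tolerance failure
            raise RuntimeError("failed to extend optimal matching")
    return BondPattern(pairs=tuple(chosen))


def random_matching(n: int, seed: int | random.Random) -> BondPattern:
    """Uniform random perfect matching on ``n`` cysteines (seeded).

    Pairs the smallest free vertex with a uniformly random partner and
    recurses, which is uniform over all (n-1)!! matchings.
    """
    _check_even(n)
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    free = list(range(n))
    pairs = []
    while free:
        a = free.pop(0)
        b = free.pop(rng.randrange(len(free)))
        pairs.append((a, b))
    return BondPattern(pairs=tuple(pairs))
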