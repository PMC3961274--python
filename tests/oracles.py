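"""Independent brute-force oracles used to cross-check graph enumeration.

These deliberately avoid networkx and the package's own traversal code:
cycles and paths are enumerated by exhaustive search over ordered node
tuples, which is feasible for the <=15-node graphs used in tests.
"""

from itertools import permutations


def brute_force_cycles(edges: set[tuple[str, str]], max_len: int) -> set[tuple[str, ...]]:
    """All simple directed cycles with 2..max_len nodes, rotated so the
    lexicographically smallest node comes first."""
    nodes = sorted({n for e in edges for n in e})
    found = set()
    for k in range(2, max_len + 1):
        for tup in permutations(nodes, k):
            if all((tup[i], tup[(i + 1) % k]) in edges for i in range(k)):
                pivot = tup.index(min(tup))
                found.add(tup[pivot:] + tup[:pivot])
    return found


def brute_force_paths(edges: set[tuple[str, str]], length: int) -> set[tuple[str, ...]]:
    """All simple directed paths with exactly ``length`` nodes."""
    nodes = sorted({n for e in edges for n in e})
    return {
        tup for tup in permutations(nodes, length)
        if all((tup[i], tup[i + 1]) in edges for i in range(length - 1))
    }


def brute_force_best_window_score(frequencies, window_codes) -> float:
    """Unnormalized information-weighted score of one window, summed by hand."""
    import math

    total = 0.0
    for i, code in enumerate(window_codes):
        info = sum(
            f * math.log(4.0 * f) for f in frequencies[i] if f > 0
        )
        total += info * frequencies[i][code]
    return total
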