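"""Independent brute-force reference implementations for oracle tests.

Everything here is written as plain double loops over plain tuples/dicts,
deliberately sharing no code path with the package: these are the
references the fast implementations are checked against.
"""

from __future__ import annotations


def brute_pair_count_pooled(n: int) -> int:
    """All unordered pairs of n items including self-pairs, by double loop."""
    count = 0
    for i in range(n):
        for j in range(n):
            if j >= i:
                count += 1
    return count


def brute_pair_count_grouped(group_sizes: list[int]) -> int:
    count = 0
    for size in group_sizes:
        for i in range(size):
            for j in range(size):
                if j >= i:
                    count += 1
    return count


def brute_label(seq_a: str, seq_b: str, groups: dict[str, str]) -> str:
    """Truth label from a plain sequence->group mapping."""
    if seq_a not in groups or seq_b not in groups:
        return "non_library_false"
    if groups[seq_a] != groups[seq_b]:
        return "cross_group_false"
    return "within_group_true"


def brute_fdr(pairs: list[tuple[str, str]], groups: dict[str, str]) -> float:
    if not pairs:
        return 0.0
    n_false = 0
    for a, b in pairs:
        if brute_label(a, b, groups) != "within_group_true":
            n_false += 1
    return n_false / len(pairs)


def brute_curve(
    scored_pairs: list[tuple[float, str, str]], groups: dict[str, str]
) -> list[tuple[float, int, float]]:
    """(threshold, n_retained, fdr) per distinct score, strictest first."""
    thresholds = sorted({s for s, _, _ in scored_pairs}, reverse=True)
    out = []
    for t in thresholds:
        retained = [(a, b) for s, a, b in scored_pairs if s >= t]
        out.append((t, len(retained), brute_fdr(retained, groups)))
    return out


def brute_cutoff(
    scored_pairs: list[tuple[float, str, str]],
    groups: dict[str, str],
    target: float,
) -> tuple[float | None, int, float]:
    """Least strict qualifying threshold by exhaustive ascending sweep."""
    for t in sorted({s for s, _, _ in scored_pairs}):
        retained = [(a, b) for s, a, b in scored_pairs if s >= t]
        fdr = brute_fdr(retained, groups)
        if fdr <= target:
            return t, len(retained), fdr
    return None, 0, 0.0


def brute_overlap(
    sets: dict[str, list[tuple]],
) -> dict[frozenset, set]:
    """Region -> member keys by explicit membership enumeration."""
    union = set()
    for keys in sets.values():
        union.update(keys)
    regions: dict[frozenset, set] = {}
    for k in union:
        labels = frozenset(lab for lab, keys in sets.items() if k in keys)
        regions.setdefault(labels, set()).add(k)
    return regions


def brute_ppm(
    sides: list[tuple[str, int]], window: int = 3
) -> dict[int, dict[str, float]]:
    """offset -> {aa: probability} by explicit positional counting."""
    counts: dict[int, dict[str, int]] = {
        o: {} for o in range(-window, window + 1)
    }
    for seq, site in sides:
        for o in range(-window, window + 1):
            pos = site + o
            if 1 <= pos <= len(seq):
                aa = seq[pos - 1]
                counts[o][aa] = counts[o].get(aa, 0) + 1
    probs: dict[int, dict[str, float]] = {}
    for o, c in counts.items():
        total = sum(c.values())
        probs[o] = {aa: n / total for aa, n in c.items()} if total else {}
    return probs
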