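"""Independent brute-force oracles the tests check the implementation against.

These deliberately take the dumbest correct path (full substring
enumeration, dictionary group-and-reduce, linear scans) and share no code
with the implementation they verify.
"""

from __future__ import annotations

from collections import defaultdict

from pepsearch.digestion import EnzymeRule, SEMITRYPTIC


def brute_force_digest(
    sequence: str,
    rule: EnzymeRule,
    min_length: int = 1,
    max_length: int = 10_000,
) -> set[tuple[str, int]]:
    """Enumerate ALL substrings; keep those satisfying the terminus and
    missed-cleavage predicates."""
    n = len(sequence)
    cuts = [
        sequence[i] in rule.cleave_after
        and (i + 1 >= n or sequence[i + 1] not in rule.block_if_next)
        for i in range(n)
    ]
    # prefix counts of cut sites, so the per-substring missed count is O(1)
    ncuts = [0]
    for c in cuts:
        ncuts.append(ncuts[-1] + int(c))

    def start_ok(s: int) -> bool:
        return s == 0 or cuts[s - 1]

    def end_ok(e: int) -> bool:
        return e == n or cuts[e - 1]

    out: set[tuple[str, int]] = set()
    for s in range(n):
        for e in range(s + 1, n + 1):
            if not min_length <= e - s <= max_length:
                continue
            missed = ncuts[e - 1] - ncuts[s]
            if missed > rule.max_missed_cleavages:
                continue
            if rule.mode == SEMITRYPTIC:
                if start_ok(s) or end_ok(e):
                    out.add((sequence[s:e], missed))
            else:
                if start_ok(s) and end_ok(e):
                    out.add((sequence[s:e], missed))
    return out


def group_reduce(pairs, reducer):
    """Single-threaded dictionary-based group-and-reduce oracle."""
    groups = defaultdict(list)
    for key, value in pairs:
        groups[key].append(value)
    out = []
    for key in sorted(groups):
        out.extend(reducer(key, groups[key]))
    return out
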