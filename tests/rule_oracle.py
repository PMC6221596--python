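"""Brute-force special-cause rule oracle.

Deliberately naive and structurally independent of the production rule
engine: it enumerates every candidate window, collects the qualifying
ones, and merges overlapping windows by set-union fixpoint.  Used to
cross-check ``edspc.spc.detect_special_cause`` exhaustively on short
series and by sampling on longer ones.
"""

from __future__ import annotations


def _merge_components(windows: list[set]) -> list[set]:
    groups: list[set] = []
    for w in windows:
        merged = set(w)
        keep = []
        for g in groups:
            if g & merged:
                merged |= g
            else:
                keep.append(g)
        groups = keep + [merged]
    return groups


def oracle_detect(values, center, sigma, rules) -> set:
    """Return {(rule_id, point_indices, direction)} for the given series."""
    v = [float(x) for x in values]
    n = len(v)
    sig = list(sigma) if hasattr(sigma, "__len__") else [float(sigma)] * n
    out: set = set()

    def beyond(i: int, k: float, sgn: int) -> bool:
        return sgn * (v[i] - center) > k * sig[i]

    for direction, sgn in (("above", 1), ("below", -1)):
        if "outside_3sd" in rules:
            for i in range(n):
                if beyond(i, 3, sgn):
                    out.add(("outside_3sd", (i,), direction))
        for rule, width, need, k in (
            ("four_of_five_1sd", 5, 4, 1),
            ("two_of_three_2sd", 3, 2, 2),
        ):
            if rule not in rules:
                continue
            wins = [
                set(range(s, s + width))
                for s in range(n - width + 1)
                if sum(beyond(i, k, sgn) for i in range(s, s + width)) >= need
            ]
            for g in _merge_components(wins):
                idx = tuple(sorted(i for i in g if beyond(i, k, sgn)))
                out.add((rule, idx, direction))
        if "eight_same_side" in rules:
            wins = [
                set(range(s, s + 8))
                for s in range(n - 7)
                if all(sgn * (v[i] - center) > 0 for i in range(s, s + 8))
            ]
            for g in _merge_components(wins):
                out.add(("eight_same_side", tuple(sorted(g)), direction))
    if "six_trending" in rules:
        for direction, up in (("increasing", True), ("decreasing", False)):
            wins = [
                set(range(s, s + 6))
                for s in range(n - 5)
                if all(
                    (v[i + 1] > v[i]) if up else (v[i + 1] < v[i])
                    for i in range(s, s + 5)
                )
            ]
            for g in _merge_components(wins):
                out.add(("six_trending", tuple(sorted(g)), direction))
    return out
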