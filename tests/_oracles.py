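"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (full enumeration, per-window loops) and share no
code with the package.
"""

from __future__ import annotations

import math

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "T"), ("T", "G")}


def hairpin_oracle(
    seq: str,
    min_stem: int = 3,
    min_loop: int = 3,
    max_loop: int = 30,
    allow_gu: bool = False,
) -> tuple[int, int, int, int] | None:
    """Enumerate every (outer pair, stem length) decomposition; pick the best
    by (max stem pairs, min loop, min 5' tail). Returns (stem, loop, five, three)."""
    s = seq.upper()
    n = len(s)
    valid = WC | GU if allow_gu else WC
    best = None
    best_key = None
    for i0 in range(1, n + 1):
        for j0 in range(i0 + 1, n + 1):
            span = j0 - i0 + 1
            for stem in range(min_stem, span // 2 + 1):
                loop = span - 2 * stem
                if loop < min_loop or loop > max_loop:
                    continue
                if all((s[i0 - 1 + k], s[j0 - 1 - k]) in valid for k in range(stem)):
                    key = (stem, -loop, -(i0 - 1))
                    if best_key is None or key > best_key:
                        best_key = key
                        best = (stem, loop, i0 - 1, n - j0)
    return best


def hamming_scan_oracle(seq: str, consensus: str, budget: int) -> list[tuple[int, int]]:
    """All (1-based start, mismatches) windows within budget, per-character loop."""
    out = []
    m = len(consensus)
    for i in range(len(seq) - m + 1):
        mm = sum(1 for a, b in zip(seq[i : i + m].upper(), consensus) if a != b)
        if mm <= budget:
            out.append((i + 1, mm))
    return sorted(out, key=lambda t: (t[1], t[0]))


def codon_count_oracle(seqs: list[str]) -> dict[str, int]:
    """Stride-3 codon counter over complete, unambiguous codons."""
    counts: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        for i in range(0, len(s) // 3 * 3, 3):
            c = s[i : i + 3]
            if set(c) <= set("ACGT"):
                counts[c] = counts.get(c, 0) + 1
    return counts


def jc69_closed_form(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc69_expected_p(d: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
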