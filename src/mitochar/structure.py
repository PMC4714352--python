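"""Stem-loop (hairpin) detection for the light-strand replication origin.

The O_L of vertebrate mitogenomes is a short non-coding element between
tRNA-Asn and tRNA-Cys (inside the WANCY tRNA cluster) that folds into a simple
stem-loop.  The search here is purely combinatorial: among all hairpins with a
contiguous, fully base-paired stem (no bulges or internal loops) and a loop
within the allowed size range, return the one with the most stem pairs, ties
broken by smaller loop and then smaller 5' tail.  Pairing is Watson-Crick
(A-T, G-C) with optional G.T wobble.  No thermodynamics is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .feature_table import FeatureTableError, MitoFeatureTable

__all__ = ["Hairpin", "find_best_hairpin", "locate_OL", "render_hairpin", "hairpin_to_json"]


@dataclass(frozen=True)
class Hairpin:
    """A contiguous-stem hairpin call on a (sub)sequence.

    Positions are 1-based within the searched sequence; ``pairs`` runs from
    the outermost to the innermost stem pair.  The decomposition satisfies
    ``2 * stem_pairs + loop_len + five_tail + three_tail == len(seq)``.
    """

    stem_pairs: int
    loop_len: int
    five_tail: int
    three_tail: int
    pairs: tuple[tuple[int, int], ...] = field(default_factory=tuple)


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def find_best_hairpin(
    seq: str,
    min_stem: int = 3,
    min_loop: int = 3,
    max_loop: int = 30,
    allow_gu: bool = False,
) -> Hairpin | None:
    """Best contiguous-stem hairpin of ``seq``, or None if no structure qualifies.

    "Best" maximizes the number of stem pairs; ties go to the smaller loop,
    then the smaller 5' unpaired tail.  For each candidate outer pair the stem
    is extended inward while bases pair, capped so the enclosed loop stays at
    least ``min_loop``; structures whose loop would exceed ``max_loop`` are
    rejected (shortening the stem only widens the loop further).
    """
    s = seq.upper()
    n = len(s)
    valid = _WC | _GU if allow_gu else _WC
    best: Hairpin | None = None
    best_key: tuple[int, int, int] | None = None
    for i0 in range(1, n + 1):
        for j0 in range(i0 + 2 * min_stem + min_loop - 2, n + 1):
            if (s[i0 - 1], s[j0 - 1]) not in valid:
                continue
            span = j0 - i0 + 1
            # longest run of consecutive pairs inward from (i0, j0)
            run = 0
            while (
                run < span // 2
                and (s[i0 - 1 + run], s[j0 - 1 - run]) in valid
            ):
                run += 1
            stem = min(run, (span - min_loop) // 2)
            if stem < min_stem:
                continue
            loop = span - 2 * stem
            if loop > max_loop:
                continue
            key = (stem, -loop, -(i0 - 1))  # maximize
            if best_key is None or key > best_key:
                best_key = key
                best = Hairpin(
                    stem_pairs=stem,
                    loop_len=loop,
                    five_tail=i0 - 1,
                    three_tail=n - j0,
                    pairs=tuple((i0 + k, j0 - k) for k in range(stem)),
                )
    return best


def locate_OL(table: MitoFeatureTable) -> tuple[int, int, int]:
    """(start, end, length) of the replication-origin gap between tRNA-Asn and tRNA-Cys."""

    def find(suffix: str):
        for f in table.features:
            if f.name.replace("_", "-").endswith(suffix):
                return f
        raise FeatureTableError(f"table lacks a tRNA-{suffix} feature")

    asn, cys = find("Asn"), find("Cys")
    gap = cys.start - asn.end - 1
    if gap <= 0:
        raise FeatureTableError(
            f"no gap between tRNA-Asn (end {asn.end}) and tRNA-Cys (start {cys.start})"
        )
    return asn.end + 1, cys.start - 1, gap


def render_hairpin(seq: str, hp: Hairpin) -> str:
    """Three-line ASCII rendering: 5' arm over 3' arm, pair marks between."""
    s = seq.upper()
    i0, j0 = hp.pairs[0] if hp.pairs else (1, len(s))
    top = s[: i0 - 1].lower() + s[i0 - 1 : i0 - 1 + hp.stem_pairs]
    bottom = s[j0:][::-1].lower() + s[j0 - hp.stem_pairs : j0][::-1]
    pad = max(len(s[: i0 - 1]), len(s[j0:]))
    top = top.rjust(pad + hp.stem_pairs)
    bottom = bottom.rjust(pad + hp.stem_pairs)
    marks = " " * pad + "|" * hp.stem_pairs
    loop = s[i0 - 1 + hp.stem_pairs : j0 - hp.stem_pairs]
    return (
        f"5' {top}\\\n"
        f"   {marks} loop: {loop} ({hp.loop_len} nt)\n"
        f"3' {bottom}/\n"
        f"stem {hp.stem_pairs} bp, 5' tail {hp.five_tail} nt, 3' tail {hp.three_tail} nt\n"
    )


def hairpin_to_json(hp: Hairpin) -> str:
    return json.dumps(
        {
            "stem_pairs": hp.stem_pairs,
            "loop_len": hp.loop_len,
            "five_tail": hp.five_tail,
            "three_tail": hp.three_tail,
            "pairs": [list(p) for p in hp.pairs],
        },
        indent=2,
    )
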