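"""Base composition, strand skew and codon statistics.

Strand asymmetry of the circular mitogenome is summarized by the two skew
statistics computed on the heavy strand,

    GC-skew = (G - C) / (G + C)        AT-skew = (A - T) / (A + T),

which are invariant to whether counts or percentages are used.  Protein-coding
genes of vertebrate mitogenomes frequently end on incomplete stop codons (a
terminal TA or lone T completed to TAA by post-transcriptional
polyadenylation); stop classification and translated-residue counts here
follow that convention under the vertebrate mitochondrial genetic code
(where AGA/AGG read as stop).
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .feature_table import FeatureClass, MitoFeatureTable, feature_length

__all__ = [
    "CompositionProfile",
    "SkewPair",
    "base_composition",
    "skew",
    "skew_from_percentages",
    "classify_stop",
    "stop_length",
    "amino_acid_count",
    "codon_position_composition",
    "codon_usage",
    "extract_cds",
    "extract_feature_seq",
    "load_reference_composition",
    "composition_report",
    "VERTEBRATE_MITO_CODE",
]

#: NCBI translation table 2 (vertebrate mitochondrial); data, not logic.
VERTEBRATE_MITO_CODE = CodonTable.unambiguous_dna_by_id[2]

STOP_LENGTHS = {"TAA": 3, "TAG": 3, "AGA": 3, "TA": 2, "T": 1}

_BASES = "TCAG"


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts of a sequence; ambiguity codes tallied in ``other``."""

    t: int
    c: int
    a: int
    g: int
    other: int = 0

    @property
    def n(self) -> int:
        return self.t + self.c + self.a + self.g

    def count(self, base: str) -> int:
        return getattr(self, base.lower())

    def percentage(self, base: str) -> float:
        if self.n == 0:
            raise ZeroDivisionError("empty profile has no percentages")
        return 100.0 * self.count(base) / self.n

    def percentages(self) -> dict[str, float]:
        return {b: self.percentage(b) for b in _BASES}

    def at_percent(self) -> float:
        return self.percentage("A") + self.percentage("T")

    def __add__(self, o: "CompositionProfile") -> "CompositionProfile":
        return CompositionProfile(
            self.t + o.t, self.c + o.c, self.a + o.a, self.g + o.g, self.other + o.other
        )


@dataclass(frozen=True)
class SkewPair:
    """Strand skews; ``None`` marks an undefined value (zero denominator)."""

    gc_skew: float | None
    at_skew: float | None

    def rounded(self, ndigits: int = 3) -> tuple[float | None, float | None]:
        r = lambda v: None if v is None else round(v, ndigits)
        return r(self.gc_skew), r(self.at_skew)


def base_composition(seq: str) -> CompositionProfile:
    """Exact base counts; N excluded from the total; case-insensitive."""
    counts = Counter(seq.upper())
    bad = set(counts) - set("ACGTN")
    if bad:
        offset = next(i for i, ch in enumerate(seq.upper()) if ch in bad)
        raise ValueError(
            f"non-IUPAC character {seq[offset]!r} at offset {offset} (0-based)"
        )
    return CompositionProfile(
        t=counts["T"], c=counts["C"], a=counts["A"], g=counts["G"], other=counts["N"]
    )


def skew(profile: CompositionProfile) -> SkewPair:
    """GC- and AT-skew from raw counts; undefined denominators yield None."""
    gc = profile.g + profile.c
    at = profile.a + profile.t
    return SkewPair(
        gc_skew=(profile.g - profile.c) / gc if gc else None,
        at_skew=(profile.a - profile.t) / at if at else None,
    )


def skew_from_percentages(t: float, c: float, a: float, g: float) -> SkewPair:
    """Skews recomputed from printed one-decimal percentages (an I/O-level check)."""
    gc, at = g + c, a + t
    return SkewPair(
        gc_skew=(g - c) / gc if gc else None,
        at_skew=(a - t) / at if at else None,
    )


def classify_stop(
    cds: str | int, declared_stop: str | None = None
) -> tuple[str, list[str]]:
    """Classify a gene's terminator from its sequence or length.

    Length mod 3 == 2 is an incomplete TA, mod 3 == 1 a lone T; genes of
    complete codon length end on a full stop (TAA/TAG/AGA, read from the
    sequence when available, otherwise from the declaration).  Returns the
    class and a list of consistency warnings (a declaration that disagrees
    with the length is warned about, not fatal).
    """
    if isinstance(cds, int):
        length, seq = cds, None
    else:
        seq = cds.upper()
        length = len(seq)
    if length < 4:
        raise ValueError(f"sequence too short to classify ({length} nt)")
    warnings: list[str] = []
    mod = length % 3
    if mod == 2:
        cls = "TA"
    elif mod == 1:
        cls = "T"
    else:
        if seq is not None:
            tail = seq[-3:]
            if tail not in ("TAA", "TAG", "AGA", "AGG"):
                warnings.append(f"terminal codon {tail} is not a recognized stop")
            cls = tail if tail in STOP_LENGTHS else (declared_stop or "TAA")
        elif declared_stop in ("TAA", "TAG", "AGA"):
            cls = declared_stop
        else:
            raise ValueError(
                "complete-codon length needs a sequence or declared complete stop"
            )
    if declared_stop is not None and declared_stop != cls:
        warnings.append(
            f"declared stop {declared_stop!r} inconsistent with length {length} "
            f"(classified {cls!r})"
        )
    return cls, warnings


def stop_length(stop_class: str) -> int:
    return STOP_LENGTHS[stop_class]


def amino_acid_count(length: int, stop_class: str) -> int:
    """Translated residues of a gene: (length - stop length) / 3."""
    slen = STOP_LENGTHS[stop_class]
    if (length - slen) % 3 != 0:
        raise ValueError(
            f"length {length} minus stop {stop_class} ({slen} nt) not divisible by 3"
        )
    return (length - slen) // 3


def codon_position_composition(
    cds_list: Iterable[str],
) -> tuple[CompositionProfile, CompositionProfile, CompositionProfile]:
    """Per-codon-position base composition over stop-trimmed, in-frame CDSs."""
    parts = ["", "", ""]
    for cds in cds_list:
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        for k in range(3):
            parts[k] += cds[k::3]
    p1, p2, p3 = (base_composition(p) for p in parts)
    return p1, p2, p3


def codon_usage(cds_list: Iterable[str]) -> tuple[Counter, int]:
    """Codon counts over complete codons; codons with ambiguity are skipped.

    Returns ``(counts, n_skipped)``.
    """
    counts: Counter = Counter()
    skipped = 0
    for cds in cds_list:
        cds = cds.upper()
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
            else:
                skipped += 1
    return counts, skipped


# ---------------------------------------------------------------------------
# Sequence extraction and reporting
# ---------------------------------------------------------------------------


def extract_feature_seq(genome: str, start: int, end: int, strand: str = "H") -> str:
    """Coding-strand sequence of a (1-based inclusive) interval, wrap-aware."""
    if start <= end:
        sub = genome[start - 1 : end]
    else:  # wraps through the origin
        sub = genome[start - 1 :] + genome[:end]
    return sub if strand == "H" else str(Seq(sub).reverse_complement())


def extract_cds(genome: str, table: MitoFeatureTable) -> dict[str, str]:
    """Coding-strand sequences of all protein genes (L-strand genes reverse-complemented)."""
    return {
        f.name: extract_feature_seq(genome, f.start, f.end, f.strand)
        for f in table.by_class(FeatureClass.protein_coding)
    }


def load_reference_composition() -> pd.DataFrame:
    """Published per-region base-composition percentages, indexed by region."""
    path = importlib.resources.files("mitochar").joinpath("data/bahaba_composition.tsv")
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return df.set_index("Region")


def composition_report(genome: str, table: MitoFeatureTable) -> pd.DataFrame:
    """Per-gene / per-position / total composition table (percentages, one source of truth).

    Rows mirror the published rendering: each protein gene, the three codon
    positions of the concatenated protein genes (stops trimmed), the protein
    total, pooled tRNA and rRNA, the control region, and the overall genome.
    """
    glen = table.genome_length or len(genome)
    rows: list[dict] = []

    def row(region: str, profile: CompositionProfile) -> dict:
        pct = profile.percentages()
        return {
            "Region": region,
            "T": pct["T"],
            "C": pct["C"],
            "A": pct["A"],
            "G": pct["G"],
            "A+T": pct["A"] + pct["T"],
            "N": profile.n,
        }

    cds = extract_cds(genome, table)
    trimmed: list[str] = []
    pcg_profile = CompositionProfile(0, 0, 0, 0)
    for f in table.by_class(FeatureClass.protein_coding):
        seq = cds[f.name]
        rows.append(row(f.name, base_composition(seq)))
        pcg_profile = pcg_profile + base_composition(seq)
        cls, _ = classify_stop(seq, f.stop_codon)
        trimmed.append(seq[: len(seq) - STOP_LENGTHS[cls]])
    if trimmed:
        p1, p2, p3 = codon_position_composition(trimmed)
        rows.append(row("PCG_1st", p1))
        rows.append(row("PCG_2nd", p2))
        rows.append(row("PCG_3rd", p3))
        rows.append(row("PCG_total", pcg_profile))
    for cls_name, label in ((FeatureClass.tRNA, "tRNA"), (FeatureClass.rRNA, "rRNA")):
        feats = table.by_class(cls_name)
        if feats:
            pooled = CompositionProfile(0, 0, 0, 0)
            for f in feats:
                pooled = pooled + base_composition(
                    extract_feature_seq(genome, f.start, f.end, f.strand)
                )
            rows.append(row(label, pooled))
    for f in table.by_class(FeatureClass.control_region):
        rows.append(row(f.name, base_composition(extract_feature_seq(genome, f.start, f.end, f.strand))))
    overall = base_composition(genome)
    rec = row("Overall", overall)
    sk = skew(overall)
    rec["GC_skew"], rec["AT_skew"] = sk.gc_skew, sk.at_skew
    rows.append(rec)
    return pd.DataFrame(rows).set_index("Region")
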