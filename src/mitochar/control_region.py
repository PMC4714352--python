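"""Control-region domain annotation by fuzzy consensus scanning.

The teleost control region (D-loop) is organized into three domains: an
extended termination-associated sequence (ETAS) domain at the 5' end, a
central conserved domain carrying the CSB-F, CSB-E and CSB-D blocks (the
mammalian CSB-B/C blocks are usually absent in fishes), and a conserved
sequence block domain carrying CSB-1, CSB-2 and CSB-3 near the replication
priming sites.  Blocks are located by scanning a consensus string over the
CR sense strand and keeping windows within a per-motif Hamming-mismatch
budget.

Note on "palindromic": the ETAS core TACATAT and its partner ATGTATA are
position-wise base complements of each other (no reversal).  That strict
complement relation - not the reverse-complement sense usual elsewhere in
molecular biology - is what ``check_palindrome_pair`` tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotifDef",
    "MotifHit",
    "CRAnnotation",
    "scan_motif",
    "annotate_cr",
    "check_palindrome_pair",
    "load_motifs",
    "DEFAULT_MOTIFS",
    "ETAS_PALINDROME",
    "CANONICAL_MOTIF_ORDER",
    "annotation_to_bed",
]

#: Block order along the CR expected in fishes (5' to 3' on the sense strand).
CANONICAL_MOTIF_ORDER = (
    "ETAS_core",
    "CSB-F",
    "CSB-E",
    "CSB-D",
    "CSB-1",
    "CSB-2",
    "CSB-3",
)


@dataclass(frozen=True)
class MotifDef:
    name: str
    consensus: str
    max_mismatch: int

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus) - set("ACGT"):
            raise ValueError(f"{self.name}: consensus must be non-empty uppercase ACGT")
        if not 0 <= self.max_mismatch < len(self.consensus):
            raise ValueError(f"{self.name}: max_mismatch must be < consensus length")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 1-based position within the CR
    mismatches: int


@dataclass
class CRAnnotation:
    """Best hit per motif plus the three inferred domains.

    ``domains`` maps domain name to a 1-based inclusive (start, end) interval;
    the three intervals tile the CR: ETAS domain up to just before CSB-F, the
    central conserved domain from CSB-F up to just before CSB-1, and the CSB
    domain from CSB-1 to the CR end.  ``partial`` is set when any motif of the
    supplied set was not found within its mismatch budget.
    """

    hits: dict[str, MotifHit] = field(default_factory=dict)
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    order_valid: bool = False
    partial: bool = False


_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_ENC[[ord(c) for c in "acgt"]] = np.arange(4)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = _ENC[arr].astype(np.int16)
    codes[~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))] = -1  # never matches
    return codes


def scan_motif(seq: str, motif: MotifDef) -> list[MotifHit]:
    """All windows of ``seq`` within the motif's Hamming budget.

    Hits are sorted by (mismatches, start); a consensus longer than the
    sequence yields an empty list.
    """
    m, n = len(motif), len(seq)
    if m > n:
        return []
    codes = _encode(seq)
    cons = _encode(motif.consensus)
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    mismatches = (windows != cons).sum(axis=1)
    idx = np.nonzero(mismatches <= motif.max_mismatch)[0]
    hits = [MotifHit(motif.name, int(i) + 1, int(mismatches[i])) for i in idx]
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def annotate_cr(cr_seq: str, motifs: list[MotifDef] | None = None) -> CRAnnotation:
    """Locate conserved blocks in a control-region sequence and infer domains.

    One best hit per motif (fewest mismatches, then leftmost).  Domains are
    only reported when their anchor blocks (CSB-F and CSB-1) were found.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    ann = CRAnnotation()
    for motif in motifs:
        found = scan_motif(cr_seq, motif)
        if found:
            ann.hits[motif.name] = found[0]
        else:
            ann.partial = True
    ordered = [ann.hits[n].start for n in CANONICAL_MOTIF_ORDER if n in ann.hits]
    ann.order_valid = (
        all(n in ann.hits for n in CANONICAL_MOTIF_ORDER)
        and ordered == sorted(ordered)
        and len(set(ordered)) == len(ordered)
    )
    if "CSB-F" in ann.hits and "CSB-1" in ann.hits:
        f_start = ann.hits["CSB-F"].start
        c1_start = ann.hits["CSB-1"].start
        if 1 < f_start < c1_start:
            ann.domains = {
                "ETAS_domain": (1, f_start - 1),
                "central_conserved_domain": (f_start, c1_start - 1),
                "CSB_domain": (c1_start, len(cr_seq)),
            }
    return ann


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def check_palindrome_pair(a: str, b: str) -> bool:
    """True iff ``b`` is the position-wise base complement of ``a`` (no reversal)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return a.upper().translate(_COMPLEMENT) == b.upper()


def load_motifs() -> list[MotifDef]:
    """Full motif set shipped with the package (including the ETAS palindrome)."""
    text = importlib.resources.files("mitochar").joinpath("data/motifs.tsv").read_text()
    motifs = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("Name\t"):
            continue
        name, consensus, budget = line.split("\t")
        motifs.append(MotifDef(name, consensus, int(budget)))
    return motifs


_ALL = load_motifs()
#: The seven ordered blocks used for domain annotation.
DEFAULT_MOTIFS = [m for m in _ALL if m.name in CANONICAL_MOTIF_ORDER]
ETAS_PALINDROME = next(m for m in _ALL if m.name == "ETAS_palindrome")


def annotation_to_bed(ann: CRAnnotation, chrom: str = "CR") -> str:
    """Domains and hits as BED lines (0-based half-open, as BED requires)."""
    lines = []
    for name, (start, end) in ann.domains.items():
        lines.append(f"{chrom}\t{start - 1}\t{end}\t{name}")
    for name, hit in sorted(ann.hits.items(), key=lambda kv: kv[1].start):
        motif_len = next((len(m) for m in _ALL if m.name == name), None)
        end = hit.start - 1 + (motif_len or 1)
        lines.append(f"{chrom}\t{hit.start - 1}\t{end}\t{name}\t{hit.mismatches}")
    return "\n".join(lines) + "\n"
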