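"""Circular mitogenome annotation records and accounting.

A vertebrate mitogenome is a circular molecule of roughly 16-17 kb carrying a
fixed complement of 37 genes (13 protein-coding, 22 tRNA, 2 rRNA) plus the
control region and the light-strand replication origin.  This module holds the
annotation data model (1-based, both-ends-inclusive coordinates, matching the
convention of published gene tables), TSV / GenBank / FASTA input, and the
bookkeeping that characterization reports are built from: feature lengths on
the circle, signed intergenic gaps (negative = overlap), spacer totals, strand
census and tRNA size range.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "FeatureClass",
    "GeneFeature",
    "MitoFeatureTable",
    "SpacerRecord",
    "FeatureTableError",
    "parse_feature_table",
    "write_feature_table",
    "load_canonical_table",
    "load_genbank",
    "read_genome_fasta",
    "feature_length",
    "infer_genome_length",
    "intergenic_gaps",
    "spacer_summary",
    "strand_census",
    "trna_size_range",
    "validate_table",
    "DEFAULT_SPACER_EXCLUDE",
]


class FeatureTableError(ValueError):
    """Raised on malformed feature tables or out-of-range coordinates."""


class FeatureClass(str, Enum):
    protein_coding = "protein_coding"
    tRNA = "tRNA"
    rRNA = "rRNA"
    control_region = "control_region"
    OL_origin = "OL_origin"


_VALID_STRANDS = {"H", "L"}
_VALID_STOPS = {"TAA", "TAG", "AGA", "TA", "T"}


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the circular molecule.

    ``start``/``end`` are 1-based and inclusive at both ends.  A feature may
    wrap across the origin only when ``wraps`` is set, in which case
    ``start > end`` is legal and the length runs through the join.
    """

    name: str
    feature_class: FeatureClass
    start: int
    end: int
    strand: str
    start_codon: str | None = None
    stop_codon: str | None = None
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise FeatureTableError(
                f"{self.name}: coordinates must be >= 1, got ({self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise FeatureTableError(f"{self.name}: unknown strand {self.strand!r}")
        if self.start > self.end and not self.wraps:
            raise FeatureTableError(
                f"{self.name}: start > end without the wrap flag "
                f"({self.start} > {self.end})"
            )
        if self.stop_codon is not None and self.stop_codon not in _VALID_STOPS:
            raise FeatureTableError(
                f"{self.name}: stop codon {self.stop_codon!r} not one of {sorted(_VALID_STOPS)}"
            )


@dataclass(frozen=True)
class SpacerRecord:
    """Signed gap between two features adjacent on the linearized circle.

    ``signed_gap = start(downstream) - end(upstream) - 1``: negative values are
    overlaps, zero means abutting, positive values are true spacers.
    """

    upstream_name: str
    downstream_name: str
    signed_gap: int


@dataclass
class MitoFeatureTable:
    """Ordered feature list for one mitogenome."""

    features: list[GeneFeature] = field(default_factory=list)
    genome_length: int | None = None

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise FeatureTableError(f"duplicate feature names: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, cls: FeatureClass) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class is cls]

    def sorted_by_start(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))


# ---------------------------------------------------------------------------
# I/O: TSV dialect, GenBank flat file, FASTA genome
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["Gene", "Class", "From", "To", "Strand", "StartCodon", "StopCodon"]


def parse_feature_table(text: str) -> MitoFeatureTable:
    """Parse the tab-separated gene-table dialect.

    Columns: Gene, Class, From, To, Strand, StartCodon, StopCodon.  Lines
    starting with ``#`` are comments; trailing empty codon columns may be
    omitted.  Errors name the offending row.
    """
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        return MitoFeatureTable([])
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip() for h in header[:5]] != _TSV_COLUMNS[:5]:
        raise FeatureTableError(
            f"unexpected header {header!r}; expected columns {_TSV_COLUMNS}"
        )
    feats: list[GeneFeature] = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.rstrip("\n").split("\t")
        cells += [""] * (len(_TSV_COLUMNS) - len(cells))
        name, cls, frm, to, strand, start_c, stop_c = (c.strip() for c in cells[:7])
        try:
            start, end = int(frm), int(to)
        except ValueError:
            raise FeatureTableError(
                f"row {i} ({name!r}): non-integer coordinates {frm!r}/{to!r}"
            ) from None
        try:
            fclass = FeatureClass(cls)
        except ValueError:
            raise FeatureTableError(f"row {i} ({name!r}): unknown class {cls!r}") from None
        try:
            feats.append(
                GeneFeature(
                    name=name,
                    feature_class=fclass,
                    start=start,
                    end=end,
                    strand=strand,
                    start_codon=start_c or None,
                    stop_codon=stop_c or None,
                )
            )
        except FeatureTableError as exc:
            raise FeatureTableError(f"row {i}: {exc}") from None
    table = MitoFeatureTable(feats)
    table.genome_length = infer_genome_length(table) if feats else None
    return table


def write_feature_table(table: MitoFeatureTable) -> str:
    """Serialize to the canonical TSV dialect (round-trips with the parser)."""
    out = ["\t".join(_TSV_COLUMNS)]
    for f in table.features:
        out.append(
            "\t".join(
                [
                    f.name,
                    f.feature_class.value,
                    str(f.start),
                    str(f.end),
                    f.strand,
                    f.start_codon or "",
                    f.stop_codon or "",
                ]
            )
        )
    return "\n".join(out) + "\n"


def load_canonical_table() -> MitoFeatureTable:
    """The published 38-row Chinese bahaba gene table shipped with the package."""
    text = (
        importlib.resources.files("mitochar")
        .joinpath("data/bahaba_features.tsv")
        .read_text()
    )
    return parse_feature_table(text)


_GENBANK_CLASS = {
    "CDS": FeatureClass.protein_coding,
    "tRNA": FeatureClass.tRNA,
    "rRNA": FeatureClass.rRNA,
    "D-loop": FeatureClass.control_region,
}


def load_genbank(path) -> MitoFeatureTable:
    """Read CDS/tRNA/rRNA/D-loop features from a GenBank flat file (read-only)."""
    record = SeqIO.read(path, "genbank")
    feats: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for gb in record.features:
        if gb.type not in _GENBANK_CLASS:
            continue
        name = (
            gb.qualifiers.get("gene", gb.qualifiers.get("product", [gb.type]))[0]
            .replace(" ", "_")
        )
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1:
            name = f"{name}.{seen[name]}"
        strand = "H" if (gb.location.strand or 1) >= 0 else "L"
        feats.append(
            GeneFeature(
                name=name,
                feature_class=_GENBANK_CLASS[gb.type],
                start=int(gb.location.start) + 1,  # GenBank parser is 0-based half-open
                end=int(gb.location.end),
                strand=strand,
            )
        )
    return MitoFeatureTable(feats, genome_length=len(record.seq))


def read_genome_fasta(path) -> str:
    """Read a single-record FASTA genome, uppercased."""
    record = SeqIO.read(path, "fasta")
    return str(record.seq).upper()


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------


def feature_length(f: GeneFeature, genome_length: int | None = None) -> int:
    """Length in bp of a feature on the circle (wrap-aware)."""
    if f.wraps or f.start > f.end:
        if genome_length is None:
            raise FeatureTableError(f"{f.name}: wrapping feature needs genome_length")
        if f.start > genome_length or f.end > genome_length:
            raise FeatureTableError(
                f"{f.name}: coordinates exceed genome length {genome_length}"
            )
        return genome_length - f.start + 1 + f.end
    if genome_length is not None and (f.start > genome_length or f.end > genome_length):
        raise FeatureTableError(
            f"{f.name}: coordinates exceed genome length {genome_length}"
        )
    return f.end - f.start + 1


def infer_genome_length(table: MitoFeatureTable) -> int:
    """Genome length as the maximum end coordinate over non-wrapping features."""
    ends = [f.end for f in table.features if not f.wraps]
    if not ends:
        raise FeatureTableError("cannot infer genome length from an empty table")
    return max(ends)


def intergenic_gaps(table: MitoFeatureTable, circular: bool = True) -> list[SpacerRecord]:
    """Signed gaps between start-sorted adjacent features.

    With ``circular`` and a known genome length, a closing record joining the
    last feature back to the first is appended.
    """
    feats = [f for f in table.sorted_by_start() if not f.wraps]
    records = [
        SpacerRecord(a.name, b.name, b.start - a.end - 1)
        for a, b in zip(feats, feats[1:])
    ]
    if circular and len(feats) >= 2 and table.genome_length:
        last, first = feats[-1], feats[0]
        records.append(
            SpacerRecord(
                last.name, first.name, table.genome_length - last.end + first.start - 1
            )
        )
    return records


#: The two locations the published spacer total leaves out: the replication-origin
#: gap between tRNA-Asn and tRNA-Cys, and the control region itself.
DEFAULT_SPACER_EXCLUDE = frozenset({"tRNA-Asn:tRNA-Cys", "D-loop"})


def spacer_summary(
    table: MitoFeatureTable, exclude: Iterable[str] = DEFAULT_SPACER_EXCLUDE
) -> tuple[int, int]:
    """Total bp and location count of strictly positive intergenic spacers.

    ``exclude`` entries are either feature names (any gap flanking that feature
    is skipped) or ``"upstream:downstream"`` pair keys naming one specific gap.
    """
    exclude = set(exclude)
    total = count = 0
    for rec in intergenic_gaps(table):
        if rec.signed_gap <= 0:
            continue
        if (
            rec.upstream_name in exclude
            or rec.downstream_name in exclude
            or f"{rec.upstream_name}:{rec.downstream_name}" in exclude
        ):
            continue
        total += rec.signed_gap
        count += 1
    return total, count


def strand_census(table: MitoFeatureTable) -> dict[tuple[FeatureClass, str], int]:
    """Counts of features per (class, strand)."""
    census: dict[tuple[FeatureClass, str], int] = {}
    for f in table.features:
        key = (f.feature_class, f.strand)
        census[key] = census.get(key, 0) + 1
    return census


def trna_size_range(table: MitoFeatureTable) -> tuple[int, int]:
    """(min, max) length over tRNA features."""
    trnas = table.by_class(FeatureClass.tRNA)
    if not trnas:
        raise FeatureTableError("no tRNA features in table")
    glen = table.genome_length
    sizes = [feature_length(f, glen) for f in trnas]
    return min(sizes), max(sizes)


_STOP_LEN = {"TAA": 3, "TAG": 3, "AGA": 3, "TA": 2, "T": 1}

_EXPECTED_COMPLEMENT = {
    FeatureClass.protein_coding: 13,
    FeatureClass.tRNA: 22,
    FeatureClass.rRNA: 2,
    FeatureClass.control_region: 1,
}


def validate_table(
    table: MitoFeatureTable,
    declared_sizes: Mapping[str, int] | None = None,
    expect_standard_complement: bool = True,
) -> list[str]:
    """Warn-level consistency checks; coordinates always win over declarations.

    Returns a list of human-readable warnings: deviations from the standard
    37-gene complement, declared stop codons inconsistent with length mod 3,
    and declared sizes (e.g. sizes quoted in a publication text) that differ
    from coordinate-derived lengths.
    """
    warnings: list[str] = []
    glen = table.genome_length
    if expect_standard_complement:
        counts: dict[FeatureClass, int] = {}
        for f in table.features:
            counts[f.feature_class] = counts.get(f.feature_class, 0) + 1
        for cls, expected in _EXPECTED_COMPLEMENT.items():
            got = counts.get(cls, 0)
            if got != expected:
                warnings.append(f"expected {expected} {cls.value} features, found {got}")
    for f in table.by_class(FeatureClass.protein_coding):
        if f.stop_codon is None:
            warnings.append(f"{f.name}: protein gene without a declared stop codon")
            continue
        length = feature_length(f, glen)
        if (length - _STOP_LEN[f.stop_codon]) % 3 != 0:
            warnings.append(
                f"{f.name}: declared stop {f.stop_codon} inconsistent with "
                f"length {length} (mod 3 = {length % 3})"
            )
    if declared_sizes:
        for name, declared in declared_sizes.items():
            try:
                f = table.get(name)
            except KeyError:
                warnings.append(f"declared size for unknown feature {name!r}")
                continue
            actual = feature_length(f, glen)
            if actual != declared:
                warnings.append(
                    f"{name}: declared size {declared} bp differs from "
                    f"coordinate-derived {actual} bp (coordinates win)"
                )
    return warnings
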