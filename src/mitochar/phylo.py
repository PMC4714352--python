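"""Partitioned supermatrix construction and distance/NJ phylogenetics.

Mitogenome phylogenies of fishes are commonly built from the concatenated
protein-coding and rRNA genes, with ND6 dropped for its anomalous base
composition, stop codons removed, and third codon positions excluded once a
saturation plot (transitions/transversions against p-distance) shows the
signal plateauing.  This module implements that preparation plus a
distance-based inference engine: p/JC69/K80 pairwise distances, neighbor
joining (delegated to scikit-bio), and a within-partition column bootstrap
summarized as a majority-rule consensus with percent support.  Bayesian and
maximum-likelihood inference are deliberately not provided; topology-level
claims are validated by simulation-recovery tests instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

__all__ = [
    "GeneAlignment",
    "PartitionedAlignment",
    "SaturationReport",
    "PairDivergence",
    "DistanceMatrix",
    "read_alignment",
    "strip_stops_and_nd6",
    "build_supermatrix",
    "write_partition_map",
    "saturation_stats",
    "pairwise_distance",
    "nj_tree",
    "bootstrap_consensus",
    "split_support",
    "has_split",
    "PhyloError",
]


class PhyloError(ValueError):
    pass


@dataclass
class GeneAlignment:
    """One per-gene multiple alignment (rows already aligned, equal length)."""

    gene: str
    kind: str  # "protein_coding" | "rRNA"
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if self.kind not in ("protein_coding", "rRNA"):
            raise PhyloError(f"{self.gene}: kind must be protein_coding or rRNA")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise PhyloError(f"{self.gene}: ragged alignment, row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def taxa(self) -> set[str]:
        return set(self.sequences)


@dataclass
class PartitionedAlignment:
    """Concatenated matrix with labeled, disjoint column partitions (0-based indices)."""

    matrix: dict[str, str]
    partitions: dict[str, np.ndarray]
    total_columns: int

    @property
    def taxa(self) -> list[str]:
        return list(self.matrix)

    def partition_sizes(self) -> dict[str, int]:
        return {k: int(v.size) for k, v in self.partitions.items()}


def read_alignment(path, gene: str, kind: str, fmt: str = "fasta") -> GeneAlignment:
    """Read a per-gene alignment from FASTA or relaxed PHYLIP."""
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
    aln = AlignIO.read(path, fmt)
    return GeneAlignment(gene, kind, {rec.id: str(rec.seq).upper() for rec in aln})


_STOP_TRIM = {0: 3, 2: 2, 1: 1}  # alignment length mod 3 -> terminal stop columns


def strip_stops_and_nd6(genes: Iterable[GeneAlignment]) -> list[GeneAlignment]:
    """Drop ND6 and trim the terminal (possibly incomplete) stop from protein genes."""
    out: list[GeneAlignment] = []
    for g in genes:
        if g.gene.upper().replace("-", "") == "ND6":
            continue
        if g.kind == "protein_coding":
            trim = _STOP_TRIM[g.length % 3]
            out.append(
                GeneAlignment(
                    g.gene, g.kind, {t: s[: len(s) - trim] for t, s in g.sequences.items()}
                )
            )
        else:
            out.append(g)
    return out


def build_supermatrix(genes: Sequence[GeneAlignment]) -> PartitionedAlignment:
    """Concatenate genes, keeping only 1st+2nd codon positions of protein genes.

    Partitions: ``codon1``, ``codon2`` (protein genes, stops assumed already
    stripped so lengths are codon-complete) and ``rRNA``.  Column indices refer
    to the concatenated (post-drop) matrix.
    """
    if not genes:
        raise PhyloError("no gene alignments supplied")
    shared = set.intersection(*(g.taxa for g in genes))
    for g in genes:
        missing = shared.symmetric_difference(g.taxa)
        if g.taxa != shared:
            raise PhyloError(
                f"taxon sets differ: gene {g.gene} vs shared set, offending taxa "
                f"{sorted(missing)}"
            )
    taxa = sorted(shared)
    parts: dict[str, list[int]] = {"codon1": [], "codon2": [], "rRNA": []}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    for g in genes:
        if g.kind == "protein_coding":
            if g.length % 3 != 0:
                raise PhyloError(
                    f"{g.gene}: protein alignment length {g.length} not codon-complete "
                    "(strip stops first)"
                )
            keep = [i for i in range(g.length) if i % 3 != 2]
            for t in taxa:
                row = g.sequences[t]
                chunks[t].append("".join(row[i] for i in keep))
            for k, i in enumerate(keep):
                parts["codon1" if i % 3 == 0 else "codon2"].append(offset + k)
            offset += len(keep)
        else:
            for t in taxa:
                chunks[t].append(g.sequences[t])
            parts["rRNA"].extend(range(offset, offset + g.length))
            offset += g.length
    return PartitionedAlignment(
        matrix={t: "".join(chunks[t]) for t in taxa},
        partitions={k: np.asarray(v, dtype=np.intp) for k, v in parts.items()},
        total_columns=offset,
    )


def write_partition_map(pa: PartitionedAlignment) -> str:
    """RAxML-style partition text ("DNA, codon1 = 1-10,13-14,...", 1-based)."""
    lines = []
    for name, idx in pa.partitions.items():
        if idx.size == 0:
            continue
        runs, start, prev = [], int(idx[0]), int(idx[0])
        for i in idx[1:]:
            i = int(i)
            if i == prev + 1:
                prev = i
                continue
            runs.append((start, prev))
            start = prev = i
        runs.append((start, prev))
        spans = ",".join(f"{a + 1}-{b + 1}" if a != b else f"{a + 1}" for a, b in runs)
        lines.append(f"DNA, {name} = {spans}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Divergence, saturation, distances
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_block(block: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Taxa (input order) and a uint8 matrix; gaps/ambiguities coded 255."""
    taxa = list(block)
    mat = np.vstack(
        [_CODE[np.frombuffer(block[t].encode(), dtype=np.uint8)] for t in taxa]
    )
    return taxa, mat


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    """(compared sites, transitions, transversions) under pairwise deletion."""
    ok = (x != 255) & (y != 255)
    xa, ya = x[ok], y[ok]
    diff = xa != ya
    # A=0,C=1,G=2,T=3: transitions are A<->G (0,2) and C<->T (1,3): same parity
    ts = int((diff & ((xa % 2) == (ya % 2))).sum())
    return int(ok.sum()), ts, int(diff.sum()) - ts


@dataclass(frozen=True)
class PairDivergence:
    taxon_a: str
    taxon_b: str
    sites: int
    p_distance: float
    s_proportion: float  # transitions / site
    v_proportion: float  # transversions / site


@dataclass
class SaturationReport:
    """Transition/transversion divergence per pair plus a plateau diagnostic.

    ``plateau_slope`` is the least-squares slope of transition proportion
    against JC-corrected divergence over the pairs in the upper half of the
    observed p range.  The corrected divergence is the right x-axis for a
    plateau test: observed proportions are bounded while the corrected
    distance keeps growing, so the slope decays toward zero as substitutions
    pile up.  A slope below ``threshold`` flags saturation; so does any pair
    whose observed divergence sits at or beyond the correction ceiling
    (p >= 3/4), which is saturation by definition.
    """

    pairs: list[PairDivergence]
    plateau_slope: float
    saturated: bool
    threshold: float
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)
    overflow_pairs: list[tuple[str, str]] = field(default_factory=list)


def saturation_stats(
    block: Mapping[str, str], threshold: float = 0.2
) -> SaturationReport:
    """Per-pair substitution proportions and the plateau-slope saturation flag."""
    taxa, mat = encode_block(block)
    if len(taxa) < 2:
        raise PhyloError("saturation check needs at least 2 taxa")
    pairs: list[PairDivergence] = []
    skipped: list[tuple[str, str]] = []
    overflow: list[tuple[str, str]] = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            sites, ts, tv = _pair_counts(mat[i], mat[j])
            if sites == 0:
                skipped.append((taxa[i], taxa[j]))
                continue
            p = (ts + tv) / sites
            if p >= 0.75:
                overflow.append((taxa[i], taxa[j]))
            pairs.append(
                PairDivergence(taxa[i], taxa[j], sites, p, ts / sites, tv / sites)
            )
    slope = float("nan")
    saturated = bool(overflow)
    if pairs and not overflow:
        p = np.array([x.p_distance for x in pairs])
        s = np.array([x.s_proportion for x in pairs])
        d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        cut = (p.min() + p.max()) / 2.0
        sel = p >= cut
        if sel.sum() >= 2 and np.ptp(d[sel]) > 0:
            slope = float(np.polyfit(d[sel], s[sel], 1)[0])
            saturated = slope < threshold
    return SaturationReport(pairs, slope, saturated, threshold, skipped, overflow)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances; saturation-overflow pairs listed in ``infinite_pairs``."""

    taxa: list[str]
    values: np.ndarray
    infinite_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise PhyloError("distance matrix shape does not match taxa")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite]) or np.any(np.diag(v) != 0):
            raise PhyloError("distance matrix must be symmetric with zero diagonal")
        self.values = v


def _model_distance(sites: int, ts: int, tv: int, model: str) -> float:
    p = (ts + tv) / sites
    if model == "p":
        return p
    if model == "jc69":
        arg = 1.0 - 4.0 * p / 3.0
        return float("inf") if arg <= 0 else -0.75 * np.log(arg)
    if model == "k80":
        P, Q = ts / sites, tv / sites
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return float("inf")
        return float(-0.5 * np.log(a1) - 0.25 * np.log(a2))
    raise PhyloError(f"unknown model {model!r} (choose p, jc69 or k80)")


def pairwise_distance(block: Mapping[str, str], model: str = "jc69") -> DistanceMatrix:
    """Pairwise distances under p, JC69 or K80, with pairwise deletion of gaps."""
    taxa, mat = encode_block(block)
    if len(taxa) < 2:
        raise PhyloError("need at least 2 taxa")
    n = len(taxa)
    d = np.zeros((n, n))
    infinite: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            sites, ts, tv = _pair_counts(mat[i], mat[j])
            if sites == 0:
                raise PhyloError(f"no comparable sites for pair ({taxa[i]}, {taxa[j]})")
            val = _model_distance(sites, ts, tv, model.lower())
            if not np.isfinite(val):
                infinite.append((taxa[i], taxa[j]))
            d[i, j] = d[j, i] = val
    return DistanceMatrix(taxa, d, infinite)


# ---------------------------------------------------------------------------
# Tree inference
# ---------------------------------------------------------------------------


def nj_tree(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Neighbor-joining tree (scikit-bio agglomeration); negative branches clamped to 0."""
    if len(dm.taxa) < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    if dm.infinite_pairs:
        raise PhyloError(f"matrix has non-finite distances for pairs {dm.infinite_pairs}")
    sk = _skbio_nj(_SkbioDM(dm.values, ids=dm.taxa))
    tree = dendropy.Tree.get(
        data=str(sk),
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )
    clamped = False
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0", stacklevel=2)
    tree.is_rooted = False
    return tree


def _nontrivial_split_masks(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    n_leaves = len(tree.taxon_namespace)
    masks = set()
    for bp in tree.bipartition_encoding:
        size = bin(bp.leafset_bitmask).count("1")
        if 1 < size < n_leaves - 1:
            masks.add(bp.split_bitmask)
    return masks


def split_support(tree: dendropy.Tree, labels: Iterable[str]) -> float | None:
    """Support (%) of the unrooted split separating ``labels`` from the rest.

    Matches either orientation of the bipartition; returns None when the tree
    does not contain the split.  For trees without bootstrap annotation the
    split's presence is reported as 100.0 (it is in the single tree given).
    """
    want = frozenset(labels)
    every = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if not want < every:
        raise PhyloError(f"labels {sorted(want - every)} not in tree")
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if side == want or side == every - want:
            support = getattr(node, "support", None)
            if support is None and node.label is not None:
                try:
                    support = float(node.label)
                except ValueError:
                    support = None
            return 100.0 if support is None else float(support)
    return None


def has_split(tree: dendropy.Tree, labels: Iterable[str]) -> bool:
    """True iff the unrooted split separating ``labels`` is in the tree."""
    return split_support(tree, labels) is not None


def bootstrap_consensus(
    pa: PartitionedAlignment,
    n_reps: int,
    seed: int,
    model: str = "jc69",
) -> dendropy.Tree:
    """Within-partition column bootstrap; majority-rule consensus with % support.

    Columns are resampled with replacement inside each partition so every
    replicate keeps the partition sizes; each replicate is analyzed by the
    same distance + NJ route as the original data.  Internal edges of the 50%
    majority-rule consensus carry support as a percentage of replicates
    containing the split (stored as node labels and ``support`` attributes).
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    taxa, mat = encode_block(pa.matrix)
    tns = dendropy.TaxonNamespace(taxa)
    counts: dict[int, int] = {}
    replicates = dendropy.TreeList(taxon_namespace=tns)
    for _ in range(n_reps):
        cols = np.concatenate(
            [rng.choice(idx, size=idx.size, replace=True) for idx in pa.partitions.values()]
        )
        sub = mat[:, cols]
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                sites, ts, tv = _pair_counts(sub[i], sub[j])
                if sites == 0:
                    raise PhyloError(f"bootstrap pair ({taxa[i]}, {taxa[j]}) has no sites")
                d[i, j] = d[j, i] = _model_distance(sites, ts, tv, model.lower())
        if not np.all(np.isfinite(d)):
            raise PhyloError("non-finite bootstrap distances; sequences too divergent")
        rep = nj_tree(DistanceMatrix(taxa, d), taxon_namespace=tns)
        replicates.append(rep)
        for mask in _nontrivial_split_masks(rep):
            counts[mask] = counts.get(mask, 0) + 1
    consensus = replicates.consensus(min_freq=0.5)
    consensus.encode_bipartitions()
    n_leaves = len(tns)
    for edge in consensus.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        size = bin(edge.bipartition.leafset_bitmask).count("1")
        if 1 < size < n_leaves - 1:
            support = 100.0 * counts.get(edge.bipartition.split_bitmask, 0) / n_reps
            edge.head_node.label = f"{support:.0f}"
            edge.head_node.support = support
    consensus.is_rooted = False
    return consensus
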