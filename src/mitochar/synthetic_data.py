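"""Synthetic mitogenomes and alignments with recorded ground truth.

Every downstream stage is exercised on data whose truth is known by
construction: a 16.5-kb circular genome laid out with the canonical 37-gene
vertebrate order, i.i.d. background bases drawn from a target composition,
ATG starts and declared (possibly incomplete) stops written into protein
genes, the seven control-region blocks planted at recorded offsets in a
motif-free background, and a stem-loop of exact geometry written into the
replication-origin gap.  Alignments are evolved site-independently along a
known tree under JC69/K80/HKY with per-partition rate multipliers.  All
generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.linalg import expm

from .control_region import DEFAULT_MOTIFS, ETAS_PALINDROME, MotifDef, scan_motif
from .feature_table import (
    FeatureClass,
    MitoFeatureTable,
    feature_length,
    load_canonical_table,
)
from .phylo import GeneAlignment, PhyloError
from .structure import find_best_hairpin, locate_OL

__all__ = [
    "GenomeSpec",
    "SimSpec",
    "generate_mitogenome",
    "simulate_alignment",
    "DEFAULT_CR_OFFSETS",
    "STUDY_TREE",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGT", "TGCA")

#: Default control-region offsets (1-based within the 826-bp CR), canonical order.
DEFAULT_CR_OFFSETS: dict[str, int] = {
    "ETAS_core": 20,
    "ETAS_palindrome": 27,
    "CSB-F": 280,
    "CSB-E": 380,
    "CSB-D": 450,
    "CSB-1": 600,
    "CSB-2": 680,
    "CSB-3": 730,
}

#: An 11-taxon sciaenid-like topology with internal edges long enough for
#: confident recovery; branch lengths in substitutions/site.
STUDY_TREE = (
    "(Parapristipoma_trilineatum:0.15,(Dendrophysa_russelii:0.12,"
    "((Pennahia_argentata:0.06,(Nibea_albiflora:0.05,Nibea_coibor:0.05):0.03):0.04,"
    "(((Larimichthys_crocea:0.04,Larimichthys_polyactis:0.04):0.03,"
    "(Collichthys_lucida:0.03,Collichthys_niveatus:0.03):0.03):0.03,"
    "(Bahaba_taipingensis:0.05,Miichthys_miiuy:0.05):0.03):0.04):0.05):0.03);"
)


@dataclass
class GenomeSpec:
    """Recipe for one synthetic mitogenome.

    ``target_composition`` is (T, C, A, G) in percent; the default is the
    published overall row of the Chinese bahaba genome.  ``planted_hairpin``
    is (stem_pairs, loop_len, five_tail) and must fit the Asn-Cys gap of the
    layout.  Offsets in ``cr_offsets`` are 1-based within the control region.
    """

    layout: MitoFeatureTable = field(default_factory=load_canonical_table)
    target_composition: tuple[float, float, float, float] = (25.1, 31.4, 27.6, 15.9)
    motifs: list[MotifDef] = field(
        default_factory=lambda: list(DEFAULT_MOTIFS) + [ETAS_PALINDROME]
    )
    cr_offsets: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CR_OFFSETS))
    planted_hairpin: tuple[int, int, int] = (10, 13, 4)
    seed: int = 42

    def __post_init__(self) -> None:
        if abs(sum(self.target_composition) - 100.0) > 1e-6:
            raise ValueError("target composition percentages must sum to 100")


def _base_probs(spec: GenomeSpec) -> np.ndarray:
    t, c, a, g = (x / 100.0 for x in spec.target_composition)
    return np.array([a, c, g, t])  # ACGT order


def _write_coding(genome: np.ndarray, feat, coding_offset: int, text: str) -> None:
    """Write ``text`` at a coding-strand offset (0-based) of a feature, strand-aware."""
    for i, base in enumerate(text):
        k = coding_offset + i
        if feat.strand == "H":
            pos = feat.start - 1 + k
            genome[pos] = ord(base)
        else:
            pos = feat.end - 1 - k
            genome[pos] = ord(base.translate(_COMP))


def _hairpin_sequence(stem: int, loop: int, five_tail: int, total: int) -> str:
    """Deterministic sequence whose unique maximal hairpin has the given geometry.

    Alphabet blocks A^f C^s T^l G^s A^rest: the only Watson-Crick stem of
    length ``stem`` pairs the C-run against the G-run, provided the A/T runs
    are shorter than the stem or the loop keeps them apart.
    """
    rest = total - five_tail - 2 * stem - loop
    if rest < 0:
        raise ValueError(
            f"hairpin geometry ({stem} pairs, {loop} loop, {five_tail} tail) "
            f"does not fit in {total} nt"
        )
    return "A" * five_tail + "C" * stem + "T" * loop + "G" * stem + "A" * rest


def _motif_free_background(
    rng: np.random.Generator, length: int, probs: np.ndarray, motifs: list[MotifDef]
) -> str:
    for _ in range(200):
        seq = bytes(rng.choice(_BASES, size=length, p=probs)).decode()
        if all(not scan_motif(seq, m) for m in motifs):
            return seq
    raise RuntimeError("could not sample a motif-free control-region background")


def generate_mitogenome(
    spec: GenomeSpec | None = None, seed: int | None = None
) -> tuple[str, MitoFeatureTable, dict]:
    """Synthesize (genome sequence, feature table, truth record).

    The truth record stores everything planted: motif offsets (CR-local and
    genome coordinates), hairpin geometry and the O_L interval, the target
    composition, and per-feature lengths.
    """
    spec = spec or GenomeSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    table = spec.layout
    glen = table.genome_length
    if glen is None:
        raise ValueError("layout must carry a genome length")
    for f in table.features:
        if f.end > glen:
            raise ValueError(f"feature {f.name} exceeds genome length {glen}")
    probs = _base_probs(spec)
    genome = np.array(
        bytearray(bytes(rng.choice(_BASES, size=glen, p=probs))), dtype=np.uint8
    )

    # protein genes: ATG start, declared stop at the coding 3' end
    for f in table.by_class(FeatureClass.protein_coding):
        length = feature_length(f, glen)
        stop = f.stop_codon or "TAA"
        _write_coding(genome, f, 0, f.start_codon or "ATG")
        _write_coding(genome, f, length - len(stop), stop)

    # control region: motif-free background, then the planted blocks
    cr = table.by_class(FeatureClass.control_region)[0]
    cr_len = feature_length(cr, glen)
    motif_truth: dict[str, dict] = {}
    for _ in range(50):
        background = _motif_free_background(rng, cr_len, probs, spec.motifs)
        cr_seq = bytearray(background.encode())
        for m in spec.motifs:
            off = spec.cr_offsets[m.name]
            if off + len(m) - 1 > cr_len:
                raise ValueError(f"motif {m.name} at offset {off} exceeds the CR")
            cr_seq[off - 1 : off - 1 + len(m)] = m.consensus.encode()
        cr_str = cr_seq.decode()
        # planting may create incidental cross-motif matches; require each
        # planted copy to be the unique best hit, else resample background
        ok = all(
            [h for h in scan_motif(cr_str, m) if h.mismatches == 0]
            == [h for h in scan_motif(cr_str, m) if h.start == spec.cr_offsets[m.name]]
            for m in spec.motifs
        )
        if ok:
            break
    else:
        raise RuntimeError("could not plant motifs uniquely in the control region")
    genome[cr.start - 1 : cr.end] = np.frombuffer(cr_str.encode(), dtype=np.uint8)
    for m in spec.motifs:
        off = spec.cr_offsets[m.name]
        motif_truth[m.name] = {"cr_offset": off, "genome_start": cr.start + off - 1}

    # replication-origin gap: hairpin of exact geometry
    ol_start, ol_end, ol_len = locate_OL(table)
    stem, loop, tail5 = spec.planted_hairpin
    ol_seq = _hairpin_sequence(stem, loop, tail5, ol_len)
    genome[ol_start - 1 : ol_end] = np.frombuffer(ol_seq.encode(), dtype=np.uint8)
    found = find_best_hairpin(ol_seq, min_stem=3, min_loop=3, max_loop=max(30, loop))
    if found is None or (found.stem_pairs, found.loop_len) != (stem, loop):
        raise ValueError(
            f"planted hairpin geometry {spec.planted_hairpin} is not the maximal "
            f"structure of its own sequence (found {found})"
        )

    seq = genome.tobytes().decode()
    truth = {
        "seed": spec.seed,
        "genome_length": glen,
        "target_composition": dict(
            zip("TCAG", (float(x) for x in spec.target_composition))
        ),
        "feature_lengths": {f.name: feature_length(f, glen) for f in table.features},
        "cr": {"start": cr.start, "end": cr.end, "motifs": motif_truth},
        "hairpin": {
            "stem_pairs": stem,
            "loop_len": loop,
            "five_tail": tail5,
            "three_tail": ol_len - tail5 - 2 * stem - loop,
            "ol_start": ol_start,
            "ol_end": ol_end,
        },
    }
    return seq, table, truth


# ---------------------------------------------------------------------------
# Alignment simulation along a known tree
# ---------------------------------------------------------------------------


@dataclass
class SimSpec:
    """Recipe for simulating per-gene alignments along a tree.

    ``genes`` lists (name, kind, aligned length); protein sites take the
    codon1/codon2/codon3 rate multipliers by position, rRNA sites the rRNA
    multiplier.  ``base_freqs`` are stationary (A, C, G, T) frequencies (HKY
    only; JC69/K80 are uniform).
    """

    tree: str
    genes: list[tuple[str, str, int]] = field(
        default_factory=lambda: [("gene1", "protein_coding", 300)]
    )
    model: str = "JC69"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    partition_rate_multipliers: dict[str, float] = field(
        default_factory=lambda: {"codon1": 1.0, "codon2": 1.0, "codon3": 1.0, "rRNA": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model.upper() not in ("JC69", "K80", "HKY"):
            raise ValueError(f"unknown model {self.model!r}")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if any(m <= 0 for m in self.partition_rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")


def _rate_matrix(spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Normalized HKY-family generator (expected 1 substitution/site/unit) + freqs."""
    model = spec.model.upper()
    if model == "JC69":
        freqs, kappa = np.full(4, 0.25), 1.0
    elif model == "K80":
        freqs, kappa = np.full(4, 0.25), spec.kappa
    else:
        freqs, kappa = np.asarray(spec.base_freqs, dtype=float), spec.kappa
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T in ACGT order
    for i in range(4):
        for j in range(4):
            if i != j:
                q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
        q[i, i] = -q[i].sum()
    mu = -float(np.dot(freqs, np.diag(q)))
    return q / mu, freqs


def simulate_alignment(spec: SimSpec) -> tuple[list[GeneAlignment], dendropy.Tree]:
    """Evolve sequences site-independently along the tree; returns genes + truth tree."""
    try:
        tree = dendropy.Tree.get(
            data=spec.tree, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise PhyloError(f"malformed Newick tree: {exc}") from exc
    rng = np.random.default_rng(spec.seed)
    q, freqs = _rate_matrix(spec)

    mult = spec.partition_rate_multipliers
    rates: list[float] = []
    for _name, kind, length in spec.genes:
        if kind == "protein_coding":
            per_codon = [mult["codon1"], mult["codon2"], mult["codon3"]]
            rates.extend(per_codon[i % 3] for i in range(length))
        else:
            rates.extend([mult["rRNA"]] * length)
    rates_arr = np.asarray(rates)
    n_sites = rates_arr.size
    unique_rates = np.unique(rates_arr)
    cat_masks = {r: rates_arr == r for r in unique_rates}

    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.choice(4, size=n_sites, p=freqs)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = seqs[id(node.parent_node)]
        b = node.edge.length or 0.0
        child = parent.copy()
        if b > 0:
            for r, mask in cat_masks.items():
                p_mat = expm(q * b * r)
                p_mat = np.clip(p_mat, 0, None)
                p_mat /= p_mat.sum(axis=1, keepdims=True)
                sub = parent[mask]
                new = np.empty_like(sub)
                for base in range(4):
                    sel = sub == base
                    if sel.any():
                        new[sel] = rng.choice(4, size=int(sel.sum()), p=p_mat[base])
                idx = np.nonzero(mask)[0]
                child[idx] = new
        seqs[id(node)] = child

    leaf_seqs = {
        leaf.taxon.label: seqs[id(leaf)] for leaf in tree.leaf_node_iter()
    }
    genes: list[GeneAlignment] = []
    offset = 0
    decode = np.array(list("ACGT"))
    for name, kind, length in spec.genes:
        block = {
            taxon: "".join(decode[arr[offset : offset + length]])
            for taxon, arr in leaf_seqs.items()
        }
        genes.append(GeneAlignment(name, kind, block))
        offset += length
    return genes, tree
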