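"""Orchestration of characterization and phylogenetics runs.

``run_characterize`` assembles the full report bundle for one genome +
feature table (gene accounting, composition/skew, control-region annotation,
O_L hairpin); ``run_phylo`` runs strip -> supermatrix -> saturation ->
distances -> NJ -> bootstrap.  Every reported number is produced by exactly
one stage function from the library modules; the reporters only format.

Errors are split into configuration problems (:class:`PipelineConfigError`,
CLI exit 1) and data validation failures (:class:`DataValidationError`,
CLI exit 2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import composition as comp
from . import control_region as cr_mod
from . import feature_table as ft
from . import phylo as ph
from . import structure as st

log = logging.getLogger("mitochar")

__all__ = [
    "RunConfig",
    "PipelineConfigError",
    "DataValidationError",
    "run_characterize",
    "run_phylo",
]


class PipelineConfigError(Exception):
    """Unusable configuration: missing files, contradictory options."""


class DataValidationError(Exception):
    """Inputs parsed but are mutually inconsistent or malformed."""


@dataclass
class RunConfig:
    genome: Path | None = None
    features: Path | None = None
    genbank: Path | None = None
    motifs: Path | None = None
    out_dir: Path | None = None
    min_stem: int = 3
    min_loop: int = 3
    max_loop: int = 30
    allow_gu: bool = False
    model: str = "jc69"
    bootstrap: int = 100
    seed: int | None = None
    #: (path, gene name, kind, format) per alignment
    alignments: list[tuple[str, str, str, str]] = field(default_factory=list)

    def validate_paths(self, require: tuple[str, ...] = ()) -> None:
        for attr in ("genome", "features", "genbank", "motifs"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise PipelineConfigError(f"{attr} file not found: {p}")
        for name in require:
            if getattr(self, name) is None:
                raise PipelineConfigError(f"--{name} is required for this command")
        for path, gene, _kind, _fmt in self.alignments:
            if not Path(path).exists():
                raise PipelineConfigError(f"alignment file for {gene} not found: {path}")
        if self.bootstrap and self.alignments and self.seed is None:
            raise PipelineConfigError("--seed is required when bootstrapping")


def _load_table(cfg: RunConfig) -> ft.MitoFeatureTable:
    if cfg.features is not None:
        try:
            return ft.parse_feature_table(Path(cfg.features).read_text())
        except ft.FeatureTableError as exc:
            raise DataValidationError(str(exc)) from exc
    if cfg.genbank is not None:
        return ft.load_genbank(cfg.genbank)
    raise PipelineConfigError("a feature table (--features or --genbank) is required")


def run_characterize(cfg: RunConfig) -> dict:
    """Characterization bundle; composition stages are skipped without a genome."""
    cfg.validate_paths()
    table = _load_table(cfg)
    glen = table.genome_length
    genome = None
    if cfg.genome is not None:
        genome = ft.read_genome_fasta(cfg.genome)
        if glen is not None and len(genome) != glen:
            raise DataValidationError(
                f"genome is {len(genome)} bp but the feature table implies {glen} bp"
            )
    log.info("characterizing %d features, genome length %s", len(table), glen)

    gene_rows = []
    gaps = {r.upstream_name: r.signed_gap for r in ft.intergenic_gaps(table)}
    for f in table.sorted_by_start():
        length = ft.feature_length(f, glen)
        row = {
            "Gene": f.name,
            "Class": f.feature_class.value,
            "From": f.start,
            "To": f.end,
            "Strand": f.strand,
            "Size_bp": length,
            "StartCodon": f.start_codon or "",
            "StopCodon": f.stop_codon or "",
            "Intergenic": gaps.get(f.name, ""),
        }
        if f.feature_class is ft.FeatureClass.protein_coding and f.stop_codon:
            row["AminoAcids"] = comp.amino_acid_count(length, f.stop_codon)
        gene_rows.append(row)
    gene_report = pd.DataFrame(gene_rows)

    total, count = ft.spacer_summary(table)
    census = {
        f"{cls.value}:{strand}": n for (cls, strand), n in ft.strand_census(table).items()
    }
    bundle: dict = {
        "genome_length": glen,
        "gene_report": gene_report,
        "spacer_total_bp": total,
        "spacer_locations": count,
        "strand_census": census,
        "trna_size_range": ft.trna_size_range(table),
        "validation_warnings": ft.validate_table(table),
    }

    if genome is None:
        bundle["notice"] = "no genome sequence given; composition stages skipped"
        log.info("composition stages skipped (no sequence)")
    else:
        bundle["composition"] = comp.composition_report(genome, table)
        overall = comp.base_composition(genome)
        bundle["skew"] = comp.skew(overall)
        motifs = None
        if cfg.motifs is not None:
            motifs = [
                cr_mod.MotifDef(n, c, int(k))
                for n, c, k in (
                    ln.split("\t")
                    for ln in Path(cfg.motifs).read_text().splitlines()
                    if ln.strip() and not ln.startswith(("#", "Name\t"))
                )
            ]
        crs = table.by_class(ft.FeatureClass.control_region)
        if crs:
            f = crs[0]
            cr_seq = comp.extract_feature_seq(genome, f.start, f.end, f.strand)
            bundle["cr_annotation"] = cr_mod.annotate_cr(cr_seq, motifs)
        ol_start, ol_end, ol_len = st.locate_OL(table)
        ol_seq = comp.extract_feature_seq(genome, ol_start, ol_end, "H")
        bundle["ol"] = {"start": ol_start, "end": ol_end, "length": ol_len}
        bundle["ol_hairpin"] = st.find_best_hairpin(
            ol_seq,
            min_stem=cfg.min_stem,
            min_loop=cfg.min_loop,
            max_loop=cfg.max_loop,
            allow_gu=cfg.allow_gu,
        )
        bundle["ol_seq"] = ol_seq

    if cfg.out_dir is not None:
        _write_characterize(cfg, bundle)
    return bundle


def _jsonify(obj):
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _write_characterize(cfg: RunConfig, bundle: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["gene_report"].to_csv(out / "gene_report.tsv", sep="\t", index=False)
    summary = {
        k: _jsonify(v)
        for k, v in bundle.items()
        if k
        in (
            "genome_length",
            "spacer_total_bp",
            "spacer_locations",
            "strand_census",
            "trna_size_range",
            "validation_warnings",
            "ol",
            "notice",
        )
    }
    if "skew" in bundle:
        summary["gc_skew"], summary["at_skew"] = bundle["skew"].rounded()
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    if "composition" in bundle:
        df = bundle["composition"]
        rounding = {c: (3 if c.endswith("skew") else 1) for c in df.columns if c != "N"}
        df.round(rounding).to_csv(out / "composition.tsv", sep="\t")  # printed rendering
        (out / "composition.json").write_text(df.to_json(orient="index", indent=2))
    if "cr_annotation" in bundle:
        ann = bundle["cr_annotation"]
        (out / "cr_annotation.json").write_text(json.dumps(_jsonify(ann), indent=2) + "\n")
        (out / "cr_annotation.bed").write_text(cr_mod.annotation_to_bed(ann))
    if bundle.get("ol_hairpin") is not None:
        hp = bundle["ol_hairpin"]
        (out / "ol_hairpin.json").write_text(st.hairpin_to_json(hp) + "\n")
        (out / "ol_hairpin.txt").write_text(st.render_hairpin(bundle["ol_seq"], hp))
    log.info("characterization report written to %s", out)


def run_phylo(cfg: RunConfig, genes: list[ph.GeneAlignment] | None = None) -> dict:
    """Tree bundle: partition map, saturation report, Newick with supports, provenance."""
    if genes is None:
        cfg.validate_paths()
        if not cfg.alignments:
            raise PipelineConfigError("no alignments given")
        genes = [
            ph.read_alignment(path, gene, kind, fmt)
            for path, gene, kind, fmt in cfg.alignments
        ]
    try:
        stripped = ph.strip_stops_and_nd6(genes)
        pa = ph.build_supermatrix(stripped)
        log.info(
            "supermatrix: %d taxa x %d columns, partitions %s",
            len(pa.taxa),
            pa.total_columns,
            pa.partition_sizes(),
        )
        saturation = ph.saturation_stats(pa.matrix)
        dm = ph.pairwise_distance(pa.matrix, model=cfg.model)
        if cfg.bootstrap >= 1:
            if cfg.seed is None:
                raise PipelineConfigError("--seed is required when bootstrapping")
            tree = ph.bootstrap_consensus(pa, cfg.bootstrap, seed=cfg.seed, model=cfg.model)
        else:
            tree = ph.nj_tree(dm)
        newick = tree.as_string(schema="newick", suppress_rooting=True)
    except ph.PhyloError as exc:
        raise DataValidationError(str(exc)) from exc
    bundle = {
        "partition_sizes": pa.partition_sizes(),
        "partition_map": ph.write_partition_map(pa),
        "saturation": saturation,
        "distance_matrix": dm,
        "tree": tree,
        "newick": newick,
        "provenance": {
            "seed": cfg.seed,
            "model": cfg.model,
            "bootstrap_replicates": cfg.bootstrap,
        },
    }
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "partitions.txt").write_text(bundle["partition_map"])
        (out / "tree.nwk").write_text(newick)
        sat = pd.DataFrame([_jsonify(p) for p in saturation.pairs])
        sat.to_csv(out / "saturation.tsv", sep="\t", index=False)
        (out / "provenance.json").write_text(
            json.dumps(
                {
                    **bundle["provenance"],
                    "partition_sizes": bundle["partition_sizes"],
                    "plateau_slope": saturation.plateau_slope,
                    "saturated": saturation.saturated,
                },
                indent=2,
            )
            + "\n"
        )
        log.info("phylogenetics bundle written to %s", out)
    return bundle
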