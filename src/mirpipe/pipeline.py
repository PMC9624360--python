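"""End-to-end pipeline: config validation, stage chaining, manifest.

Stage order follows the data dependencies: differential expression first,
then peak annotation intersected with the DE calls, then the target
network, then the survival screen (restricted, by default, to the DE
miRNA panel). Each stage writes its outputs before the next starts, so a
failing stage leaves completed artifacts intact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__, io, microarray, network, peaks, surv

log = logging.getLogger("mirpipe")


class ConfigValidationError(ValueError):
    """Aggregated config problems; .problems lists every violation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid pipeline config:\n  " + "\n  ".join(problems))


@dataclass
class PipelineConfig:
    # inputs
    expression: str = ""
    dabg: str = ""
    samples: str = ""
    genes: str = ""
    gene_mirna_map: str = ""
    peaks: dict[str, str] = field(default_factory=dict)  # "cell:rep" -> path
    interactions: str = ""
    genesets: str = ""
    oncogenes: str = ""
    tsgs: str = ""
    clinical: str = ""
    # stage parameters
    dabg_alpha: float = 0.05
    diff_threshold: float = 1.0
    fdr_alpha: float = 0.05
    grouping: str = "two_group"
    window_bp: int = 50_000
    background_size: int = network.DEFAULT_BACKGROUND_SIZE
    enrichment_query: str = "union"  # union | unique
    cut_low: float = surv.CUT_LOW_DEFAULT
    cut_high: float = surv.CUT_HIGH_DEFAULT
    alpha: float = 0.05
    survival_panel: str = "de"  # de | all
    skip: list[str] = field(default_factory=list)
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigValidationError([f"unknown config key(s): {sorted(unknown)}"])
        return cls(**raw)


_STAGES = ("de", "annotate", "network", "survival")


def validate_config(cfg: PipelineConfig) -> PipelineConfig:
    """Check every path and parameter; report all problems at once."""
    problems: list[str] = []

    def need_file(name: str, path: str):
        if not path:
            problems.append(f"{name}: path not set")
        elif not Path(path).is_file():
            problems.append(f"{name}: file not found: {path}")

    skip = set(cfg.skip)
    unknown = skip - set(_STAGES)
    if unknown:
        problems.append(f"skip: unknown stage(s) {sorted(unknown)}")
    if "de" not in skip:
        for name in ("expression", "dabg", "samples"):
            need_file(name, getattr(cfg, name))
    if "annotate" not in skip:
        need_file("genes", cfg.genes)
        need_file("gene_mirna_map", cfg.gene_mirna_map)
        if not cfg.peaks:
            problems.append("peaks: no peak files configured")
        for key, path in cfg.peaks.items():
            if ":" not in key:
                problems.append(f"peaks: key {key!r} must be 'cell_line:replicate'")
            need_file(f"peaks[{key}]", path)
    if "network" not in skip:
        need_file("interactions", cfg.interactions)
        need_file("genesets", cfg.genesets)
        need_file("oncogenes", cfg.oncogenes)
        need_file("tsgs", cfg.tsgs)
    if "survival" not in skip:
        need_file("clinical", cfg.clinical)

    for name in ("dabg_alpha", "fdr_alpha", "alpha"):
        v = getattr(cfg, name)
        if not 0 < v < 1:
            problems.append(f"{name}: must be in (0,1), got {v}")
    if cfg.diff_threshold <= 0:
        problems.append(f"diff_threshold: must be > 0, got {cfg.diff_threshold}")
    if cfg.window_bp <= 0:
        problems.append(f"window_bp: must be > 0, got {cfg.window_bp}")
    if cfg.background_size <= 0:
        problems.append(f"background_size: must be > 0, got {cfg.background_size}")
    if cfg.cut_low >= cfg.cut_high:
        problems.append(f"cut_low {cfg.cut_low} must be < cut_high {cfg.cut_high}")
    if cfg.grouping not in ("two_group", "four_group"):
        problems.append(f"grouping: unknown value {cfg.grouping!r}")
    if cfg.enrichment_query not in ("union", "unique"):
        problems.append(f"enrichment_query: unknown value {cfg.enrichment_query!r}")
    if cfg.survival_panel not in ("de", "all"):
        problems.append(f"survival_panel: unknown value {cfg.survival_panel!r}")

    if problems:
        raise ConfigValidationError(problems)
    return cfg


def _load_matrix(cfg: PipelineConfig) -> microarray.ProbesetMatrix:
    expr = io.read_expression(cfg.expression)
    dabg = io.read_expression(cfg.dabg)
    meta = io.read_sample_meta(cfg.samples)
    sample_cols = meta["sample_id"].tolist()
    return microarray.ProbesetMatrix(
        intensities=expr[sample_cols].astype(float),
        dabg_p=dabg[sample_cols].astype(float),
        probe_class=expr["probe_class"],
        samples=meta,
    )


def run_all(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    validate_config(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = set(cfg.skip)
    started = datetime.now(timezone.utc).isoformat()
    counts: dict[str, dict] = {}
    caught: list[str] = []

    de_cfg = microarray.DEConfig(
        dabg_alpha=cfg.dabg_alpha,
        diff_threshold=cfg.diff_threshold,
        fdr_alpha=cfg.fdr_alpha,
        grouping=cfg.grouping,
    )

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        de = None
        if "de" not in skip:
            log.info("[de] normalizing and testing")
            matrix = _load_matrix(cfg)
            normalized = microarray.normalize(matrix, de_cfg)
            de = microarray.call_de(microarray.tukey_hsd(normalized, de_cfg), de_cfg)
            de.to_csv(outdir / "de_results.tsv", sep="\t")
            microarray.ma_table(normalized, de).to_csv(
                outdir / "ma_table.tsv", sep="\t"
            )
            counts["de"] = {
                "probesets_in": int(len(matrix.intensities)),
                "expressed": int(normalized.expressed.sum()),
                "tested": int(len(de)),
                "up": int((de["direction"] == "up").sum()),
                "down": int((de["direction"] == "down").sum()),
            }

        if "annotate" not in skip:
            log.info("[annotate] reproducible peaks + TSS windows")
            peak_sets = {
                tuple(key.split(":", 1)): io.read_peaks(path)
                for key, path in cfg.peaks.items()
            }
            genes = io.read_gtf_genes(cfg.genes)
            gene_map = io.read_gene_mirna_map(cfg.gene_mirna_map)
            repro = peaks.reproducible_peaks(peak_sets)
            links = peaks.annotate_within_window(repro, genes, cfg.window_bp)
            links.to_csv(outdir / "peak_gene_links.tsv", sep="\t", index=False)
            io.write_bed(repro, outdir / "reproducible_peaks.bed")
            summary = {
                "n_input_peaks": int(sum(len(df) for df in peak_sets.values())),
                "n_reproducible_peaks": int(len(repro)),
                "n_links": int(len(links)),
                "n_genes_within_window": int(links["gene_id"].nunique()),
            }
            if de is not None:
                bound = peaks.bound_de_mirnas(links, genes, gene_map, de)
                summary.update(
                    n_mirna_genes_bound=len(bound.bound_mirna_gene_ids),
                    n_de_bound=len(bound.bound_de_ids),
                    n_de=bound.n_de,
                    fraction_bound_percent=bound.fraction_bound_percent,
                )
                io.write_gene_list(
                    bound.bound_mirna_gene_ids, outdir / "bound_mirna_genes.txt"
                )
                io.write_gene_list(bound.bound_de_ids, outdir / "bound_de_mirnas.txt")
            io.write_json(summary, outdir / "annotation_summary.json")
            counts["annotate"] = summary

        if "network" not in skip:
            if de is None:
                raise RuntimeError("network stage requires the de stage")
            log.info("[network] target sets + enrichment")
            interactions = network.InteractionTable(
                io.read_interactions(cfg.interactions),
                background_size=cfg.background_size,
            )
            sets = network.collect_targets(de, interactions)
            oncogenes = io.read_gene_list(cfg.oncogenes)
            tsgs = io.read_gene_list(cfg.tsgs)
            overlaps = network.intersect_gene_lists(sets, oncogenes, tsgs)
            for name, table in overlaps.items():
                table.to_csv(outdir / f"overlap_{name}.tsv", sep="\t", index=False)
            genesets = io.read_gmt(cfg.genesets)
            queries = (
                {"up": sets.up_targets, "down": sets.down_targets}
                if cfg.enrichment_query == "union"
                else {"up": sets.up_unique, "down": sets.down_unique}
            )
            for direction, query in queries.items():
                enr = network.hypergeom_enrich(
                    query, genesets, background_size=cfg.background_size
                )
                enr.to_csv(
                    outdir / f"enrichment_{direction}.tsv", sep="\t", index=False
                )
            nodes, edges = network.build_network(sets, de, oncogenes, tsgs)
            network.export_network(nodes, edges, outdir)
            counts["network"] = {
                "up_targets": len(sets.up_targets),
                "down_targets": len(sets.down_targets),
                "up_unique": len(sets.up_unique),
                "down_unique": len(sets.down_unique),
                "oncogene_overlap_up_unique": len(overlaps["up_unique_oncogenes"]),
                "tsg_overlap_down_unique": len(overlaps["down_unique_tsgs"]),
                "nodes": len(nodes),
                "edges": len(edges),
            }

        if "survival" not in skip:
            log.info("[survival] z-score screen")
            cohort = io.read_clinical(cfg.clinical)
            non_expr = {"patient_id", "time", "event"}
            panel = [c for c in cohort.columns if c not in non_expr]
            if cfg.survival_panel == "de" and de is not None:
                de_ids = set(de.index[de["direction"].isin(["up", "down"])])
                panel = [m for m in panel if m in de_ids]
            screen = surv.screen_mirnas(
                cohort, panel, cfg.cut_low, cfg.cut_high, cfg.alpha
            )
            screen.to_csv(outdir / "survival_screen.tsv", sep="\t", index=False)
            if len(screen):
                top = screen.iloc[0]["mirna_id"]
                strat = surv.stratify(cohort, top, cfg.cut_low, cfg.cut_high)
                for b, km in surv.km_tables(cohort, strat).items():
                    km.to_csv(outdir / f"km_{top}_{b}.tsv", sep="\t", index=False)
            counts["survival"] = {
                "patients": int(len(cohort)),
                "excluded_missing": int(cohort.attrs.get("n_excluded", 0)),
                "screened": int(len(screen)),
                "significant": int(screen["significant"].sum()),
            }

        caught = [str(w.message) for w in wrec]

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "counts": counts,
        "skipped": sorted(skip),
        "warnings": caught,
    }
    io.write_json(manifest, outdir / "run_manifest.json")
    return manifest
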