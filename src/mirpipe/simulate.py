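"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: two B-ALL
cell lines, each with duplicate control (CON) and induced (IK1) samples on
a mature-miRNA array with anti-genomic background probesets and per-probeset
detection p-values; replicate ChIP-seq peak sets with controlled
reproducibility around miRNA-gene TSSs; a many-to-many miRNA->target
interaction table; gene-set collections; and a right-censored survival
cohort with an expression-dependent hazard planted for chosen miRNAs.

Intensities follow a log-normal signal model on the linear scale: each
probeset's true signal is 2**x with x = baseline + condition effect +
Gaussian noise (log2 units), added to a per-probe Gaussian array
background — consistent with a pipeline that subtracts the mean
anti-genomic background and then log2-transforms. Detection p-values are
drawn directly per probeset (below 0.05 for expressed miRNAs, above it
otherwise) rather than from a probe-level detection model, because the
pipeline consumes p-values only.

Everything is driven by one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .microarray import ANTIGENOMIC, HUMAN_MATURE, ProbesetMatrix

DETECTION_ALPHA = 0.05  # planted detection p-values fall strictly below this


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic expression experiment.

    Defaults are the desk-scale study conditions: 200 mature miRNAs
    (of which 10% planted up-, 5% down-regulated at 2 log2 units with
    0.3 log2 residual sd), 95 anti-genomic probesets, two cell lines with
    duplicate CON/IK1 samples.
    """

    n_mirnas: int = 200
    n_antigenomic: int = 95
    n_other: int = 20
    cell_lines: tuple[str, ...] = ("MXP5", "PDX2")
    replicates_per_condition: int = 2
    frac_de_up: float = 0.10
    frac_de_down: float = 0.05
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.3
    background_mean: float = 50.0
    background_sd: float = 10.0
    dabg_alpha_truth: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_mirnas", "n_antigenomic", "replicates_per_condition"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_other < 0:
            raise ConfigurationError(f"n_other must be >= 0, got {self.n_other}")
        if not self.cell_lines:
            raise ConfigurationError("cell_lines must be non-empty")
        for name in ("frac_de_up", "frac_de_down", "dabg_alpha_truth"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.frac_de_up + self.frac_de_down > 1:
            raise ConfigurationError("frac_de_up + frac_de_down must be <= 1")
        if self.noise_sd_log2 <= 0:
            raise ConfigurationError(f"noise_sd_log2 must be > 0, got {self.noise_sd_log2}")
        if self.background_mean < 0 or self.background_sd < 0:
            raise ConfigurationError("background parameters must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth collected across generators."""

    de_labels: dict[str, str] = field(default_factory=dict)  # up/down/null
    expressed_labels: dict[str, bool] = field(default_factory=dict)
    bound_genes: set[str] = field(default_factory=set)
    hazard_beta: dict[str, float] = field(default_factory=dict)


# ------------------------------------------------------------- expression

def design_table(cfg: SimConfig) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{line}_{cond}_{rep}",
            "cell_line": line,
            "condition": cond,
            "replicate": str(rep),
        }
        for line in cfg.cell_lines
        for cond in ("CON", "IK1")
        for rep in range(1, cfg.replicates_per_condition + 1)
    ]
    return pd.DataFrame(rows)


def generate_expression(cfg: SimConfig) -> tuple[ProbesetMatrix, GroundTruth]:
    """Probeset x sample matrix with planted DE and detection truth.

    Expressed miRNAs get log2 baselines in [6, 9]; planted up/down miRNAs
    differ between IK1 and CON by +/- effect_size_log2 in every cell line.
    A fraction dabg_alpha_truth of miRNAs is below detection (high DABG p,
    near-background intensity).
    """
    rng = np.random.default_rng(cfg.seed)
    samples = design_table(cfg)
    n_samples = len(samples)

    mirna_ids = [f"syn-miR-{i:04d}" for i in range(cfg.n_mirnas)]
    n_unexpressed = int(round(cfg.n_mirnas * cfg.dabg_alpha_truth))
    n_up = int(round(cfg.n_mirnas * cfg.frac_de_up))
    n_down = int(round(cfg.n_mirnas * cfg.frac_de_down))
    n_expressed = cfg.n_mirnas - n_unexpressed
    if n_up + n_down > n_expressed:
        raise ConfigurationError(
            "frac_de_up + frac_de_down exceeds the expressed fraction "
            "(1 - dabg_alpha_truth): DE miRNAs must be expressed"
        )

    perm = rng.permutation(cfg.n_mirnas)
    up_idx = perm[:n_up]
    down_idx = perm[n_up : n_up + n_down]
    unexpr_idx = perm[n_up + n_down : n_up + n_down + n_unexpressed]

    labels = np.array(["null"] * cfg.n_mirnas, dtype=object)
    labels[up_idx], labels[down_idx] = "up", "down"
    expressed = np.ones(cfg.n_mirnas, dtype=bool)
    expressed[unexpr_idx] = False

    baseline = rng.uniform(6.0, 9.0, cfg.n_mirnas)
    baseline[~expressed] = rng.uniform(0.0, 1.0, n_unexpressed)
    delta = np.zeros(cfg.n_mirnas)
    delta[up_idx] = cfg.effect_size_log2
    delta[down_idx] = -cfg.effect_size_log2

    is_ik1 = (samples["condition"] == "IK1").values.astype(float)
    x = (
        baseline[:, None]
        + delta[:, None] * is_ik1[None, :]
        + rng.normal(0.0, cfg.noise_sd_log2, (cfg.n_mirnas, n_samples))
    )
    # additive array background is an array-level constant; the residual on
    # the log2 scale is then noise_sd_log2 as configured (the anti-genomic
    # mean estimates the constant with error ~ background_sd / sqrt(n_anti))
    mirna_intensity = cfg.background_mean + np.exp2(x)

    anti_ids = [f"anti-bg-{i:03d}" for i in range(cfg.n_antigenomic)]
    anti_intensity = np.clip(
        rng.normal(
            cfg.background_mean, cfg.background_sd, (cfg.n_antigenomic, n_samples)
        ),
        0.0,
        None,
    )
    other_ids = [f"decoy-{i:03d}" for i in range(cfg.n_other)]
    other_intensity = np.clip(
        rng.normal(cfg.background_mean, cfg.background_sd, (cfg.n_other, n_samples))
        + np.exp2(rng.uniform(0.0, 6.0, (cfg.n_other, 1))),
        0.0,
        None,
    )

    # detection p-values: strictly below the 0.05 mask for expressed miRNAs
    dabg_mirna = np.where(
        expressed[:, None],
        rng.uniform(0.0, DETECTION_ALPHA * 0.9, (cfg.n_mirnas, n_samples)),
        rng.uniform(DETECTION_ALPHA * 1.5, 1.0, (cfg.n_mirnas, n_samples)),
    )
    dabg_anti = rng.uniform(DETECTION_ALPHA, 1.0, (cfg.n_antigenomic, n_samples))
    dabg_other = rng.uniform(0.0, 1.0, (cfg.n_other, n_samples))

    ids = mirna_ids + anti_ids + other_ids
    intensities = pd.DataFrame(
        np.vstack([mirna_intensity, anti_intensity, other_intensity]),
        index=pd.Index(ids, name="probeset_id"),
        columns=samples["sample_id"].tolist(),
    )
    dabg = pd.DataFrame(
        np.vstack([dabg_mirna, dabg_anti, dabg_other]),
        index=intensities.index,
        columns=intensities.columns,
    )
    probe_class = pd.Series(
        [HUMAN_MATURE] * cfg.n_mirnas
        + [ANTIGENOMIC] * cfg.n_antigenomic
        + ["other"] * cfg.n_other,
        index=intensities.index,
        name="probe_class",
    )
    matrix = ProbesetMatrix(
        intensities=intensities, dabg_p=dabg, probe_class=probe_class, samples=samples
    )
    truth = GroundTruth(
        de_labels=dict(zip(mirna_ids, labels)),
        expressed_labels=dict(zip(mirna_ids, expressed.tolist())),
    )
    return matrix, truth


# ------------------------------------------------------------- annotation

def generate_annotation(
    mirna_ids,
    n_other_genes: int = 50,
    mirnas_per_gene: int = 2,
    gene_spacing_bp: int = 250_000,
    genes_per_chrom: int = 40,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic gene annotation + gene->mature-miRNA map.

    Mature miRNAs are grouped ``mirnas_per_gene`` per (polycistronic)
    miRNA gene. TSSs are spaced far enough apart (default 250 kb) that a
    peak near one TSS never falls in another gene's 50 kb window, keeping
    planted peak->gene truth unambiguous. Strands alternate.
    """
    rng = np.random.default_rng(seed)
    mirna_ids = list(mirna_ids)
    if not mirna_ids:
        raise ConfigurationError("mirna_ids must be non-empty")
    gene_rows, map_rows = [], []
    n_mirna_genes = (len(mirna_ids) + mirnas_per_gene - 1) // mirnas_per_gene
    total = n_mirna_genes + n_other_genes
    for gi in range(total):
        chrom = f"chrS{gi // genes_per_chrom + 1}"
        slot = gi % genes_per_chrom
        start = 100_000 + slot * gene_spacing_bp
        length = int(rng.integers(2_000, 40_000))
        strand = "+" if gi % 2 == 0 else "-"
        is_mir = gi < n_mirna_genes
        gene_id = f"MIRG{gi:04d}" if is_mir else f"GENE{gi:04d}"
        end = start + length
        gene_rows.append(
            {
                "gene_id": gene_id,
                "gene_name": gene_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "tss": start if strand == "+" else end - 1,
                "is_mirna_gene": is_mir,
            }
        )
        if is_mir:
            for mid in mirna_ids[gi * mirnas_per_gene : (gi + 1) * mirnas_per_gene]:
                map_rows.append({"gene_id": gene_id, "mature_id": mid})
    return pd.DataFrame(gene_rows), pd.DataFrame(map_rows)


# ------------------------------------------------------------------ peaks

def generate_peaks(
    genes: pd.DataFrame,
    bound_fraction: float = 0.2,
    window_bp: int = 50_000,
    n_replicates: int = 2,
    cell_lines: tuple[str, ...] = ("ICN1", "LAX2"),
    reproducibility: float = 1.0,
    decoy_rate: float = 0.3,
    n_intergenic: int = 5,
    peak_width: int = 400,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], pd.DataFrame], set[str]]:
    """Replicate peak sets with planted reproducibly bound genes.

    For each bound gene a peak is placed within window_bp of its TSS in
    every replicate of every cell line (small coordinate jitter keeps
    >= 1 bp mutual overlap); at reproducibility < 1 each replicate copy is
    instead retained with that probability. Decoy peaks near unbound gene
    TSSs appear in a strict subset of replicate sets only, so the
    reproducibility filter removes them; a few reproducible intergenic
    peaks on a gene-free chromosome exercise the annotation's
    no-gene-in-window path.
    """
    if genes.empty:
        raise ConfigurationError("gene annotation must be non-empty")
    if not 0 <= bound_fraction <= 1 or not 0 <= reproducibility <= 1:
        raise ConfigurationError("bound_fraction and reproducibility must be in [0,1]")
    rng = np.random.default_rng(seed)
    keys = [(cl, f"rep{r}") for cl in cell_lines for r in range(1, n_replicates + 1)]
    peaks: dict[tuple[str, str], list] = {k: [] for k in keys}

    n_bound = int(round(len(genes) * bound_fraction))
    order = rng.permutation(len(genes))
    bound = genes.iloc[order[:n_bound]]
    unbound = genes.iloc[order[n_bound:]]

    half = peak_width // 2
    for g in bound.itertuples():
        offset = int(rng.integers(-(window_bp - peak_width), window_bp - peak_width))
        center = max(g.tss + offset, half + 1)
        for key in keys:
            if reproducibility < 1 and rng.random() > reproducibility:
                continue
            jitter = int(rng.integers(-half + 1, half - 1)) if half > 2 else 0
            s = center + jitter - half
            peaks[key].append((g.chrom, s, s + peak_width, g.gene_id))

    n_sets = len(keys)
    for g in unbound.itertuples():
        if rng.random() > decoy_rate:
            continue
        offset = int(rng.integers(-(window_bp - peak_width), window_bp - peak_width))
        center = max(g.tss + offset, half + 1)
        n_in = int(rng.integers(1, n_sets))  # strict subset: never all sets
        for ki in rng.choice(n_sets, size=n_in, replace=False):
            s = center - half
            peaks[keys[ki]].append((g.chrom, s, s + peak_width, f"decoy_{g.gene_id}"))

    for i in range(n_intergenic):
        s = 100_000 + i * 10 * window_bp
        for key in keys:
            peaks[key].append(("chrU", s, s + peak_width, f"intergenic_{i}"))

    out = {}
    for key, rows in peaks.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        df["score"] = 100
        df["strand"] = "."
        df["summit"] = -1
        out[key] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out, set(bound["gene_id"])


# ---------------------------------------------------------------- targets

def generate_targets(
    up_mirnas,
    down_mirnas,
    gene_universe,
    mean_targets_per_mirna: float = 50.0,
    overlap_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Many-to-many miRNA->target table with controlled directional overlap.

    The gene universe is split into an up-pool, a down-pool and a shared
    pool of relative size ``overlap_rate``; up-regulated miRNAs draw
    targets from up-pool + shared, down-regulated from down-pool + shared.
    overlap_rate = 0 therefore makes the two directional target unions
    disjoint by construction. Per-miRNA target counts are Poisson with
    the given mean; duplicate pairs are never emitted.
    """
    up_mirnas, down_mirnas = list(up_mirnas), list(down_mirnas)
    genes = sorted(set(gene_universe))
    if not genes or not (up_mirnas or down_mirnas):
        raise ConfigurationError("miRNA and gene universes must be non-empty")
    if not 0 <= overlap_rate <= 1:
        raise ConfigurationError("overlap_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    genes = list(rng.permutation(genes))
    n_shared = int(round(len(genes) * overlap_rate))
    shared = genes[:n_shared]
    rest = genes[n_shared:]
    half = len(rest) // 2
    up_pool = rest[:half] + shared
    down_pool = rest[half:] + shared

    rows = []
    for mirnas, pool in ((up_mirnas, up_pool), (down_mirnas, down_pool)):
        for mid in mirnas:
            k = min(int(rng.poisson(mean_targets_per_mirna)), len(pool))
            for g in rng.choice(pool, size=k, replace=False):
                rows.append({"mirna_id": mid, "gene_symbol": str(g).upper()})
    return (
        pd.DataFrame(rows, columns=["mirna_id", "gene_symbol"])
        .drop_duplicates()
        .reset_index(drop=True)
    )


def generate_genesets(
    gene_universe,
    enriched_in: set[str],
    n_enriched: int = 2,
    n_random: int = 8,
    set_size: int = 40,
    enrich_fraction: float = 0.75,
    seed: int = 0,
) -> dict[str, set[str]]:
    """GMT-style collection with a few sets planted to overlap a query."""
    rng = np.random.default_rng(seed)
    universe = sorted(set(gene_universe))
    inside = sorted(set(enriched_in) & set(universe))
    outside = sorted(set(universe) - set(enriched_in))
    sets: dict[str, set[str]] = {}
    for i in range(n_enriched):
        k_in = min(int(set_size * enrich_fraction), len(inside))
        members = set(rng.choice(inside, size=k_in, replace=False))
        members |= set(rng.choice(outside, size=min(set_size - k_in, len(outside)), replace=False))
        sets[f"PLANTED_PATHWAY_{i + 1}"] = {str(g) for g in members}
    for i in range(n_random):
        members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        sets[f"RANDOM_PATHWAY_{i + 1}"] = {str(g) for g in members}
    return sets


# --------------------------------------------------------------- survival

def generate_survival(
    n_patients: int,
    mirna_ids,
    hazard_beta: dict[str, float] | None = None,
    censor_rate: float = 0.3,
    baseline_hazard: float = 1.0 / 1000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Censored cohort with an expression-dependent exponential hazard.

    Expression columns are log-normal counts, 2**(8 + u) with u standard
    normal. The hazard acts on the cohort z-score of the expression value
    itself — the same standardization the downstream stratifier applies —
    so a planted ``hazard_beta`` is the log hazard ratio per unit z that
    the pipeline's Cox fit estimates. Event times are exponential with
    hazard baseline * exp(sum_j beta_j * z_j); censoring is an independent
    exponential calibrated so that, under the null, a fraction
    ``censor_rate`` of patients is censored. Times are in days.
    """
    if n_patients < 10:
        raise ConfigurationError(f"n_patients must be >= 10, got {n_patients}")
    if not 0 <= censor_rate < 1:
        raise ConfigurationError(f"censor_rate must be in [0,1), got {censor_rate}")
    mirna_ids = list(mirna_ids)
    if not mirna_ids:
        raise ConfigurationError("mirna_ids must be non-empty")
    hazard_beta = dict(hazard_beta or {})
    unknown = set(hazard_beta) - set(mirna_ids)
    if unknown:
        raise ConfigurationError(f"hazard_beta for unknown miRNAs: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_patients, len(mirna_ids)))
    expr = np.exp2(8.0 + u)
    # hazard acts on the cohort-standardized expression (what stratify sees)
    z = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=1)
    log_hr = np.zeros(n_patients)
    for j, mid in enumerate(mirna_ids):
        log_hr += hazard_beta.get(mid, 0.0) * z[:, j]
    rate = baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, n_patients)
    else:
        censor_time = np.full(n_patients, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    cohort = pd.DataFrame(
        {"patient_id": [f"PT{i:04d}" for i in range(n_patients)],
         "time": np.maximum(time, 1e-3), "event": event}
    )
    for j, mid in enumerate(mirna_ids):
        cohort[mid] = expr[:, j]
    truth = GroundTruth(hazard_beta=hazard_beta)
    return cohort, truth


# ---------------------------------------------------------------- scenario

def simulate_scenario(
    outdir: str | Path,
    cfg: SimConfig = SimConfig(),
    bound_fraction: float = 0.2,
    reproducibility: float = 1.0,
    overlap_rate: float = 0.0,
    n_patients: int = 500,
    survival_hazard_beta: float = float(np.log(2.0)),
    censor_rate: float = 0.3,
) -> dict:
    """Generate and write every pipeline input to ``outdir``.

    One planted-DE miRNA (the first planted up-regulated one) receives the
    survival hazard. Returns a manifest dict (also written as
    manifest.json) with all parameters, file paths and the ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(cfg)

    mirna_ids = [m for m, c in matrix.probe_class.items() if c == HUMAN_MATURE]
    genes, gene_map = generate_annotation(mirna_ids, seed=cfg.seed + 1)
    peak_sets, bound = generate_peaks(
        genes,
        bound_fraction=bound_fraction,
        reproducibility=reproducibility,
        seed=cfg.seed + 2,
    )
    truth.bound_genes = bound

    up = sorted(m for m, l in truth.de_labels.items() if l == "up")
    down = sorted(m for m, l in truth.de_labels.items() if l == "down")
    gene_universe = [f"TG{i:05d}" for i in range(2000)]
    interactions = generate_targets(
        up, down, gene_universe, overlap_rate=overlap_rate, seed=cfg.seed + 3
    )
    up_targets = set(interactions.loc[interactions["mirna_id"].isin(up), "gene_symbol"])
    genesets = generate_genesets(gene_universe, up_targets, seed=cfg.seed + 4)
    rng = np.random.default_rng(cfg.seed + 5)
    oncogenes = set(rng.choice(sorted(up_targets), size=min(60, len(up_targets)), replace=False))
    down_targets = set(
        interactions.loc[interactions["mirna_id"].isin(down), "gene_symbol"]
    )
    tsg_pool = sorted(down_targets - up_targets) or sorted(down_targets)
    tsgs = set(rng.choice(tsg_pool, size=min(60, len(tsg_pool)), replace=False))

    de_panel = up + down
    hazard = {up[0]: survival_hazard_beta} if up else {}
    cohort, surv_truth = generate_survival(
        n_patients, de_panel, hazard_beta=hazard,
        censor_rate=censor_rate, seed=cfg.seed + 6,
    )
    truth.hazard_beta = surv_truth.hazard_beta

    # ---- write everything
    expr = matrix.intensities.copy()
    expr.insert(0, "probe_class", matrix.probe_class)
    io.write_expression(expr, outdir / "expression.tsv")
    dab = matrix.dabg_p.copy()
    dab.insert(0, "probe_class", matrix.probe_class)
    io.write_expression(dab, outdir / "dabg.tsv")
    io.write_sample_meta(matrix.samples, outdir / "samples.tsv")
    io.write_gtf_genes(genes, outdir / "genes.gtf")
    io.write_gene_mirna_map(gene_map, outdir / "gene_mirna_map.tsv")
    peak_paths = {}
    for (cl, rep), df in peak_sets.items():
        p = outdir / f"peaks_{cl}_{rep}.bed"
        io.write_bed(df, p)
        peak_paths[f"{cl}:{rep}"] = str(p)
    io.write_interactions(interactions, outdir / "interactions.tsv")
    io.write_gmt(genesets, outdir / "genesets.gmt")
    io.write_gene_list(oncogenes, outdir / "oncogenes.txt")
    io.write_gene_list(tsgs, outdir / "tsgs.txt")
    io.write_clinical(cohort, outdir / "clinical.tsv")

    manifest = {
        "config": asdict(cfg),
        "bound_fraction": bound_fraction,
        "reproducibility": reproducibility,
        "overlap_rate": overlap_rate,
        "n_patients": n_patients,
        "censor_rate": censor_rate,
        "files": {
            "expression": str(outdir / "expression.tsv"),
            "dabg": str(outdir / "dabg.tsv"),
            "samples": str(outdir / "samples.tsv"),
            "genes": str(outdir / "genes.gtf"),
            "gene_mirna_map": str(outdir / "gene_mirna_map.tsv"),
            "peaks": peak_paths,
            "interactions": str(outdir / "interactions.tsv"),
            "genesets": str(outdir / "genesets.gmt"),
            "oncogenes": str(outdir / "oncogenes.txt"),
            "tsgs": str(outdir / "tsgs.txt"),
            "clinical": str(outdir / "clinical.tsv"),
        },
        "truth": {
            "de_labels": truth.de_labels,
            "expressed_labels": truth.expressed_labels,
            "bound_genes": sorted(truth.bound_genes),
            "hazard_beta": truth.hazard_beta,
        },
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
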