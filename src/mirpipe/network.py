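"""Directional miRNA->target sets, list intersections, and enrichment.

Targets of up- and down-regulated miRNAs are unioned separately; the
"unique" sets are the set differences (genes targeted only by one
direction). Gene-set enrichment is the upper-tail hypergeometric test
against a fixed background universe size (default 17,387 — the number of
distinct target genes in miRTarBase v8.0), BH-adjusted per collection.
Gene symbols are case-normalized to upper case before any comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .microarray import bh_adjust

DEFAULT_BACKGROUND_SIZE = 17_387


@dataclass
class InteractionTable:
    """Deduplicated (mirna_id, gene_symbol) pairs plus the background size
    of the source database."""

    pairs: pd.DataFrame
    background_size: int = DEFAULT_BACKGROUND_SIZE

    def __post_init__(self):
        self.pairs = self.pairs[["mirna_id", "gene_symbol"]].copy()
        self.pairs["gene_symbol"] = self.pairs["gene_symbol"].str.upper()
        self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)
        n_genes = self.pairs["gene_symbol"].nunique()
        if self.background_size < n_genes:
            raise ValueError(
                f"background_size {self.background_size} < {n_genes} distinct "
                "target genes in the table"
            )

    @property
    def genes(self) -> set[str]:
        return set(self.pairs["gene_symbol"])


@dataclass
class TargetSets:
    up_targets: set[str]
    down_targets: set[str]
    per_mirna: dict[str, set[str]] = field(default_factory=dict)
    uncovered_mirnas: set[str] = field(default_factory=set)

    @property
    def up_unique(self) -> set[str]:
        return self.up_targets - self.down_targets

    @property
    def down_unique(self) -> set[str]:
        return self.down_targets - self.up_targets


def collect_targets(de: pd.DataFrame, interactions: InteractionTable) -> TargetSets:
    """Union targets of up- and of down-regulated miRNAs.

    miRNAs absent from the interaction table contribute empty sets and are
    listed in ``uncovered_mirnas`` (with a warning). -3p/-5p arms are
    distinct identifiers and are matched exactly.
    """
    by_mirna = interactions.pairs.groupby("mirna_id")["gene_symbol"].apply(set)
    per_mirna: dict[str, set[str]] = {}
    uncovered = set()
    up, down = set(), set()
    for mid, direction in de["direction"].items():
        if direction not in ("up", "down"):
            continue
        targets = set(by_mirna.get(mid, set()))
        per_mirna[mid] = targets
        if not targets:
            uncovered.add(mid)
        if direction == "up":
            up |= targets
        else:
            down |= targets
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} DE miRNA(s) with zero interaction coverage",
            RuntimeWarning,
            stacklevel=2,
        )
    return TargetSets(
        up_targets=up, down_targets=down, per_mirna=per_mirna,
        uncovered_mirnas=uncovered,
    )


def intersect_gene_lists(
    sets: TargetSets, oncogenes: set[str], tsgs: set[str]
) -> dict[str, pd.DataFrame]:
    """Overlap the unique directional target sets with curated gene lists.

    Returns per-overlap tables (gene, targeting miRNAs) for the headline
    pairs (up-unique x oncogenes, down-unique x TSGs) and the symmetric
    pairs for completeness.
    """
    oncogenes = {g.upper() for g in oncogenes}
    tsgs = {g.upper() for g in tsgs}
    if not oncogenes or not tsgs:
        warnings.warn("empty oncogene or TSG list", RuntimeWarning, stacklevel=2)

    def table(genes: set[str]) -> pd.DataFrame:
        rows = []
        for g in sorted(genes):
            mirnas = sorted(m for m, t in sets.per_mirna.items() if g in t)
            rows.append({"gene_symbol": g, "targeting_mirnas": ",".join(mirnas)})
        return pd.DataFrame(rows, columns=["gene_symbol", "targeting_mirnas"])

    return {
        "up_unique_oncogenes": table(sets.up_unique & oncogenes),
        "down_unique_tsgs": table(sets.down_unique & tsgs),
        "up_unique_tsgs": table(sets.up_unique & tsgs),
        "down_unique_oncogenes": table(sets.down_unique & oncogenes),
    }


def hypergeom_enrich(
    query: set[str],
    genesets: dict[str, set[str]],
    background_size: int = DEFAULT_BACKGROUND_SIZE,
    background_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene set collection.

    p = P(X >= k) for X ~ Hypergeom(N=background_size, K=|geneset|,
    n=|query|), with query and gene sets first restricted to
    ``background_genes`` when a background universe list is supplied.
    BH adjustment is one family across the collection; rows are sorted
    by FDR. Gene sets entirely outside the background are skipped.
    """
    if not genesets:
        raise ValueError("empty gene-set collection")
    query = {g.upper() for g in query}
    if background_genes is not None:
        background_genes = {g.upper() for g in background_genes}
        query &= background_genes
    if background_size < len(query):
        raise ValueError(
            f"background_size {background_size} smaller than query ({len(query)})"
        )

    rows = []
    skipped = []
    for name, members in genesets.items():
        members = {g.upper() for g in members}
        if background_genes is not None:
            members &= background_genes
        if not members:
            skipped.append(name)
            continue
        k = len(query & members)
        K = len(members)
        n = len(query)
        p = float(hypergeom.sf(k - 1, background_size, K, n))
        rows.append(
            {"geneset": name, "k": k, "K": K, "n": n,
             "N": background_size, "p_value": min(p, 1.0)}
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} gene set(s) entirely outside the background "
            f"universe skipped: {skipped[:5]}",
            RuntimeWarning,
            stacklevel=2,
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(
            columns=["geneset", "k", "K", "n", "N", "p_value", "fdr"]
        )
    result["fdr"] = bh_adjust(result["p_value"].values)
    return result.sort_values(["fdr", "p_value"]).reset_index(drop=True)


def build_network(
    sets: TargetSets,
    de: pd.DataFrame,
    oncogenes: set[str] | None = None,
    tsgs: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of the directional miRNA->target network.

    miRNA node size (degree) is its target count; gene nodes carry
    oncogene/TSG flags. Edge endpoints always exist in the node table.
    """
    oncogenes = {g.upper() for g in (oncogenes or set())}
    tsgs = {g.upper() for g in (tsgs or set())}
    edges = [
        {"mirna_id": m, "gene_symbol": g}
        for m, targets in sorted(sets.per_mirna.items())
        for g in sorted(targets)
    ]
    edges_df = pd.DataFrame(edges, columns=["mirna_id", "gene_symbol"])
    gene_degree = edges_df.groupby("gene_symbol").size() if len(edges_df) else {}
    nodes = []
    for m in sorted(sets.per_mirna):
        nodes.append(
            {
                "id": m, "kind": "mirna",
                "direction": de.loc[m, "direction"] if m in de.index else "ns",
                "oncogene": False, "tsg": False,
                "degree": len(sets.per_mirna[m]),
            }
        )
    for g in sorted(sets.up_targets | sets.down_targets):
        nodes.append(
            {
                "id": g, "kind": "gene", "direction": "",
                "oncogene": g in oncogenes, "tsg": g in tsgs,
                "degree": int(gene_degree[g]),
            }
        )
    return pd.DataFrame(nodes), edges_df


def export_network(
    nodes: pd.DataFrame, edges: pd.DataFrame, outdir: str | Path,
    prefix: str = "network",
) -> dict[str, Path]:
    """Write SIF + node/edge attribute TSVs importable by graph tools."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sif = outdir / f"{prefix}.sif"
    with open(sif, "w") as fh:
        for e in edges.itertuples():
            fh.write(f"{e.mirna_id}\ttargets\t{e.gene_symbol}\n")
    nodes_path = outdir / f"{prefix}_nodes.tsv"
    edges_path = outdir / f"{prefix}_edges.tsv"
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)
    return {"sif": sif, "nodes": nodes_path, "edges": edges_path}
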