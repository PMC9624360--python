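"""ChIP-seq peak reproducibility filtering and TSS-window annotation.

A binding site is kept only when it is covered by at least one peak in
every replicate of every cell line (strict intersection with >= 1 bp
overlap) — the most conservative reading of "present in two independent
replicates for two independent cell lines". Genes are linked to a kept
peak when the peak anchor (narrowPeak summit when called, interval
midpoint otherwise) lies within a closed +/- window of the gene TSS
(50 kb by default). Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_WINDOW_BP = 50_000


class ReplicateDesignError(ValueError):
    pass


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent-overlapping intervals per chromosome."""
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"].values, sub["end"].values):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # >= 1 bp overlap required to merge
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intersection of two merged, sorted interval sets (sorted sweep)."""
    out = []
    b_by_chrom = dict(tuple(b.groupby("chrom", sort=False)))
    for chrom, sub_a in a.groupby("chrom", sort=True):
        sub_b = b_by_chrom.get(chrom)
        if sub_b is None:
            continue
        sa, ea = sub_a["start"].values, sub_a["end"].values
        sb, eb = sub_b["start"].values, sub_b["end"].values
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo, hi = max(sa[i], sb[j]), min(ea[i], eb[j])
            if lo < hi:
                out.append((chrom, lo, hi))
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def reproducible_peaks(
    peak_sets: dict[tuple[str, str], pd.DataFrame],
    min_cell_lines: int = 2,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Regions covered by >= 1 peak in every replicate of every cell line.

    peak_sets maps (cell_line, replicate) -> peak table. The result is the
    merged strict intersection, sorted and non-overlapping; summit is set
    to -1 (the intersected interval midpoint is the downstream anchor).
    """
    lines: dict[str, list] = {}
    for (cell_line, rep), df in peak_sets.items():
        lines.setdefault(cell_line, []).append((rep, df))
    if len(lines) < min_cell_lines:
        raise ReplicateDesignError(
            f"need >= {min_cell_lines} cell lines, got {sorted(lines)}"
        )
    for cell_line, reps in lines.items():
        if len(reps) < min_replicates:
            missing = [(cell_line, r) for r, _ in reps]
            raise ReplicateDesignError(
                f"cell line {cell_line!r} has only {len(reps)} replicate "
                f"set(s) {missing}; >= {min_replicates} required"
            )

    result = None
    for (_, _), df in sorted(peak_sets.items()):
        merged = merge_intervals(df)
        result = merged if result is None else intersect_intervals(result, merged)
    result["summit"] = -1
    return result.sort_values(["chrom", "start"]).reset_index(drop=True)


def peak_anchor(peaks: pd.DataFrame) -> np.ndarray:
    """Summit when called (>= 0), midpoint (integer floor) otherwise."""
    mid = (peaks["start"].values + peaks["end"].values) // 2
    if "summit" in peaks.columns:
        summit = peaks["summit"].values
        return np.where(summit >= 0, summit, mid)
    return mid


def annotate_within_window(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Link each peak to every gene whose TSS is within +/- window_bp
    (closed interval) of the peak anchor.

    Returns one row per (peak, gene) pair with the signed distance from
    anchor to TSS on the gene strand (negative = upstream of the TSS).
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be > 0, got {window_bp}")
    peak_chroms = set(peaks["chrom"])
    gene_chroms = set(genes["chrom"])
    orphan = peak_chroms - gene_chroms
    if orphan:
        counts = peaks["chrom"].value_counts().loc[sorted(orphan)].to_dict()
        warnings.warn(
            f"peak chromosomes absent from annotation (peaks dropped from "
            f"linking): {counts}",
            RuntimeWarning,
            stacklevel=2,
        )

    anchors = peak_anchor(peaks)
    rows = []
    for chrom, sub_genes in genes.groupby("chrom", sort=False):
        mask = (peaks["chrom"] == chrom).values
        if not mask.any():
            continue
        sub_peaks = peaks.loc[mask]
        sub_anchor = anchors[mask]
        order = np.argsort(sub_genes["tss"].values)
        tss = sub_genes["tss"].values[order]
        gid = sub_genes["gene_id"].values[order]
        strand = sub_genes["strand"].values[order]
        lo = np.searchsorted(tss, sub_anchor - window_bp, side="left")
        hi = np.searchsorted(tss, sub_anchor + window_bp, side="right")
        for (p, a), l, h in zip(
            zip(sub_peaks.itertuples(), sub_anchor), lo, hi
        ):
            for gi in range(l, h):
                raw = int(a) - int(tss[gi])
                dist = raw if strand[gi] != "-" else -raw
                rows.append((p.chrom, p.start, p.end, int(a), gid[gi], dist))
    links = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "anchor", "gene_id", "distance"]
    )
    return links.drop_duplicates(["chrom", "start", "end", "gene_id"]).reset_index(
        drop=True
    )


@dataclass
class BoundSummary:
    """Intersection of peak-linked miRNA genes with the DE miRNA list."""

    bound_mirna_gene_ids: set
    bound_de_ids: set
    n_de: int
    fraction_bound_percent: int
    unmapped_de_ids: set

    @property
    def fraction_bound(self) -> float:
        return len(self.bound_de_ids) / self.n_de if self.n_de else 0.0


def bound_de_mirnas(
    links: pd.DataFrame,
    genes: pd.DataFrame,
    gene_mirna_map: pd.DataFrame,
    de: pd.DataFrame,
) -> BoundSummary:
    """Which DE mature miRNAs have a peak-linked encoding gene.

    gene_mirna_map is the two-column gene_id -> mature_id table; a DE miRNA
    whose mature id maps to no gene is counted as unbound and reported in
    unmapped_de_ids. The fraction is reported rounded to a whole percent.
    """
    mirna_genes = set(genes.loc[genes["is_mirna_gene"], "gene_id"])
    linked_genes = set(links["gene_id"])
    bound_genes = linked_genes & mirna_genes

    de_ids = set(de.index[de["direction"].isin(["up", "down"])])
    gene_of = gene_mirna_map.groupby("mature_id")["gene_id"].apply(set)
    bound_de = set()
    unmapped = set()
    for mid in de_ids:
        if mid not in gene_of.index:
            unmapped.add(mid)
        elif gene_of[mid] & bound_genes:
            bound_de.add(mid)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} DE miRNA(s) with no gene mapping counted as "
            f"unbound: {sorted(unmapped)[:10]}",
            RuntimeWarning,
            stacklevel=2,
        )
    n_de = len(de_ids)
    percent = round(100 * len(bound_de) / n_de) if n_de else 0
    return BoundSummary(
        bound_mirna_gene_ids=bound_genes,
        bound_de_ids=bound_de,
        n_de=n_de,
        fraction_bound_percent=percent,
        unmapped_de_ids=unmapped,
    )
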