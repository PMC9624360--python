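"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular formats are tab-separated with a header row unless a format
standard says otherwise (BED/narrowPeak and GMT are headerless; GTF follows
the 9-column convention). Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "summit",
]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------- expression

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a probeset-summary table: probeset_id, probe_class, one column
    per sample (linear-scale intensities or detection p-values)."""
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str})
    if "probeset_id" not in df.columns or "probe_class" not in df.columns:
        raise ValueError(
            f"{path}: expected columns 'probeset_id' and 'probe_class'"
        )
    return df.set_index("probeset_id")


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().rename(columns={"index": "probeset_id"}).to_csv(
        path, sep="\t", index=False
    )


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Sample sheet: sample_id, cell_line, condition (CON/IK1), replicate."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cell_line", "condition", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id entries")
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- peaks

def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read BED6 or ENCODE narrowPeak. Returns chrom/start/end (+ summit as
    absolute position when a valid narrowPeak summit offset is present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 10:
        df = df.iloc[:, :10]
        df.columns = NARROWPEAK_COLUMNS
        # narrowPeak summit is an offset from start; -1 means "not called"
        has = df["summit"] >= 0
        df.loc[has, "summit"] = df.loc[has, "start"] + df.loc[has, "summit"]
        df.loc[~has, "summit"] = -1
    else:
        df = df.iloc[:, : min(df.shape[1], 6)]
        df.columns = BED6_COLUMNS[: df.shape[1]]
        df["summit"] = -1
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: zero- or negative-length interval")
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- annotation

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Read gene lines from a GTF into a gene annotation table.

    Only `gene` features are used. TSS = start for + strand, end for -
    strand (converted to 0-based). A gene is flagged as a miRNA gene when
    its gene_biotype/gene_type attribute equals 'miRNA'.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            start1, end1 = int(f[3]), int(f[4])  # GTF is 1-based closed
            strand = f[6]
            tss = start1 - 1 if strand != "-" else end1 - 1
            biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
            rows.append(
                {
                    "gene_id": attrs.get("gene_id", ""),
                    "gene_name": attrs.get("gene_name", attrs.get("gene_id", "")),
                    "chrom": f[0],
                    "start": start1 - 1,
                    "end": end1,
                    "strand": strand,
                    "tss": tss,
                    "is_mirna_gene": biotype == "miRNA",
                }
            )
    if not rows:
        raise ValueError(f"{path}: no gene features found")
    return pd.DataFrame(rows)


def write_gtf_genes(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples():
            biotype = "miRNA" if g.is_mirna_gene else "protein_coding"
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{biotype}";'
            )
            fh.write(
                f"{g.chrom}\tmirpipe\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gene_mirna_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV: gene_id -> mature miRNA id (many-to-many)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "mature_id"]:
        raise ValueError(f"{path}: expected columns gene_id, mature_id")
    return df.drop_duplicates()


def write_gene_mirna_map(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "mature_id"]].to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- network

def read_interactions(path: str | Path) -> pd.DataFrame:
    """miRNA->target interaction TSV with columns mirna_id, gene_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "gene_symbol"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns mirna_id, gene_symbol")
    return df[["mirna_id", "gene_symbol"]].drop_duplicates().reset_index(drop=True)


def write_interactions(df: pd.DataFrame, path: str | Path) -> None:
    df[["mirna_id", "gene_symbol"]].drop_duplicates().to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text gene list, one symbol per line, case-normalized upper."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# ------------------------------------------------------------------ clinical

def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical table: patient_id, time (days), event (0/1), one expression
    column per miRNA. Rows with missing time or event are dropped (the count
    is recorded in df.attrs['n_excluded'])."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    n0 = len(df)
    df = df.dropna(subset=["time", "event"]).reset_index(drop=True)
    df.attrs["n_excluded"] = n0 - len(df)
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: non-positive follow-up time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0 (censored) or 1 (death)")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ manifest

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
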