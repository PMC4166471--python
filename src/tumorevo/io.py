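"""File formats: VCF 4.2, BED, TSV tables, truth/report JSON, Newick.

Coordinates are 1-based inclusive inside the package; BED files are
written/read as 0-based half-open, converting at the boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import pysam


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    """Write intervals (1-based inclusive columns chrom/start/end) as BED."""
    out = df[["chrom", "start", "end"]].copy()
    out["start"] = out["start"] - 1  # 0-based half-open
    if name_col is not None:
        out["name"] = df[name_col].values
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED into 1-based inclusive chrom/start/end (+name if present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    if df.shape[1] >= 4:
        cols[3] = "name"
    df.columns = cols
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_region_vcf(variants: pd.DataFrame, path: str | Path, region: str) -> None:
    """Write one region's candidate variants as VCF 4.2 with NORMAL and
    TUMOR genotype columns (DP and AD per sample).

    Only variants observed in the region (alt reads > 0) or flagged
    germline are emitted. The germline record carries ``GERMLINE`` in INFO.
    """
    from .simulate import GENOME, GERMLINE_VARIANT_ID

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom, length in GENOME.items():
        header.contigs.add(chrom, length=length)
    header.info.add("GERMLINE", 0, "Flag", "Variant present in the matched normal")
    header.info.add("KIND", 1, "String", "Variant kind (snv/indel)")
    header.info.add("VID", 1, "String", "Variant identifier")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample("NORMAL")
    header.add_sample("TUMOR")

    df = variants[(variants.alt_count > 0) | (variants.variant_id == GERMLINE_VARIANT_ID)]
    df = df.sort_values(["chrom", "pos"])
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, v in df.iterrows():
            rec = vcf.new_record(
                contig=str(v.chrom), start=int(v.pos) - 1,
                alleles=(v.ref, v.alt_allele), id=str(v.variant_id),
            )
            germline = v.variant_id == GERMLINE_VARIANT_ID
            if germline:
                rec.info["GERMLINE"] = True
            rec.info["KIND"] = str(v.kind)
            rec.info["VID"] = str(v.variant_id)
            rec.samples["NORMAL"]["GT"] = (0, 1) if germline else (0, 0)
            rec.samples["NORMAL"]["DP"] = int(v.depth)
            rec.samples["TUMOR"]["GT"] = (0, 1)
            rec.samples["TUMOR"]["DP"] = int(v.depth)
            rec.samples["TUMOR"]["AD"] = (int(v.depth - v.alt_count), int(v.alt_count))
            vcf.write(rec)


def read_region_vcf(path: str | Path, region: str | None = None) -> pd.DataFrame:
    """Read a per-region VCF back into the variant observation table."""
    rows = []
    if region is None:
        region = Path(path).stem
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            depth = rec.samples["TUMOR"]["DP"]
            ad = rec.samples["TUMOR"]["AD"]
            alt_count = int(ad[1]) if ad is not None else 0
            rows.append(dict(
                variant_id=rec.info.get("VID", rec.id),
                chrom=rec.contig, pos=rec.pos, ref=rec.ref,
                alt_allele=rec.alts[0], kind=rec.info.get("KIND", "snv"),
                region=region, depth=int(depth), alt_count=alt_count,
                vaf=alt_count / depth if depth else 0.0,
                germline="GERMLINE" in rec.info,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mutation matrix / segments TSV
# ---------------------------------------------------------------------------

def write_matrix_tsv(presence: pd.DataFrame, meta: pd.DataFrame, path: str | Path) -> None:
    """Events as rows (with kind/class metadata), regions as columns."""
    out = meta.join(presence)
    out.to_csv(path, sep="\t", index_label="event")


def read_matrix_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="event")
    meta_cols = [c for c in ("kind", "event_class") if c in df.columns]
    meta = df[meta_cols]
    presence = df.drop(columns=meta_cols).astype(int)
    return presence, meta


def write_segments_tsv(segments: pd.DataFrame, path: str | Path) -> None:
    segments.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_segments_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Newick clone trees
# ---------------------------------------------------------------------------

def tree_to_newick(parents: Mapping[str, str | None]) -> str:
    """Serialize a clone tree (child -> parent map) as a Newick string."""
    children: dict[str | None, list[str]] = {}
    for node, parent in parents.items():
        children.setdefault(parent, []).append(node)
    roots = sorted(children.get(None, []))
    if len(roots) != 1:
        raise ValueError("clone tree must have exactly one root")

    def render(node: str) -> str:
        kids = sorted(children.get(node, []))
        label = node.replace(" ", "_")
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    return render(roots[0]) + ";"


def newick_to_parents(newick: str) -> dict[str, str | None]:
    """Parse a Newick string (via dendropy) back to a child -> parent map."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    parents: dict[str, str | None] = {}
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        label = label.replace(" ", "_") if label else label
        parent = node.parent_node
        if parent is None:
            parents[label] = None
        else:
            plabel = parent.taxon.label if parent.taxon else parent.label
            parents[label] = plabel.replace(" ", "_") if plabel else plabel
    return parents
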