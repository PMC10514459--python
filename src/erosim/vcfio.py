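"""Readers and writers for the empirical-side file formats.

Variant input is VCF v4.2 (plain or bgzipped, read with cyvcf2) plus an
annotation TSV (``chrom  pos  category``) and a population map TSV
(``sample  population``).  The derived allele is assumed to be ALT
(polarization happens upstream).  Output formats are a per-sample ROH BED
(0-based half-open), tidy summary TSVs, and VCF v4.2 with GT/DP/AD fields
written as plain text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .loadstats import CATEGORIES, VariantTable
from .roh import RohSegment

__all__ = [
    "read_annotation",
    "read_popmap",
    "read_variant_table",
    "write_vcf",
    "write_roh_bed",
    "write_genotype_matrix",
    "read_genotype_matrix",
]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Annotation TSV with columns chrom, pos (1-based), category."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    bad = set(df["category"].unique()) - set(CATEGORIES)
    if bad:
        raise ValueError(f"annotation file {path} has unknown categories: {sorted(bad)}")
    return df


def read_popmap(path: str | Path) -> Dict[str, str]:
    """Population map TSV with columns sample, population."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"population map {path} lacks columns: {sorted(missing)}")
    return dict(zip(df["sample"], df["population"]))


def read_variant_table(
    vcf_path: str | Path,
    annotation_path: str | Path,
    popmap_path: str | Path,
) -> VariantTable:
    """Assemble a :class:`VariantTable` from VCF + annotation + popmap.

    Sites absent from the annotation are skipped.  GT is converted to a
    derived-allele dosage (ALT = derived); DP and the reference AD are kept
    when present so the hard filters can run downstream.
    """
    from cyvcf2 import VCF

    ann = read_annotation(annotation_path)
    cat_by_site = {
        (c, int(p)): cat
        for c, p, cat in zip(ann["chrom"], ann["pos"], ann["category"])
    }
    popmap = read_popmap(popmap_path)

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in popmap]
    if unknown:
        raise ValueError(f"samples missing from population map: {unknown}")

    chroms: List[str] = []
    poss: List[int] = []
    cats: List[str] = []
    quals: List[float] = []
    indels: List[bool] = []
    gts: List[np.ndarray] = []
    depths: List[np.ndarray] = []
    ad_refs: List[np.ndarray] = []
    has_dp = has_ad = True
    for var in vcf:
        key = (var.CHROM, var.POS)
        if key not in cat_by_site:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        cats.append(cat_by_site[key])
        quals.append(var.QUAL if var.QUAL is not None else np.nan)
        indels.append(var.is_indel)
        g = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2, 3=missing
        g[g == 3] = -1
        gts.append(g)
        try:
            dp = var.format("DP")
            depths.append(np.asarray(dp, dtype=np.int32).ravel())
        except (KeyError, TypeError):
            has_dp = False
        try:
            ad = var.format("AD")
            ad_refs.append(np.asarray(ad, dtype=np.int32)[:, 0])
        except (KeyError, TypeError):
            has_ad = False
    vcf.close()
    if not chroms:
        raise ValueError(f"no annotated sites found in {vcf_path}")
    return VariantTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        category=np.asarray(cats, dtype=object),
        genotypes=np.vstack(gts),
        samples=samples,
        populations=np.asarray([popmap[s] for s in samples], dtype=object),
        qual=np.asarray(quals, dtype=float),
        depth=np.vstack(depths) if has_dp and depths else None,
        ad_ref=np.vstack(ad_refs) if has_ad and ad_refs else None,
        is_indel=np.asarray(indels, dtype=bool),
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=erosim
##INFO=<ID=CAT,Number=1,Type=String,Description="Impact category">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(table: VariantTable, path: str | Path, contig_lengths: Optional[Dict[str, int]] = None) -> None:
    """Write a VariantTable as plain-text VCF v4.2 with GT/DP/AD fields."""
    path = Path(path)
    has_aux = table.depth is not None and table.ad_ref is not None
    fmt = "GT:DP:AD" if has_aux else "GT"
    lines = [_VCF_HEADER]
    if contig_lengths:
        for c, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={c},length={ln}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples) + "\n"
    )
    for i in range(table.n_sites):
        qual = table.qual[i] if table.qual is not None else None
        qual_s = "." if qual is None or np.isnan(qual) else f"{qual:g}"
        ref, alt = ("A", "T")
        if table.is_indel is not None and table.is_indel[i]:
            ref, alt = ("AT", "A")
        fields = [
            str(table.chrom[i]),
            str(int(table.pos[i])),
            ".",
            ref,
            alt,
            qual_s,
            "PASS",
            f"CAT={table.category[i]}",
            fmt,
        ]
        cells = []
        for j in range(table.n_samples):
            g = int(table.genotypes[i, j])
            cell = _GT_STRING[g]
            if has_aux:
                dp = int(table.depth[i, j])
                ar = int(table.ad_ref[i, j])
                cell += f":{dp}:{ar},{max(dp - ar, 0)}"
            cells.append(cell)
        lines.append("\t".join(fields + cells) + "\n")
    path.write_text("".join(lines))


def write_roh_bed(segments_by_sample: Dict[str, Sequence[RohSegment]], path: str | Path) -> None:
    """Write per-sample ROH segments as BED (0-based half-open) with
    columns chrom, start, end, sample, n_snps, n_het."""
    with open(path, "w") as fh:
        for sample, segments in segments_by_sample.items():
            for s in segments:
                fh.write(
                    f"{s.chromosome}\t{s.start - 1}\t{s.end}\t{sample}\t{s.n_snps}\t{s.n_het}\n"
                )


def write_genotype_matrix(table: VariantTable, path: str | Path) -> None:
    """Documented genotype-matrix TSV: chrom, pos, category then one dosage
    column per sample (-1 = missing)."""
    df = pd.DataFrame({"chrom": table.chrom, "pos": table.pos, "category": table.category})
    for j, s in enumerate(table.samples):
        df[s] = table.genotypes[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path: str | Path, popmap: Dict[str, str]) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["chrom", "pos", "category"]
    samples = [c for c in df.columns if c not in meta]
    missing = [s for s in samples if s not in popmap]
    if missing:
        raise ValueError(f"samples missing from population map: {missing}")
    return VariantTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        category=df["category"].to_numpy(dtype=object),
        genotypes=df[samples].to_numpy(dtype=np.int8),
        samples=samples,
        populations=np.asarray([popmap[s] for s in samples], dtype=object),
    )
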