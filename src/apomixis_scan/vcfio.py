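"""VCF input/output for genotype matrices.

Reading goes through :mod:`cyvcf2`; writing emits a minimal deterministic
VCF 4.2 text stream (FORMAT ``GT:DP:AD``) that round-trips losslessly
through :func:`read_vcf`.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix, sort_site_table

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_vcf(
    path: str | Path,
    samples: list[str] | None = None,
    all_sites: bool = False,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF path (plain text or bgzipped).
    samples
        Optional subset of sample names to load, in the given order.
    all_sites
        When True, invariant records (no ALT allele) are retained and the
        matrix is flagged ``all_sites``; otherwise invariant records are
        skipped.

    Multi-allelic records are retained but flagged in the site table
    (column ``multiallelic``); downstream site filtering drops them.
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    if samples is not None:
        missing = set(samples) - set(vcf.samples)
        if missing:
            raise KeyError(f"samples not in VCF: {sorted(missing)}")
        vcf.set_samples(samples)
    names = list(vcf.samples)

    has_dp = "##FORMAT=<ID=DP" in vcf.raw_header
    has_ad = "##FORMAT=<ID=AD" in vcf.raw_header
    if not has_ad:
        warnings.warn(
            "VCF lacks per-sample AD: allele depths unavailable, "
            "allele-balance QC will be a no-op",
            stacklevel=2,
        )

    chrom_lengths: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            body = line.split("<", 1)[1].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in body.split(",") if "=" in kv)
            if "ID" in fields and "length" in fields:
                chrom_lengths[fields["ID"]] = int(fields["length"])

    rows = []
    gts, dps, ads_r, ads_a = [], [], [], []
    for variant in vcf:
        alts = [a for a in variant.ALT if a not in (".", "<NON_REF>")]
        invariant = len(alts) == 0
        if invariant and not all_sites:
            continue
        rows.append(
            (
                variant.CHROM,
                variant.POS - 1,  # to 0-based
                variant.REF,
                alts[0] if alts else ".",
                len(alts) > 1,
                not invariant,
            )
        )
        gt = variant.gt_types.astype(np.int8)  # gts012: 3 == unknown
        gt[gt == 3] = MISSING
        if invariant:
            gt[gt != MISSING] = 0
        gts.append(gt)
        if has_dp:
            d = variant.gt_depths.astype(np.int32)
            d[d < 0] = 0
            dps.append(d)
        if has_ad:
            r = variant.gt_ref_depths.astype(np.int32)
            a = variant.gt_alt_depths.astype(np.int32)
            r[r < 0] = 0
            a[a < 0] = 0
            ads_r.append(r)
            ads_a.append(a)

    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "multiallelic", "is_variant"]
    )
    n_sites = len(sites)
    calls = (
        np.stack(gts, axis=1)
        if n_sites
        else np.empty((len(names), 0), dtype=np.int8)
    )
    m = GenotypeMatrix(
        sample_ids=names,
        sites=sites,
        calls=calls,
        depth=np.stack(dps, axis=1) if dps else None,
        ad_ref=np.stack(ads_r, axis=1) if ads_r else None,
        ad_alt=np.stack(ads_a, axis=1) if ads_a else None,
        all_sites=all_sites,
        chrom_lengths=chrom_lengths,
    )
    if samples is not None and names != list(samples):
        m = m.take_samples(list(samples))  # cyvcf2 keeps VCF order
    return m


def write_vcf(m: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix as VCF 4.2 with FORMAT GT:DP:AD (GT only when no depth)."""
    with_depth = m.depth is not None
    with_ad = m.ad_ref is not None
    fmt = "GT" + (":DP" if with_depth else "") + (":AD" if with_ad else "")
    sites = m.sites
    lines = ["##fileformat=VCFv4.2"]
    for chrom in m.chroms():
        lines.append(f"##contig=<ID={chrom},length={m.chrom_length(chrom)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_depth:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if with_ad:
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(m.sample_ids)
    )
    chrom_a = sites["chrom"].to_numpy()
    pos_a = sites["pos"].to_numpy()
    ref_a = sites["ref"].to_numpy()
    alt_a = sites["alt"].to_numpy()
    for j in range(m.n_sites):
        cells = []
        for i in range(m.n_samples):
            g = _GT_STR[int(m.calls[i, j])]
            if with_depth:
                g += f":{int(m.depth[i, j])}"
            if with_ad:
                g += f":{int(m.ad_ref[i, j])},{int(m.ad_alt[i, j])}"
            cells.append(g)
        lines.append(
            f"{chrom_a[j]}\t{pos_a[j] + 1}\t.\t{ref_a[j]}\t{alt_a[j]}\t.\tPASS\t.\t"
            f"{fmt}\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_matrix(m: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    """Write a matrix to ``path`` as VCF or as a genotype-code TSV."""
    if format == "vcf":
        write_vcf(m, path)
    elif format == "tsv":
        df = m.sites[["chrom", "pos", "ref", "alt"]].copy()
        for i, s in enumerate(m.sample_ids):
            df[s] = m.calls[i]
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


__all__ = ["read_vcf", "write_vcf", "write_matrix", "sort_site_table"]
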