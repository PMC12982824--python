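"""Derived deleterious mutation load, stratified by zygosity, haplotype and LOH.

The accounting unit is the derived-allele dosage per call: after
polarizing each site against two outgroups (ancestral = the allele both
outgroups carry as identical homozygotes; anything else leaves the site
unpolarized and excluded), a heterozygote carries one derived allele and a
derived homozygote two. Per sample and functional class (SYN, TOL, DEL,
LOF):

    total_derived = n_het + 2 * n_hom
    pct_hom       = 2 * n_hom / total_derived   (the realized-load share)

Ratios of deleterious classes to synonymous (DEL/SYN, LOF/SYN), separately
for heterozygous and homozygous sites, normalise load across samples;
the 0-fold/4-fold heterozygosity ratio proxies purifying-selection
efficacy. All statistics can be restricted by site masks (haplotype of
origin in a hybrid, LOH vs non-LOH window membership).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from .loh import LOHProfile

FUNCTIONAL_CLASSES = ("SYN", "TOL", "DEL", "LOF")
GRANTHAM_DELETERIOUS_MIN = 150

_AA3 = "SRLPTAVGIFYCHQNKDEMW"
# Grantham (1974) physicochemical distances, upper triangle in _AA3 order
_GRANTHAM_UPPER = [
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],
    [194, 83, 99, 143, 85, 160, 122, 36, 37],
    [174, 154, 139, 202, 154, 170, 196, 215],
    [24, 68, 32, 81, 40, 87, 115],
    [46, 53, 61, 29, 101, 130],
    [94, 23, 42, 142, 174],
    [101, 56, 95, 110],
    [45, 160, 181],
    [126, 152],
    [67],
]

GRANTHAM: dict[tuple[str, str], int] = {}
for _i, _row in enumerate(_GRANTHAM_UPPER):
    for _k, _d in enumerate(_row):
        _a, _b = _AA3[_i], _AA3[_i + 1 + _k]
        GRANTHAM[(_a, _b)] = _d
        GRANTHAM[(_b, _a)] = _d


def grantham_score(aa_from: str, aa_to: str) -> int:
    """Grantham distance between two amino acids (one-letter codes)."""
    if aa_from == aa_to:
        return 0
    try:
        return GRANTHAM[(aa_from.upper(), aa_to.upper())]
    except KeyError:
        raise KeyError(f"no Grantham distance for pair ({aa_from}, {aa_to})") from None


def grantham_classify(
    scores: np.ndarray | float, threshold: int = GRANTHAM_DELETERIOUS_MIN
) -> np.ndarray | str:
    """DEL for scores >= threshold (inclusive), TOL below."""
    if np.isscalar(scores):
        return "DEL" if scores >= threshold else "TOL"
    scores = np.asarray(scores)
    return np.where(scores >= threshold, "DEL", "TOL")


# --------------------------------------------------------------------------- #
# degeneracy classification

_BASES = "ACGT"


def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


_CODE = _codon_table()

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def codon_position_degeneracy(codon: str, position: int) -> str:
    """Degeneracy of one codon position: '4-fold', '0-fold' or 'other'."""
    codon = codon.upper()
    aa = _CODE[codon]
    same = 0
    for b in _BASES:
        if b == codon[position]:
            continue
        alt = codon[:position] + b + codon[position + 1 :]
        if _CODE[alt] == aa:
            same += 1
    if same == 3:
        return "4-fold"
    if same == 0:
        return "0-fold"
    return "other"


def read_cds_gff3(path: str) -> list[dict]:
    """Load CDS features from a GFF3, grouped by parent transcript.

    Returns a list of ``{"id", "chrom", "strand", "exons"}`` with exons as
    0-based half-open intervals in genomic order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    groups: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [cds.id or "gene"])[0]
        g = groups.setdefault(
            parent, {"id": parent, "chrom": cds.seqid, "strand": cds.strand, "exons": []}
        )
        g["exons"].append((cds.start - 1, cds.end))  # GFF is 1-based inclusive
    for g in groups.values():
        g["exons"].sort()
    return list(groups.values())


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def classify_degeneracy(
    reference: dict[str, str], cds_features: list[dict]
) -> dict[tuple[str, int], str]:
    """Per-site degeneracy labels for all coding positions.

    ``reference`` maps chromosome -> sequence; ``cds_features`` as produced
    by :func:`read_cds_gff3`. Genes whose spliced CDS length is not a
    multiple of 3 are skipped with a warning. Positions claimed by several
    genes with conflicting labels are demoted to 'other'.
    """
    labels: dict[tuple[str, int], str] = {}
    for gene in cds_features:
        chrom = gene["chrom"]
        seq = reference[chrom]
        coords: list[int] = []
        for start, end in gene["exons"]:
            coords.extend(range(start, end))
        cds = "".join(seq[i] for i in coords)
        if gene["strand"] == "-":
            coords = coords[::-1]
            cds = cds.translate(_COMPLEMENT)[::-1]
        if len(cds) % 3 != 0:
            warnings.warn(
                f"CDS length of {gene['id']} not divisible by 3; gene skipped",
                stacklevel=2,
            )
            continue
        for c0 in range(0, len(cds), 3):
            codon = cds[c0 : c0 + 3]
            if any(b not in _BASES for b in codon):
                continue
            for offset in range(3):
                key = (chrom, coords[c0 + offset])
                label = codon_position_degeneracy(codon, offset)
                if key in labels and labels[key] != label:
                    labels[key] = "other"
                else:
                    labels[key] = label
    return labels


def annotate_degeneracy(
    sites: pd.DataFrame, labels: dict[tuple[str, int], str]
) -> np.ndarray:
    """Map degeneracy labels onto a site table ('noncoding' where absent)."""
    return np.array(
        [
            labels.get((c, p), "noncoding")
            for c, p in zip(sites["chrom"], sites["pos"])
        ],
        dtype=object,
    )


# --------------------------------------------------------------------------- #
# polarization and derived dosage

ANC_REF = 0
ANC_ALT = 1
UNPOLARIZED = -1


def polarize(m: GenotypeMatrix, outgroup_ids: list[str]) -> np.ndarray:
    """Ancestral-allele state per site from strict two-outgroup concordance.

    Requires both outgroups homozygous for the same allele; otherwise the
    site is unpolarized (-1) and excluded from derived-allele counts.
    Returns int8 codes: 0 = ref ancestral, 1 = alt ancestral, -1 =
    unpolarized.
    """
    if len(outgroup_ids) != 2:
        raise ValueError("exactly two outgroup samples required")
    a = m.calls[m.sample_index(outgroup_ids[0])]
    b = m.calls[m.sample_index(outgroup_ids[1])]
    anc = np.full(m.n_sites, UNPOLARIZED, dtype=np.int8)
    anc[(a == HOM_REF) & (b == HOM_REF)] = ANC_REF
    anc[(a == HOM_ALT) & (b == HOM_ALT)] = ANC_ALT
    return anc


def derived_dosage(m: GenotypeMatrix, ancestral: np.ndarray) -> np.ndarray:
    """Per-call derived-allele dosage (0/1/2); -1 = missing or unpolarized."""
    d = np.full(m.calls.shape, -1, dtype=np.int8)
    anc_ref = ancestral == ANC_REF
    anc_alt = ancestral == ANC_ALT
    calls = m.calls
    d[:, anc_ref] = np.select(
        [calls[:, anc_ref] == HOM_REF, calls[:, anc_ref] == HET, calls[:, anc_ref] == HOM_ALT],
        [0, 1, 2],
        default=-1,
    )
    d[:, anc_alt] = np.select(
        [calls[:, anc_alt] == HOM_ALT, calls[:, anc_alt] == HET, calls[:, anc_alt] == HOM_REF],
        [0, 1, 2],
        default=-1,
    )
    return d


# --------------------------------------------------------------------------- #
# load summaries


@dataclass
class SiteAnnotation:
    """Per-site functional annotation aligned (or alignable) to a matrix.

    ``table`` columns: chrom, pos, degeneracy, func_class and optionally
    ancestral (int codes as in :func:`polarize`), haplotype_origin
    ({'E','W','none'}), grantham.
    """

    table: pd.DataFrame

    def aligned_to(self, m: GenotypeMatrix) -> pd.DataFrame:
        merged = m.sites[["chrom", "pos"]].merge(
            self.table, on=["chrom", "pos"], how="left"
        )
        for col, default in (("degeneracy", "noncoding"), ("func_class", "none")):
            if col in merged:
                merged[col] = merged[col].fillna(default)
            else:
                merged[col] = default
        if "ancestral" in merged:
            merged["ancestral"] = merged["ancestral"].fillna(UNPOLARIZED).astype(np.int8)
        if "haplotype_origin" in merged:
            merged["haplotype_origin"] = merged["haplotype_origin"].fillna("none")
        return merged

    @classmethod
    def read_tsv(cls, path: str) -> "SiteAnnotation":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def load_counts(
    m: GenotypeMatrix,
    ann: SiteAnnotation,
    ancestral: np.ndarray | None = None,
    samples: list[str] | None = None,
    site_mask: np.ndarray | None = None,
    stratum: str = "all",
    classes: tuple[str, ...] = FUNCTIONAL_CLASSES,
) -> pd.DataFrame:
    """Per-sample derived-allele load by functional class.

    ``ancestral`` defaults to the annotation's ``ancestral`` column.
    ``site_mask`` restricts counting to a site subset (haplotype or region
    stratum). Columns: sample, class, stratum, n_het, n_hom,
    total_derived, pct_hom (NaN when total 0).
    """
    aligned = ann.aligned_to(m)
    if ancestral is None:
        if "ancestral" not in aligned:
            raise ValueError("no ancestral states: polarize first or annotate")
        ancestral = aligned["ancestral"].to_numpy()
    dosage = derived_dosage(m, ancestral)
    func = aligned["func_class"].to_numpy()
    sample_list = samples or m.sample_ids
    rows = []
    for cls_name in classes:
        cmask = func == cls_name
        if site_mask is not None:
            cmask = cmask & site_mask
        for s in sample_list:
            d = dosage[m.sample_index(s), cmask]
            n_het = int((d == 1).sum())
            n_hom = int((d == 2).sum())
            total = n_het + 2 * n_hom
            rows.append(
                (
                    s,
                    cls_name,
                    stratum,
                    n_het,
                    n_hom,
                    total,
                    (2 * n_hom / total) if total else np.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "class", "stratum", "n_het", "n_hom", "total_derived", "pct_hom"],
    )


def load_ratios(summary: pd.DataFrame) -> pd.DataFrame:
    """DEL/SYN and LOF/SYN ratios at het and hom sites, per sample x stratum."""
    rows = []
    for (sample, stratum), sub in summary.groupby(["sample", "stratum"]):
        by = sub.set_index("class")

        def ratio(num: str, den: str, col: str) -> float:
            if num not in by.index or den not in by.index or by.loc[den, col] == 0:
                return np.nan
            return by.loc[num, col] / by.loc[den, col]

        rows.append(
            (
                sample,
                stratum,
                ratio("DEL", "SYN", "n_het"),
                ratio("LOF", "SYN", "n_het"),
                ratio("DEL", "SYN", "n_hom"),
                ratio("LOF", "SYN", "n_hom"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "stratum", "het_del_syn", "het_lof_syn", "hom_del_syn", "hom_lof_syn"],
    )


def haplotype_stratified_load(
    m: GenotypeMatrix, ann: SiteAnnotation, ancestral: np.ndarray | None = None
) -> pd.DataFrame:
    """Load summary split by haplotype of origin (hybrid E/W pools)."""
    aligned = ann.aligned_to(m)
    if "haplotype_origin" not in aligned:
        raise ValueError("annotation has no haplotype_origin column")
    origin = aligned["haplotype_origin"].to_numpy()
    parts = []
    for pool in ("E", "W"):
        parts.append(
            load_counts(m, ann, ancestral=ancestral, site_mask=origin == pool, stratum=pool)
        )
    return pd.concat(parts, ignore_index=True)


def zero_four_ratio(m: GenotypeMatrix, degeneracy: np.ndarray) -> pd.DataFrame:
    """Per-sample ratio of heterozygosity at 0-fold vs 4-fold sites.

    Heterozygosity per class = het calls / non-missing genotyped sites of
    that class. NaN when the sample has no called 4-fold sites or zero
    4-fold heterozygosity.
    """
    degeneracy = np.asarray(degeneracy)
    mask0 = degeneracy == "0-fold"
    mask4 = degeneracy == "4-fold"
    if not mask4.any():
        warnings.warn("no 4-fold sites: ratio undefined", stacklevel=2)
    rows = []
    for i, s in enumerate(m.sample_ids):
        calls = m.calls[i]

        def rate(mask: np.ndarray) -> float:
            nm = (calls[mask] != MISSING).sum()
            return (calls[mask] == HET).sum() / nm if nm else np.nan

        r0, r4 = rate(mask0), rate(mask4)
        rows.append((s, r0, r4, r0 / r4 if r4 and np.isfinite(r4) and r4 > 0 else np.nan))
    return pd.DataFrame(rows, columns=["sample", "het_0fold", "het_4fold", "ratio"])


# --------------------------------------------------------------------------- #
# LOH-region stratification


def site_window_assignment(
    m: GenotypeMatrix, profile: LOHProfile
) -> np.ndarray:
    """Per-site LOH status for one sample: 'LOH' / 'non-LOH' / 'NA'."""
    win = profile.windows
    key = {(c, s): call for c, s, call in zip(win["chrom"], win["start"], win["call"])}
    span = int(win["end"].iloc[0] - win["start"].iloc[0]) if len(win) else 1
    # window span from the grid (all full windows share it)
    spans = (win["end"] - win["start"]).to_numpy()
    span = int(spans.max()) if len(spans) else 1
    return np.array(
        [
            key.get((c, (p // span) * span), "NA")
            for c, p in zip(m.sites["chrom"], m.sites["pos"])
        ],
        dtype=object,
    )


def region_stratified_load(
    m: GenotypeMatrix,
    ann: SiteAnnotation,
    profiles: list[LOHProfile],
    ancestral: np.ndarray | None = None,
) -> pd.DataFrame:
    """Load summary per sample split into LOH vs non-LOH regions.

    Profiles must use the same windowing; each sample is stratified by its
    own LOH profile. Returns the concatenated per-stratum summaries
    (strata 'LOH' and 'non-LOH').
    """
    by_sample = {p.sample: p for p in profiles}
    parts = []
    for s in m.sample_ids:
        if s not in by_sample:
            continue
        status = site_window_assignment(m, by_sample[s])
        for stratum in ("LOH", "non-LOH"):
            parts.append(
                load_counts(
                    m,
                    ann,
                    ancestral=ancestral,
                    samples=[s],
                    site_mask=status == stratum,
                    stratum=stratum,
                )
            )
    return pd.concat(parts, ignore_index=True)


def windows_site_mask(
    m: GenotypeMatrix, profile_windows: pd.DataFrame, window_index: set[int]
) -> np.ndarray:
    """Boolean site mask for a set of window indices of a profile grid."""
    sel = profile_windows.iloc[sorted(window_index)]
    keys = set(zip(sel["chrom"], sel["start"]))
    spans = (profile_windows["end"] - profile_windows["start"]).to_numpy()
    span = int(spans.max()) if len(spans) else 1
    return np.array(
        [
            (c, (p // span) * span) in keys
            for c, p in zip(m.sites["chrom"], m.sites["pos"])
        ]
    )


# --------------------------------------------------------------------------- #
# group comparisons

_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cut, mark in _STARS:
        if p < cut:
            return mark
    return "ns"


def compare_groups(
    a: np.ndarray, b: np.ndarray, test: str = "welch"
) -> tuple[float, float, str]:
    """Two-sided Welch's t-test or Wilcoxon rank-sum between two groups.

    Returns (statistic, p-value, significance stars). No multiple-testing
    correction is applied. Degenerate inputs give NaN with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if test == "welch":
        if len(a) < 2 or len(b) < 2:
            warnings.warn("Welch test needs >=2 values per group", stacklevel=2)
            return np.nan, np.nan, "ns"
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "wilcoxon":
        if len(a) < 1 or len(b) < 1:
            warnings.warn("empty group", stacklevel=2)
            return np.nan, np.nan, "ns"
        if np.array_equal(np.sort(a), np.sort(b)):
            return 0.0, 1.0, "ns"
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue), significance_stars(float(res.pvalue))


__all__ = [
    "FUNCTIONAL_CLASSES",
    "GRANTHAM",
    "grantham_score",
    "grantham_classify",
    "codon_position_degeneracy",
    "classify_degeneracy",
    "annotate_degeneracy",
    "read_cds_gff3",
    "read_fasta",
    "polarize",
    "derived_dosage",
    "SiteAnnotation",
    "load_counts",
    "load_ratios",
    "haplotype_stratified_load",
    "zero_four_ratio",
    "site_window_assignment",
    "region_stratified_load",
    "windows_site_mask",
    "compare_groups",
    "significance_stars",
]
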