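"""Folded site frequency spectrum and diversity statistics.

All estimators work directly on genotype-code arrays. Window statistics
follow the "all sites" convention: per-site difference and comparison
counts are summed within fixed non-overlapping windows and divided at the
window level, so invariant sites contribute to denominators when the
matrix contains them (gVCF/all-sites input). On a variant-only matrix the
same code yields per-variant-site averages, which are upward-biased per bp
and should be interpreted relative, not absolute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import HET, MISSING, GenotypeMatrix


@dataclass
class FoldedSFS:
    """Folded site frequency spectrum over complete-case segregating sites."""

    counts: np.ndarray  # index b-1 holds the count of minor-allele-count b
    n_alleles: int  # 2 x samples

    @property
    def n_segregating(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"minor_allele_count": np.arange(1, len(self.counts) + 1),
             "n_sites": self.counts}
        )


def folded_sfs(m: GenotypeMatrix) -> FoldedSFS:
    """Folded SFS from complete-case sites; monomorphic sites excluded."""
    n_alleles = 2 * m.n_samples
    complete = ~(m.calls == MISSING).any(axis=0)
    ac = m.alt_allele_counts()[complete]
    seg = (ac > 0) & (ac < n_alleles)
    minor = np.minimum(ac[seg], n_alleles - ac[seg])
    n_bins = n_alleles // 2
    counts = np.bincount(minor, minlength=n_bins + 1)[1 : n_bins + 1]
    if counts.sum() == 0:
        import warnings

        warnings.warn("no usable segregating sites: empty SFS", stacklevel=2)
    return FoldedSFS(counts=counts.astype(np.int64), n_alleles=n_alleles)


def _site_diff_comp(sub: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pairwise allele differences and comparable pairs within a set."""
    k = sub.alt_allele_counts().astype(np.float64)
    c = sub.called_allele_counts().astype(np.float64)
    diffs = k * (c - k)
    comps = c * (c - 1) / 2.0
    return diffs, comps


def windowed_diversity(
    m: GenotypeMatrix,
    pops: dict[str, list[str]],
    window: int = 20_000,
) -> pd.DataFrame:
    """Windowed pi (per population), and dxy / Hudson FST for two populations.

    ``pops`` maps population name -> sample ids; one or two populations.
    Windows are fixed non-overlapping tiles from coordinate 0. Columns:
    ``chrom, start, end, n_sites, pi_<name>...`` plus ``dxy, fst`` when two
    populations are given. Windows with no comparable pairs get NaN.
    """
    if not 1 <= len(pops) <= 2:
        raise ValueError("pops must contain one or two sample sets")
    if window <= 0:
        raise ValueError("window must be positive")
    names = list(pops)
    subs = {p: m.take_samples(pops[p]) for p in names}
    per_pop = {p: _site_diff_comp(subs[p]) for p in names}

    if len(names) == 2:
        a, b = subs[names[0]], subs[names[1]]
        k1, c1 = a.alt_allele_counts().astype(float), a.called_allele_counts().astype(float)
        k2, c2 = b.alt_allele_counts().astype(float), b.called_allele_counts().astype(float)
        dxy_diffs = k1 * (c2 - k2) + k2 * (c1 - k1)
        dxy_comps = c1 * c2

    chrom_arr = m.sites["chrom"].to_numpy()
    pos_arr = m.sites["pos"].to_numpy()
    rows = []
    for chrom in m.chroms():
        on = chrom_arr == chrom
        length = m.chrom_length(chrom)
        widx = pos_arr[on] // window
        n_windows = max(int(length - 1) // window + 1, int(widx.max()) + 1 if on.any() else 1)
        for w in range(n_windows):
            in_w = on.copy()
            in_w[on] = widx == w
            row: dict = {
                "chrom": chrom,
                "start": w * window,
                "end": min((w + 1) * window, length),
                "n_sites": int(in_w.sum()),
            }
            for p in names:
                diffs, comps = per_pop[p]
                tot_c = comps[in_w].sum()
                row[f"pi_{p}"] = diffs[in_w].sum() / tot_c if tot_c > 0 else np.nan
            if len(names) == 2:
                tot = dxy_comps[in_w].sum()
                dxy = dxy_diffs[in_w].sum() / tot if tot > 0 else np.nan
                row["dxy"] = dxy
                mean_pi = np.nanmean([row[f"pi_{p}"] for p in names])
                row["fst"] = (dxy - mean_pi) / dxy if dxy and np.isfinite(dxy) and dxy > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def individual_heterozygosity(
    m: GenotypeMatrix, genome_length: int | None = None
) -> pd.DataFrame:
    """Per-sample h = heterozygous-site count / genome length (per bp)."""
    if genome_length is None:
        genome_length = sum(m.chrom_length(c) for c in m.chroms())
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    n_het = (m.calls == HET).sum(axis=1)
    return pd.DataFrame(
        {"sample": m.sample_ids, "n_het": n_het, "h": n_het / genome_length}
    )


__all__ = [
    "FoldedSFS",
    "folded_sfs",
    "windowed_diversity",
    "individual_heterozygosity",
]
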