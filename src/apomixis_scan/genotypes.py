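"""Diploid genotype matrices.

The central in-memory container is :class:`GenotypeMatrix`: a samples x sites
array of diploid genotype calls with per-call sequencing depth and allele
depths, plus a site table. Genotypes are coded as small integers:

====  =================
code  meaning
====  =================
 0    homozygous reference
 1    heterozygous
 2    homozygous alternate
-1    missing
====  =================

Coordinates are 0-based half-open internally; VCF input/output converts to
and from 1-based positions at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

#: columns every site table must carry
SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid genotype calls with depth information.

    Parameters
    ----------
    sample_ids
        Ordered sample names; rows of ``calls``.
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (pos 0-based) and
        optionally ``multiallelic`` (bool) and ``is_variant`` (bool, for
        all-sites matrices). Sorted by (chrom, pos), unique.
    calls
        int8 array (n_samples, n_sites) of genotype codes.
    depth, ad_ref, ad_alt
        Optional int32 arrays of the same shape: total read depth and
        reference/alternate allele depths per call. ``None`` when the source
        VCF carried no DP/AD.
    all_sites
        True when invariant sites are present (gVCF-derived "all sites"
        matrices), which makes window heterozygosity denominators exact.
    chrom_lengths
        Optional chromosome lengths (bp) used for windowing and h.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    all_sites: bool = False
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"site table lacks columns {missing}")

    # ------------------------------------------------------------------ #

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def mean_depth(self) -> np.ndarray:
        """Per-sample mean depth over called (non-missing) sites."""
        if self.depth is None:
            raise ValueError("matrix carries no depth information")
        called = self.calls != MISSING
        with np.errstate(invalid="ignore"):
            tot = np.where(called, self.depth, 0).sum(axis=1).astype(float)
            n = called.sum(axis=1)
        return np.divide(tot, n, out=np.zeros(self.n_samples), where=n > 0)

    def take_samples(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return replace(
            self,
            sample_ids=list(samples),
            calls=self.calls[idx],
            depth=None if self.depth is None else self.depth[idx],
            ad_ref=None if self.ad_ref is None else self.ad_ref[idx],
            ad_alt=None if self.ad_alt is None else self.ad_alt[idx],
        )

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.shape != (self.n_sites,):
            raise ValueError("site mask length mismatch")
        return replace(
            self,
            sites=self.sites.loc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.sites.iloc[mask].reset_index(drop=True),
            calls=self.calls[:, mask],
            depth=None if self.depth is None else self.depth[:, mask],
            ad_ref=None if self.ad_ref is None else self.ad_ref[:, mask],
            ad_alt=None if self.ad_alt is None else self.ad_alt[:, mask],
        )

    def variant_mask(self) -> np.ndarray:
        """Sites segregating among the samples (any non-ref, non-missing call)."""
        return ((self.calls == HET) | (self.calls == HOM_ALT)).any(axis=0)

    def alt_allele_counts(self) -> np.ndarray:
        """Per-site alternate allele count over non-missing diploid calls."""
        calls = self.calls
        return ((calls == HET).sum(axis=0) + 2 * (calls == HOM_ALT).sum(axis=0)).astype(
            np.int64
        )

    def called_allele_counts(self) -> np.ndarray:
        """Per-site number of called alleles (2 x non-missing genotypes)."""
        return (2 * (self.calls != MISSING).sum(axis=0)).astype(np.int64)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def chrom_length(self, chrom: str) -> int:
        """Known length, else 1 past the last site position."""
        if chrom in self.chrom_lengths:
            return self.chrom_lengths[chrom]
        pos = self.sites.loc[self.sites["chrom"] == chrom, "pos"]
        return int(pos.max()) + 1 if len(pos) else 0


def sort_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    return sites.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
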