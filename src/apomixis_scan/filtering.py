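"""Genotype-level QC and site-level SNP filtering.

Two layers, applied in a fixed order:

1. :func:`genotype_qc` — per-call quality control. Calls whose depth falls
   outside an individual-specific envelope (mean/3 .. 2x mean, with a
   tissue-specific floor of 6x for adults and 3x for embryos) are set
   missing; heterozygous calls failing a depth-tiered allele-balance rule
   (0.2-0.8 at high depth, 0.1-0.9 at moderate depth) are reassigned to the
   homozygote of the majority allele.
2. :func:`site_filters` — the six-step site pipeline: (1) biallelic SNPs
   only; (2) optional site-QUAL floor; (3) missing-rate ceiling;
   (4) singleton removal; (5) exclusion of coding regions plus 20-kb
   flanks; (6) thinning to one SNP per 20-kb window. Each step logs its
   retention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

#: (min_depth, low, high) allele-balance tiers, most stringent tier first
ADULT_BALANCE_RULES = [(20, 0.2, 0.8), (10, 0.1, 0.9)]
EMBRYO_BALANCE_RULES = [(6, 0.2, 0.8), (3, 0.1, 0.9)]


@dataclass
class FilterConfig:
    biallelic_only: bool = True
    depth_lower_factor: float = 1.0 / 3.0
    depth_upper_factor: float = 2.0
    min_depth_floor_adult: int = 6
    min_depth_floor_embryo: int = 3
    max_missing_rate: float | None = None
    drop_singletons: bool = True
    neutral_exclude_flank: int = 20_000
    thin_window: int = 20_000
    site_qual_min: float | None = None  # optional step-2 QUAL filter, off by default
    allele_balance_rules: dict[str, list[tuple[int, float, float]]] = field(
        default_factory=lambda: {
            "adult": list(ADULT_BALANCE_RULES),
            "embryo": list(EMBRYO_BALANCE_RULES),
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.depth_lower_factor < self.depth_upper_factor:
            raise ValueError("require 0 < depth_lower_factor < depth_upper_factor")
        if self.neutral_exclude_flank < 0 or self.thin_window < 0:
            raise ValueError("flank and thin_window must be >= 0")
        for rules in self.allele_balance_rules.values():
            for _, lo, hi in rules:
                if not (0 <= lo < hi <= 1):
                    raise ValueError(f"bad balance bounds ({lo}, {hi})")

    def depth_floor(self, tissue: str) -> int:
        if tissue == "adult":
            return self.min_depth_floor_adult
        if tissue == "embryo":
            return self.min_depth_floor_embryo
        raise ValueError(f"unknown tissue {tissue!r} (expected 'adult' or 'embryo')")


def genotype_qc(
    m: GenotypeMatrix, cfg: FilterConfig | None = None, tissue: str = "adult"
) -> GenotypeMatrix:
    """Apply per-call depth-envelope and allele-balance QC.

    Returns a new matrix; never creates heterozygotes and never changes a
    homozygote except to missing.
    """
    cfg = cfg or FilterConfig()
    floor = cfg.depth_floor(tissue)
    if m.depth is None:
        warnings.warn("no depth information: genotype QC is a no-op", stacklevel=2)
        return m

    calls = m.calls.copy()
    depth = m.depth
    mean = m.mean_depth()  # over called sites of the input
    low = np.maximum(mean * cfg.depth_lower_factor, floor)[:, None]
    high = (mean * cfg.depth_upper_factor)[:, None]
    bad_depth = (calls != MISSING) & ((depth < low) | (depth > high))
    calls[bad_depth] = MISSING

    if m.ad_ref is None or m.ad_alt is None:
        warnings.warn(
            "no AD information: allele-balance rule skipped", stacklevel=2
        )
    else:
        rules = sorted(
            cfg.allele_balance_rules[tissue], key=lambda r: r[0], reverse=True
        )
        het = calls == HET
        total = m.ad_ref + m.ad_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            balance = np.where(total > 0, m.ad_alt / np.maximum(total, 1), np.nan)
        assigned = np.zeros_like(het)
        for min_d, lo, hi in rules:
            tier = het & ~assigned & (depth >= min_d)
            assigned |= tier
            fail = tier & ~((balance >= lo) & (balance <= hi))
            calls[fail & (balance > 0.5)] = HOM_ALT
            calls[fail & ~(balance > 0.5)] = HOM_REF

    out = GenotypeMatrix(
        sample_ids=m.sample_ids,
        sites=m.sites,
        calls=calls,
        depth=m.depth,
        ad_ref=m.ad_ref,
        ad_alt=m.ad_alt,
        all_sites=m.all_sites,
        chrom_lengths=m.chrom_lengths,
    )
    return out


def _exclusion_mask(
    sites: pd.DataFrame, intervals: pd.DataFrame, flank: int
) -> np.ndarray:
    """True where a site falls inside any interval expanded by ``flank``."""
    hit = np.zeros(len(sites), dtype=bool)
    for chrom, sub in intervals.groupby("chrom"):
        starts = np.maximum(sub["start"].to_numpy() - flank, 0)
        ends = sub["end"].to_numpy() + flank
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        # merge overlapping intervals
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.array(merged_s)
        me = np.array(merged_e)
        on_chrom = (sites["chrom"] == chrom).to_numpy()
        pos = sites.loc[on_chrom, "pos"].to_numpy()
        idx = np.searchsorted(ms, pos, side="right") - 1
        inside = (idx >= 0) & (pos < me[np.clip(idx, 0, None)])
        hit[on_chrom] = inside
    return hit


def site_filters(
    m: GenotypeMatrix,
    cfg: FilterConfig | None = None,
    coding_intervals: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the six-step site filter pipeline.

    ``coding_intervals`` is a DataFrame with columns ``chrom, start, end``
    (0-based half-open). The neutral-exclusion step runs exactly when
    intervals are given; each interval is expanded by
    ``cfg.neutral_exclude_flank`` on both sides.

    Returns ``(filtered matrix, retention log)`` where the log has columns
    ``step, sites_in, sites_out``. Invariant records of an all-sites matrix
    are exempt from the variant-specific steps (biallelic, singleton) but
    subject to exclusion and thinning.
    """
    cfg = cfg or FilterConfig()
    log: list[tuple[str, int, int]] = []
    is_variant = (
        m.sites["is_variant"].to_numpy()
        if "is_variant" in m.sites.columns
        else np.ones(m.n_sites, dtype=bool)
    )

    def apply(step: str, keep: np.ndarray, cur: GenotypeMatrix) -> GenotypeMatrix:
        nonlocal is_variant
        log.append((step, cur.n_sites, int(keep.sum())))
        is_variant = is_variant[keep]
        return cur.take_sites(keep)

    cur = m
    # (1) biallelic SNPs
    if cfg.biallelic_only:
        multi = (
            cur.sites["multiallelic"].to_numpy()
            if "multiallelic" in cur.sites.columns
            else np.zeros(cur.n_sites, dtype=bool)
        )
        snp = (
            (cur.sites["ref"].str.len() == 1)
            & ((cur.sites["alt"].str.len() == 1) | ~is_variant)
        ).to_numpy()
        cur = apply("biallelic", ~multi & snp, cur)

    # (2) optional site-QUAL floor (off by default; depth QC is per-call)
    if cfg.site_qual_min is not None:
        if "qual" not in cur.sites.columns:
            raise ValueError("site_qual_min set but site table has no 'qual'")
        cur = apply(
            "site_qual",
            cur.sites["qual"].to_numpy() >= cfg.site_qual_min,
            cur,
        )

    # (3) missing-rate ceiling
    if cfg.max_missing_rate is not None:
        miss = (cur.calls == MISSING).mean(axis=0)
        cur = apply("missing_rate", miss <= cfg.max_missing_rate, cur)

    # (4) singleton removal (minor-allele count over retained samples == 1)
    if cfg.drop_singletons:
        ac = cur.alt_allele_counts()
        an = cur.called_allele_counts()
        mac = np.minimum(ac, an - ac)
        cur = apply("singletons", ~(is_variant & (mac == 1)), cur)

    # (5) neutral exclusion: coding intervals +/- flank
    if coding_intervals is not None:
        hit = _exclusion_mask(cur.sites, coding_intervals, cfg.neutral_exclude_flank)
        cur = apply("coding_exclusion", ~hit, cur)

    # (6) thinning: first site per window per chromosome
    if cfg.thin_window:
        key = pd.DataFrame(
            {
                "chrom": cur.sites["chrom"],
                "win": cur.sites["pos"] // cfg.thin_window,
            }
        )
        keep = ~key.duplicated().to_numpy()
        cur = apply("thinning", keep, cur)

    return cur, pd.DataFrame(log, columns=["step", "sites_in", "sites_out"])


__all__ = [
    "FilterConfig",
    "genotype_qc",
    "site_filters",
    "ADULT_BALANCE_RULES",
    "EMBRYO_BALANCE_RULES",
]
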