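"""Windowed heterozygosity, LOH calling, and residual-sex detection.

Heterozygosity is computed per sample in fixed non-overlapping 50-kb
windows as heterozygous sites / non-missing sites; windows with more than
half their sites missing are NA. A window is a loss-of-heterozygosity
(LOH) window when its value is strictly below the cutoff (default 0.001;
stringent variant 0.0005), and maximal runs of consecutive LOH windows
form LOH blocks.

On a variant-only matrix the denominator falls back to the callable window
span in bp, so values are heterozygous sites per bp — the same scale as
genome-wide individual heterozygosity; this mode is flagged approximate
(``HetTrack.span_denominator``).

Embryo sets are screened for residual sexual reproduction by comparing
each embryo's LOH profile to the clonal background of its sibling set: LOH
windows shared by most siblings are background; an embryo with a long run
of novel (non-background) LOH windows, or a large total novel span, is
classified sexual. Novel LOH is the signature of meiotic recombination +
selfing; background LOH is inherited clonally from the mother.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import HET, MISSING, GenotypeMatrix

LOH_CUTOFF = 0.001
LOH_CUTOFF_STRINGENT = 0.0005
WINDOW_SPAN = 50_000

#: minimum callable fraction for a partial terminal window
_PARTIAL_WINDOW_MIN_FRACTION = 0.2


@dataclass
class HetTrack:
    """Per-sample windowed heterozygosity track."""

    sample: str
    windows: pd.DataFrame  # chrom, start, end, n_sites, n_het, het (NaN = NA)
    window_span: int = WINDOW_SPAN
    span_denominator: bool = False  # True when variant-only fallback was used


@dataclass
class LOHProfile:
    sample: str
    cutoff: float
    windows: pd.DataFrame  # chrom, start, end, het, call in {LOH, non-LOH, NA}
    blocks: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def loh_window_index(self) -> set[int]:
        return set(np.flatnonzero((self.windows["call"] == "LOH").to_numpy()))

    def na_window_index(self) -> set[int]:
        return set(np.flatnonzero((self.windows["call"] == "NA").to_numpy()))


@dataclass
class EmbryoClassification:
    embryo: str
    mother: str
    label: str  # apomictic | sexual
    novel_loh_windows: set[int]
    novel_span: int
    ancestral_loh_windows: set[int] = field(default_factory=set)


def _window_grid(m: GenotypeMatrix, window: int) -> pd.DataFrame:
    rows = []
    for chrom in m.chroms():
        length = m.chrom_length(chrom)
        n = max((int(length) - 1) // window + 1, 1)
        for w in range(n):
            rows.append((chrom, w * window, min((w + 1) * window, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_heterozygosity(
    m: GenotypeMatrix,
    window: int = WINDOW_SPAN,
    tissue: str = "adult",
    samples: list[str] | None = None,
) -> list[HetTrack]:
    """Windowed heterozygosity per sample.

    Expects genotype QC (depth envelope + allele balance for the matching
    ``tissue``) to have been applied already. With an all-sites matrix the
    denominator is the per-window count of non-missing sites and windows
    with >50% missing sites are NA; with a variant-only matrix the
    denominator is the callable window span (approximate, flagged).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if tissue not in ("adult", "embryo"):
        raise ValueError(f"unknown tissue {tissue!r}")
    grid = _window_grid(m, window)
    span_mode = not m.all_sites
    chrom_arr = m.sites["chrom"].to_numpy()
    pos_arr = m.sites["pos"].to_numpy()
    sample_list = samples or m.sample_ids

    # map each site to its row in the window grid
    grid_key = {
        (c, s): i for i, (c, s) in enumerate(zip(grid["chrom"], grid["start"]))
    }
    site_win = np.array(
        [grid_key[(c, (p // window) * window)] for c, p in zip(chrom_arr, pos_arr)],
        dtype=np.int64,
    ) if m.n_sites else np.empty(0, dtype=np.int64)

    n_win = len(grid)
    span = (grid["end"] - grid["start"]).to_numpy()
    tracks = []
    for s in sample_list:
        i = m.sample_index(s)
        calls = m.calls[i]
        non_missing = np.bincount(site_win[calls != MISSING], minlength=n_win)
        n_total = np.bincount(site_win, minlength=n_win)
        n_het = np.bincount(site_win[calls == HET], minlength=n_win)
        if span_mode:
            denom = span.astype(float)
            with np.errstate(invalid="ignore"):
                het = n_het / denom
            # NA when over half of this sample's records in the window are missing
            na = (n_total > 0) & (non_missing < 0.5 * n_total)
        else:
            denom = non_missing.astype(float)
            het = np.divide(
                n_het, denom, out=np.full(n_win, np.nan), where=denom > 0
            )
            # NA iff >50% of the window's sites are missing (strict), or no data
            na = (n_total == 0) | (non_missing < 0.5 * n_total)
        # short partial terminal windows are unreliable
        na |= span < _PARTIAL_WINDOW_MIN_FRACTION * window
        het = np.where(na, np.nan, het)
        df = grid.copy()
        df["n_sites"] = non_missing
        df["n_het"] = n_het
        df["het"] = het
        tracks.append(
            HetTrack(sample=s, windows=df, window_span=window, span_denominator=span_mode)
        )
    return tracks


def call_loh(track: HetTrack, cutoff: float = LOH_CUTOFF) -> LOHProfile:
    """Call LOH windows (het strictly below cutoff) and merge them into blocks."""
    df = track.windows.copy()
    het = df["het"].to_numpy()
    call = np.where(np.isnan(het), "NA", np.where(het < cutoff, "LOH", "non-LOH"))
    df["call"] = call
    # maximal runs of consecutive LOH windows on the same chromosome
    blocks = []
    run_start = None
    for idx in range(len(df) + 1):
        is_loh = idx < len(df) and call[idx] == "LOH"
        contiguous = (
            run_start is not None
            and idx < len(df)
            and df["chrom"].iat[idx] == df["chrom"].iat[idx - 1]
            and df["start"].iat[idx] == df["end"].iat[idx - 1]
        )
        if is_loh and run_start is None:
            run_start = idx
        elif run_start is not None and not (is_loh and contiguous):
            blocks.append(
                (
                    df["chrom"].iat[run_start],
                    int(df["start"].iat[run_start]),
                    int(df["end"].iat[idx - 1]),
                    idx - run_start,
                )
            )
            run_start = idx if is_loh else None
    block_df = pd.DataFrame(blocks, columns=["chrom", "start", "end", "n_windows"])
    return LOHProfile(sample=track.sample, cutoff=cutoff, windows=df, blocks=block_df)


def benchmark_cutoff(control_tracks: list[HetTrack], cutoff: float = LOH_CUTOFF) -> float:
    """Pooled fraction of non-NA control windows below the cutoff.

    Run on a sexual control population, this is the expected LOH
    false-positive rate for the cutoff.
    """
    below = total = 0
    for t in control_tracks:
        het = t.windows["het"].to_numpy()
        ok = ~np.isnan(het)
        total += int(ok.sum())
        below += int((het[ok] < cutoff).sum())
    if total == 0:
        raise ValueError("no non-NA windows in control set")
    return below / total


def profile_concordance(
    profiles: list[LOHProfile], cluster_threshold: float = 0.8
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Pairwise Jaccard similarity of LOH-window sets + single-linkage clusters.

    Windows NA in either member of a pair are excluded from that pair's
    union/intersection. Profiles sharing Jaccard >= ``cluster_threshold``
    are linked; clusters are the connected components.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    n_win = {len(p.windows) for p in profiles}
    if len(n_win) != 1:
        raise ValueError("profiles have inconsistent windowing")
    names = [p.sample for p in profiles]
    loh_sets = [p.loh_window_index() for p in profiles]
    na_sets = [p.na_window_index() for p in profiles]
    rows = []
    g = nx.Graph()
    g.add_nodes_from(names)
    for a in range(len(profiles)):
        for b in range(a + 1, len(profiles)):
            excl = na_sets[a] | na_sets[b]
            sa = loh_sets[a] - excl
            sb = loh_sets[b] - excl
            union = len(sa | sb)
            jac = len(sa & sb) / union if union else 1.0
            rows.append((names[a], names[b], jac))
            if jac >= cluster_threshold:
                g.add_edge(names[a], names[b])
    clusters = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "jaccard"]), clusters


def _novel_runs(windows: pd.DataFrame, novel: set[int]) -> list[list[int]]:
    """Maximal runs of consecutive (same-chromosome, adjacent) novel windows."""
    runs: list[list[int]] = []
    cur: list[int] = []
    for idx in sorted(novel):
        if (
            cur
            and idx == cur[-1] + 1
            and windows["chrom"].iat[idx] == windows["chrom"].iat[cur[-1]]
            and windows["start"].iat[idx] == windows["end"].iat[cur[-1]]
        ):
            cur.append(idx)
        else:
            if cur:
                runs.append(cur)
            cur = [idx]
    if cur:
        runs.append(cur)
    return runs


def detect_sexual_embryos(
    profiles_by_mother: dict[str, list[LOHProfile]],
    min_block_windows: int = 10,
    min_novel_span: int = 2_000_000,
    background_fraction: float = 0.8,
    min_group_size: int = 5,
) -> list[EmbryoClassification]:
    """Classify embryos as apomictic or sexual against their sibling background.

    Background LOH windows are those LOH in at least ``background_fraction``
    of the mother's embryos (fraction over embryos with a non-NA call). An
    embryo is sexual when it has a run of >= ``min_block_windows``
    consecutive novel LOH windows, or novel LOH totalling
    >= ``min_novel_span`` bp.
    """
    out: list[EmbryoClassification] = []
    for mother, profiles in profiles_by_mother.items():
        if len(profiles) < min_group_size:
            warnings.warn(
                f"mother {mother}: only {len(profiles)} embryos "
                f"(< {min_group_size}), group skipped",
                stacklevel=2,
            )
            continue
        n_win = len(profiles[0].windows)
        loh_count = np.zeros(n_win)
        non_na = np.zeros(n_win)
        for p in profiles:
            call = p.windows["call"].to_numpy()
            loh_count += call == "LOH"
            non_na += call != "NA"
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.divide(loh_count, non_na, out=np.zeros(n_win), where=non_na > 0)
        background = set(np.flatnonzero(frac >= background_fraction))
        windows = profiles[0].windows
        spans = (windows["end"] - windows["start"]).to_numpy()
        for p in profiles:
            novel = p.loh_window_index() - background
            runs = _novel_runs(windows, novel)
            novel_span = int(spans[sorted(novel)].sum()) if novel else 0
            sexual = (
                any(len(r) >= min_block_windows for r in runs)
                or novel_span >= min_novel_span
            )
            out.append(
                EmbryoClassification(
                    embryo=p.sample,
                    mother=mother,
                    label="sexual" if sexual else "apomictic",
                    novel_loh_windows=novel,
                    novel_span=novel_span,
                )
            )
    return out


def partition_loh(
    profiles_by_mother: dict[str, list[LOHProfile]],
    classifications: list[EmbryoClassification],
    min_non_na_fraction: float = 0.8,
) -> dict[str, dict]:
    """Split embryo LOH into ancestral and novel window sets.

    Ancestral LOH windows are LOH in every embryo with a non-NA call and
    non-NA in >= ``min_non_na_fraction`` of embryos; the remainder of a
    sexual embryo's LOH windows are its novel set. Returns, per mother,
    ``{"ancestral": set, "novel": {embryo: set}}``; classifications are
    updated in place with the ancestral set.
    """
    label = {c.embryo: c for c in classifications}
    out: dict[str, dict] = {}
    for mother, profiles in profiles_by_mother.items():
        n_win = len(profiles[0].windows)
        loh_count = np.zeros(n_win)
        non_na = np.zeros(n_win)
        for p in profiles:
            call = p.windows["call"].to_numpy()
            loh_count += call == "LOH"
            non_na += call != "NA"
        ancestral = set(
            np.flatnonzero(
                (non_na >= min_non_na_fraction * len(profiles))
                & (loh_count == non_na)
                & (non_na > 0)
            )
        )
        novel = {}
        for p in profiles:
            c = label.get(p.sample)
            if c is not None:
                c.ancestral_loh_windows = ancestral & p.loh_window_index()
            if c is not None and c.label == "sexual":
                novel[p.sample] = p.loh_window_index() - ancestral
        out[mother] = {"ancestral": ancestral, "novel": novel}
    return out


__all__ = [
    "HetTrack",
    "LOHProfile",
    "EmbryoClassification",
    "window_heterozygosity",
    "call_loh",
    "benchmark_cutoff",
    "profile_concordance",
    "detect_sexual_embryos",
    "partition_loh",
    "LOH_CUTOFF",
    "LOH_CUTOFF_STRINGENT",
    "WINDOW_SPAN",
]
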