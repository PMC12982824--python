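"""Forward simulation of clonal complexes, hybrids and embryo sets.

The generator emulates the sampling design of a facultatively apomictic
tree complex: adult clonal lineages connected by occasional sexual
pedigree links, an F1-like hybrid taxon carrying two divergent haplotype
pools with asymmetric deleterious load, and polyembryonic embryo sets in
which a minority of embryos arise by selfing (meiosis with crossovers,
creating loss-of-heterozygosity tracts) rather than by clonal copying of
the mother.

Sites are unlinked (drawn independently per bp) by design: none of the
statistics the pipeline computes require linkage disequilibrium, while
crossover-driven LOH tracts are positional and simulated explicitly.
Genotypes are emitted as true diploid calls; :func:`apply_sequencing_model`
overlays Poisson depth, binomial allele sampling at heterozygotes,
symmetric genotype error and missingness to produce observed calls.

A small gene complement (single-exon CDS intervals with real random codon
sequences) is placed on each chromosome so that every coding site has a
well-defined degeneracy (0-fold/4-fold/other) computed from its codon;
functional classes (SYN at 4-fold; DEL/TOL/LOF at 0-fold) are drawn from
configurable per-pool fractions. The reference FASTA and GFF3 emitted by
:func:`write_simulation` are exactly consistent with these labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from .load import codon_position_degeneracy, _CODE  # shared genetic code
from .vcfio import write_vcf

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_GT_FROM_DOSE = np.array([HOM_REF, HET, HOM_ALT], dtype=np.int8)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters of the simulated complex.

    Depth means mirror the sequencing design (30x leaves, 10x embryos);
    the default genome is 4 chromosomes x 5 Mb, a desk-scale stand-in for
    a hickory-sized genome with all window logic length-agnostic.
    """

    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    polymorphism_density: float = 0.02  # polymorphic sites per bp
    founder_diversity: float = 0.3  # expected het per site, 'fixed' spectrum
    founder_freq_spectrum: str = "neutral"  # neutral | uniform | fixed
    n_clonal_lineages: int = 5
    lineage_sizes: tuple[int, ...] = (9, 21, 9, 2, 3)
    somatic_mutation_rate: float = 1.0  # mutations / genome / generation
    somatic_generations: int = 10
    hybrid_divergence: float = 0.01  # fixed differences per bp between pools
    deleterious_fractions: dict = field(
        default_factory=lambda: {"DEL": 0.3, "TOL": 0.6, "LOF": 0.1}
    )
    p_sexual_embryo: float = 0.15
    crossovers_per_chromosome: float = 1.0
    depth_mean_adult: float = 30.0
    depth_mean_embryo: float = 10.0
    genotype_error: float = 0.001
    missing_rate: float = 0.01
    genes_per_chromosome: int = 20
    gene_length: int = 3000  # bp, single-exon CDS, multiple of 3
    outgroup_divergence: float = 0.02
    n_embryos: int = 60
    ancestral_loh_fraction: float = 0.1
    ancestral_loh_tract_bp: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "polymorphism_density": self.polymorphism_density,
            "founder_diversity": self.founder_diversity,
            "hybrid_divergence": self.hybrid_divergence,
            "p_sexual_embryo": self.p_sexual_embryo,
            "genotype_error": self.genotype_error,
            "missing_rate": self.missing_rate,
            "outgroup_divergence": self.outgroup_divergence,
            "ancestral_loh_fraction": self.ancestral_loh_fraction,
        }
        for k, v in probs.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{k}={v} not in [0, 1]")
        if self.founder_diversity > 0.5:
            raise ConfigurationError("founder_diversity cannot exceed 0.5")
        for k in ("n_chromosomes", "chrom_length", "gene_length"):
            if getattr(self, k) <= 0:
                raise ConfigurationError(f"{k} must be positive")
        if self.gene_length % 3:
            raise ConfigurationError("gene_length must be a multiple of 3")
        if self.hybrid_divergence + 2 * self.polymorphism_density >= 1:
            raise ConfigurationError(
                "hybrid_divergence + within-pool polymorphism must stay < 1 per bp"
            )
        if self.founder_freq_spectrum not in ("neutral", "uniform", "fixed"):
            raise ConfigurationError(
                f"unknown founder_freq_spectrum {self.founder_freq_spectrum!r}"
            )
        fr = self.deleterious_fractions
        pools = fr if set(fr) <= {"E", "W"} else {"both": fr}
        for pool, f in pools.items():
            missing = {"DEL", "TOL", "LOF"} - set(f)
            if missing:
                raise ConfigurationError(
                    f"deleterious_fractions ({pool}) missing classes {sorted(missing)}"
                )

    def fractions_for(self, pool: str) -> dict:
        fr = self.deleterious_fractions
        return fr[pool] if set(fr) <= {"E", "W"} else fr

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class TruthSet:
    """Ground truth of a simulated dataset."""

    clone_assignment: dict[str, str]
    pedigree: list[tuple[str, str, str | None, str]]  # child, p1, p2, relation
    crossover_breakpoints: dict[str, list[tuple[str, int]]]
    true_loh_tracts: dict[str, list[tuple[str, int, int]]]
    ancestral_allele: np.ndarray  # 0 = ref ancestral (per polymorphic site)
    site_class: np.ndarray  # SYN/TOL/DEL/LOF/none
    degeneracy: np.ndarray  # 0-fold/4-fold/other/noncoding
    haplotype_origin: np.ndarray  # E/W/none
    sample_meta: pd.DataFrame  # sample, taxon, tissue, mother


@dataclass
class Genome:
    """Simulated genome scaffold: chromosomes, CDS genes, degeneracy labels."""

    chrom_names: list[str]
    chrom_length: int
    cds_features: list[dict]
    gene_seqs: dict[str, str]  # coding-strand sequences
    degeneracy: dict[tuple[str, int], str]
    coding_base: dict[tuple[str, int], str]  # genomic-strand base inside genes

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = [c for c in _CODE if _CODE[c] != "*"]
    return "".join(rng.choice(codons, size=n_codons))


def simulate_genome(config: SimConfig, rng: np.random.Generator) -> Genome:
    """Place genes with random codon sequences; label coding-site degeneracy."""
    features, gene_seqs = [], {}
    degeneracy: dict[tuple[str, int], str] = {}
    coding_base: dict[tuple[str, int], str] = {}
    L, G, glen = config.chrom_length, config.genes_per_chromosome, config.gene_length
    spacing = L / max(G, 1)
    for chrom in config.chrom_names():
        for g in range(G):
            center = (g + 0.5) * spacing
            jitter = rng.uniform(-0.2, 0.2) * spacing
            start = int(np.clip(center + jitter - glen / 2, 0, L - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{chrom}.g{g + 1}"
            seq = _random_cds(rng, glen // 3)
            gene_seqs[gid] = seq
            features.append(
                {"id": gid, "chrom": chrom, "strand": strand,
                 "exons": [(start, start + glen)]}
            )
            coords = list(range(start, start + glen))
            for k, gpos in enumerate(coords):
                ci = k if strand == "+" else glen - 1 - k
                codon = seq[3 * (ci // 3) : 3 * (ci // 3) + 3]
                label = codon_position_degeneracy(codon, ci % 3)
                key = (chrom, gpos)
                degeneracy[key] = label
                base = seq[ci]
                coding_base[key] = base if strand == "+" else _COMP[base]
    return Genome(
        chrom_names=config.chrom_names(),
        chrom_length=L,
        cds_features=features,
        gene_seqs=gene_seqs,
        degeneracy=degeneracy,
        coding_base=coding_base,
    )


# --------------------------------------------------------------------------- #
# site machinery


def _draw_positions(
    rng: np.random.Generator, config: SimConfig, density: float
) -> pd.DataFrame:
    rows = []
    for chrom in config.chrom_names():
        n = rng.binomial(config.chrom_length, density)
        pos = np.sort(
            rng.choice(config.chrom_length, size=n, replace=False)
        )
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return pd.concat(rows, ignore_index=True)


def _alleles_for_sites(
    rng: np.random.Generator, sites: pd.DataFrame, genome: Genome | None
) -> tuple[np.ndarray, np.ndarray]:
    n = len(sites)
    ref = rng.choice(_BASES, size=n)
    if genome is not None:
        for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"])):
            b = genome.coding_base.get((c, int(p)))
            if b is not None:
                ref[i] = b
    shift = rng.integers(1, 4, size=n)
    base_idx = np.searchsorted(_BASES, ref)
    alt = _BASES[(base_idx + shift) % 4]
    return ref, alt


def _spectrum_counts(
    rng: np.random.Generator, config: SimConfig, n_sites: int, n_haps: int
) -> np.ndarray:
    """Derived-allele counts per site in a pool of ``n_haps`` haplotypes."""
    mode = config.founder_freq_spectrum
    if mode == "neutral":
        a = np.arange(1, n_haps)
        w = 1.0 / a
        return rng.choice(a, size=n_sites, p=w / w.sum())
    if mode == "uniform":
        p = rng.uniform(0.05, 0.95, size=n_sites)
        return np.clip(rng.binomial(n_haps, p), 1, n_haps - 1)
    # fixed: allele frequency chosen so expected per-site het == founder_diversity
    p = (1 - np.sqrt(1 - 2 * config.founder_diversity)) / 2
    return rng.binomial(n_haps, np.full(n_sites, p))


def _assign_exact_counts(
    rng: np.random.Generator, counts: np.ndarray, n_haps: int, chunk: int = 50_000
) -> np.ndarray:
    """Haplotype pool (n_haps x n_sites) with exact per-site allele counts."""
    n_sites = len(counts)
    out = np.zeros((n_haps, n_sites), dtype=np.uint8)
    for lo in range(0, n_sites, chunk):
        hi = min(lo + chunk, n_sites)
        r = rng.random((hi - lo, n_haps))
        ranks = r.argsort(axis=1).argsort(axis=1)
        out[:, lo:hi] = (ranks < counts[lo:hi, None]).T
    return out


def _classify_sites(
    rng: np.random.Generator,
    sites: pd.DataFrame,
    genome: Genome,
    fractions: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """(degeneracy, functional class) per site from genome labels + fractions."""
    deg = np.array(
        [genome.degeneracy.get((c, int(p)), "noncoding")
         for c, p in zip(sites["chrom"], sites["pos"])],
        dtype=object,
    )
    cls = np.full(len(sites), "none", dtype=object)
    cls[deg == "4-fold"] = "SYN"
    zero = deg == "0-fold"
    names = ("DEL", "TOL", "LOF")
    pr = np.array([fractions[n] for n in names], dtype=float)
    pr = pr / pr.sum()
    cls[zero] = rng.choice(names, size=int(zero.sum()), p=pr)
    return deg, cls


def _matrix_from_haplotypes(
    haps: np.ndarray, sites: pd.DataFrame, sample_ids: list[str], config: SimConfig
) -> GenotypeMatrix:
    """haps: (n_samples, 2, n_sites) uint8 -> genotype matrix of true calls."""
    dose = haps.sum(axis=1).astype(np.int8)
    calls = _GT_FROM_DOSE[dose]
    site_table = sites.copy()
    site_table["multiallelic"] = False
    site_table["is_variant"] = True
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        sites=site_table,
        calls=calls,
        chrom_lengths={c: config.chrom_length for c in config.chrom_names()},
    )


def _site_frame(
    rng: np.random.Generator, config: SimConfig, genome: Genome, density: float
) -> pd.DataFrame:
    sites = _draw_positions(rng, config, density)
    ref, alt = _alleles_for_sites(rng, sites, genome)
    sites["ref"] = ref
    sites["alt"] = alt
    return sites


def _meta(samples: list[str], taxon: str, tissue: str = "adult",
          mother: str | None = None) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample": samples, "taxon": taxon, "tissue": tissue,
         "mother": mother if mother else "."}
    )


# --------------------------------------------------------------------------- #
# scenario: sexual population


def simulate_sexual_population(
    config: SimConfig, n: int
) -> tuple[GenotypeMatrix, TruthSet]:
    """Random-mating diploid population from a founder haplotype pool.

    Each individual pairs two haplotypes of a 2n founder pool whose
    per-site allele counts follow the configured frequency spectrum, so
    genotype frequencies are Hardy-Weinberg-consistent in expectation.
    """
    if n < 2:
        raise ConfigurationError("sexual population needs n >= 2")
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    sites = _site_frame(rng, config, genome, config.polymorphism_density)
    counts = _spectrum_counts(rng, config, len(sites), 2 * n)
    pool = _assign_exact_counts(rng, counts, 2 * n)
    haps = pool.reshape(n, 2, len(sites))
    samples = [f"sex{i + 1:03d}" for i in range(n)]
    deg, cls = _classify_sites(rng, sites, genome, config.fractions_for("E"))
    m = _matrix_from_haplotypes(haps, sites, samples, config)
    truth = TruthSet(
        clone_assignment={s: s for s in samples},  # everyone its own lineage
        pedigree=[],
        crossover_breakpoints={},
        true_loh_tracts={},
        ancestral_allele=np.zeros(len(sites), dtype=np.int8),
        site_class=cls,
        degeneracy=deg,
        haplotype_origin=np.full(len(sites), "none", dtype=object),
        sample_meta=_meta(samples, "sexual"),
    )
    return m, truth


# --------------------------------------------------------------------------- #
# scenario: clonal complex


def _hw_haplotypes(
    rng: np.random.Generator, freqs: np.ndarray
) -> np.ndarray:
    return (rng.random((2, len(freqs))) < freqs).astype(np.uint8)


def _free_gamete(rng: np.random.Generator, haps: np.ndarray) -> np.ndarray:
    """Gamete under free recombination (unlinked sites)."""
    pick = rng.integers(0, 2, size=haps.shape[1])
    return haps[pick, np.arange(haps.shape[1])]


def mendelian_child(
    rng: np.random.Generator, p1: np.ndarray, p2: np.ndarray
) -> np.ndarray:
    """Offspring haplotype pair from two parents, unlinked transmission."""
    return np.stack([_free_gamete(rng, p1), _free_gamete(rng, p2)])


def simulate_clonal_complex(config: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Clonal lineages whose founders form a sexual pedigree chain.

    Founder k+1 is the offspring of founder k and an unrelated mate
    (first-degree links); members of a lineage are copies of its founder
    plus private somatic mutations (Poisson, hom -> het only).
    """
    if config.n_clonal_lineages < 1:
        raise ConfigurationError("need at least one lineage")
    if len(config.lineage_sizes) != config.n_clonal_lineages:
        raise ConfigurationError(
            f"lineage_sizes has {len(config.lineage_sizes)} entries for "
            f"{config.n_clonal_lineages} lineages"
        )
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    sites = _site_frame(rng, config, genome, config.polymorphism_density)
    n_sites = len(sites)
    pool_haps = 100  # notional founder pool for allele frequencies
    freqs = _spectrum_counts(rng, config, n_sites, pool_haps) / pool_haps

    founders = [_hw_haplotypes(rng, freqs)]
    pedigree: list[tuple[str, str, str | None, str]] = []
    for k in range(1, config.n_clonal_lineages):
        mate = _hw_haplotypes(rng, freqs)
        founders.append(mendelian_child(rng, founders[k - 1], mate))
        pedigree.append((f"L{k + 1}", f"L{k}", None, "parent-offspring"))

    lam = config.somatic_mutation_rate * config.somatic_generations
    samples, hap_list, clones = [], [], {}
    for k, size in enumerate(config.lineage_sizes):
        lineage = f"L{k + 1}"
        for j in range(size):
            name = f"{lineage}_{j + 1:02d}"
            h = founders[k].copy()
            n_mut = rng.poisson(lam)
            if n_mut:
                dose = h.sum(axis=0)
                hom = np.flatnonzero((dose == 0) | (dose == 2))
                if len(hom):
                    targets = rng.choice(hom, size=min(n_mut, len(hom)), replace=False)
                    which = rng.integers(0, 2, size=len(targets))
                    h[which, targets] = 1 - h[which, targets]
            samples.append(name)
            hap_list.append(h)
            clones[name] = lineage
    haps = np.stack(hap_list)
    deg, cls = _classify_sites(rng, sites, genome, config.fractions_for("E"))
    m = _matrix_from_haplotypes(haps, sites, samples, config)
    truth = TruthSet(
        clone_assignment=clones,
        pedigree=pedigree,
        crossover_breakpoints={},
        true_loh_tracts={},
        ancestral_allele=np.zeros(n_sites, dtype=np.int8),
        site_class=cls,
        degeneracy=deg,
        haplotype_origin=np.full(n_sites, "none", dtype=object),
        sample_meta=_meta(samples, "clonal"),
    )
    return m, truth


# --------------------------------------------------------------------------- #
# scenario: hybrid apomict


def simulate_hybrid_apomict(
    config: SimConfig, n: int
) -> tuple[GenotypeMatrix, TruthSet]:
    """F1-like hybrids: one haplotype from pool E, one from pool W.

    Sites comprise fixed differences between the pools (obligate
    heterozygotes; the derived allele arose on pool E's or W's branch with
    equal probability) and within-pool polymorphisms. Deleterious-class
    fractions may differ between pools, producing the asymmetric load of
    an apomictic-origin vs sexual-origin haplotype.
    """
    if config.hybrid_divergence <= 0:
        raise ConfigurationError("hybrid mode requires hybrid_divergence > 0")
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)

    fixed = _site_frame(rng, config, genome, config.hybrid_divergence)
    fixed_origin = np.where(rng.random(len(fixed)) < 0.5, "E", "W")
    poly_e = _site_frame(rng, config, genome, config.polymorphism_density)
    poly_w = _site_frame(rng, config, genome, config.polymorphism_density)

    frames = [fixed, poly_e, poly_w]
    origin = np.concatenate(
        [fixed_origin, np.full(len(poly_e), "E"), np.full(len(poly_w), "W")]
    )
    kind = np.concatenate(
        [np.full(len(fixed), "fixed"), np.full(len(poly_e), "poly"),
         np.full(len(poly_w), "poly")]
    )
    sites = pd.concat(frames, ignore_index=True)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    origin, kind = origin[order], kind[order]
    # drop duplicate coordinates across categories
    dup = sites.duplicated(["chrom", "pos"]).to_numpy()
    sites, origin, kind = sites.loc[~dup].reset_index(drop=True), origin[~dup], kind[~dup]
    n_sites = len(sites)

    pool_haps = 100
    freq = np.zeros(n_sites)
    is_poly = kind == "poly"
    freq[is_poly] = _spectrum_counts(rng, config, int(is_poly.sum()), pool_haps) / pool_haps

    hap_list, samples = [], []
    is_fixed = kind == "fixed"
    for i in range(n):
        hap_e = np.zeros(n_sites, dtype=np.uint8)
        hap_w = np.zeros(n_sites, dtype=np.uint8)
        e_poly = is_poly & (origin == "E")
        w_poly = is_poly & (origin == "W")
        hap_e[e_poly] = rng.random(int(e_poly.sum())) < freq[e_poly]
        hap_w[w_poly] = rng.random(int(w_poly.sum())) < freq[w_poly]
        hap_e[is_fixed & (origin == "E")] = 1  # derived on E branch
        hap_w[is_fixed & (origin == "W")] = 1
        hap_list.append(np.stack([hap_e, hap_w]))
        samples.append(f"hyb{i + 1:03d}")
    haps = np.stack(hap_list)

    deg = np.empty(n_sites, dtype=object)
    cls = np.empty(n_sites, dtype=object)
    for pool in ("E", "W"):
        mask = origin == pool
        sub = sites.loc[mask]
        d, c = _classify_sites(rng, sub, genome, config.fractions_for(pool))
        deg[mask], cls[mask] = d, c

    m = _matrix_from_haplotypes(haps, sites, samples, config)
    truth = TruthSet(
        clone_assignment={s: "hybrid" for s in samples},
        pedigree=[],
        crossover_breakpoints={},
        true_loh_tracts={},
        ancestral_allele=np.zeros(n_sites, dtype=np.int8),
        site_class=cls,
        degeneracy=deg,
        haplotype_origin=origin.astype(object),
        sample_meta=_meta(samples, "hybrid"),
    )
    return m, truth


# --------------------------------------------------------------------------- #
# scenario: embryo sets with residual sex


def _phase(rng: np.random.Generator, genotypes: np.ndarray) -> np.ndarray:
    """Random phase assignment of a genotype-code vector -> (2, S) haplotypes."""
    g = np.asarray(genotypes)
    hap1 = (g == HOM_ALT).astype(np.uint8)
    hap2 = hap1.copy()
    het = g == HET
    coin = rng.random(int(het.sum())) < 0.5
    hap1[het] = coin
    hap2[het] = ~coin
    return np.stack([hap1, hap2])


def _meiotic_gamete(
    rng: np.random.Generator,
    haps: np.ndarray,
    sites: pd.DataFrame,
    chrom_length: int,
    lam: float,
) -> tuple[np.ndarray, list[tuple[str, int]], dict[str, tuple[int, list[int]]]]:
    """One gamete with Poisson(lam) crossovers per chromosome.

    Returns (allele vector, breakpoints, per-chromosome (start phase,
    breakpoints) for tract reconstruction).
    """
    allele = np.empty(haps.shape[1], dtype=np.uint8)
    breaks: list[tuple[str, int]] = []
    phase_map: dict[str, tuple[int, list[int]]] = {}
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        on = chrom_arr == chrom
        k = rng.poisson(lam)
        bps = sorted(int(b) for b in rng.integers(1, chrom_length, size=k))
        start = int(rng.integers(0, 2))
        phase_map[chrom] = (start, bps)
        breaks.extend((chrom, b) for b in bps)
        pick = (start + np.searchsorted(bps, pos_arr[on], side="right")) % 2
        idx = np.flatnonzero(on)
        allele[idx] = haps[pick, idx]
    return allele, breaks, phase_map


def _loh_tracts_from_phases(
    p1: dict[str, tuple[int, list[int]]],
    p2: dict[str, tuple[int, list[int]]],
    chrom_length: int,
) -> list[tuple[str, int, int]]:
    """Intervals where both gametes copied the same maternal haplotype."""
    tracts = []
    for chrom in p1:
        s1, b1 = p1[chrom]
        s2, b2 = p2[chrom]
        bounds = sorted({0, chrom_length, *b1, *b2})
        cur_start = None
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            h1 = (s1 + np.searchsorted(b1, lo, side="right")) % 2
            h2 = (s2 + np.searchsorted(b2, lo, side="right")) % 2
            same = h1 == h2
            if same and cur_start is None:
                cur_start = lo
            elif not same and cur_start is not None:
                tracts.append((chrom, cur_start, lo))
                cur_start = None
        if cur_start is not None:
            tracts.append((chrom, cur_start, chrom_length))
    return tracts


def simulate_embryo_set(
    mother: np.ndarray,
    config: SimConfig,
    n_embryos: int,
    sites: pd.DataFrame,
    rng: np.random.Generator | None = None,
    mother_name: str = "mother",
) -> tuple[GenotypeMatrix, TruthSet]:
    """Polyembryonic embryo set: clonal copies of the mother plus a sexual minority.

    ``mother`` is a genotype-code vector (phase randomized) or a (2, S)
    haplotype pair. Each embryo is an identical clonal copy with
    probability 1 - p_sexual_embryo, else produced by selfing the mother:
    two independent meioses with Poisson(crossovers_per_chromosome)
    crossovers, which creates homozygous tracts wherever both gametes
    copied the same maternal haplotype.
    """
    if n_embryos < 1:
        raise ConfigurationError("n_embryos must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mother = np.asarray(mother)
    mhaps = mother if mother.ndim == 2 else _phase(rng, mother)

    samples, hap_list = [], []
    clones, bkpts, tracts = {}, {}, {}
    for e in range(n_embryos):
        name = f"{mother_name}_e{e + 1:03d}"
        samples.append(name)
        if rng.random() < config.p_sexual_embryo:
            g1, br1, ph1 = _meiotic_gamete(
                rng, mhaps, sites, config.chrom_length, config.crossovers_per_chromosome
            )
            g2, br2, ph2 = _meiotic_gamete(
                rng, mhaps, sites, config.chrom_length, config.crossovers_per_chromosome
            )
            hap_list.append(np.stack([g1, g2]))
            clones[name] = "sexual"
            bkpts[name] = sorted(br1 + br2)
            tracts[name] = _loh_tracts_from_phases(ph1, ph2, config.chrom_length)
        else:
            hap_list.append(mhaps.copy())
            clones[name] = mother_name
    haps = np.stack(hap_list)
    m = _matrix_from_haplotypes(haps, sites, samples, config)
    truth = TruthSet(
        clone_assignment=clones,
        pedigree=[(s, mother_name, mother_name, "selfing")
                  for s in samples if clones[s] == "sexual"],
        crossover_breakpoints=bkpts,
        true_loh_tracts=tracts,
        ancestral_allele=np.zeros(len(sites), dtype=np.int8),
        site_class=np.full(len(sites), "none", dtype=object),
        degeneracy=np.full(len(sites), "noncoding", dtype=object),
        haplotype_origin=np.full(len(sites), "none", dtype=object),
        sample_meta=_meta(samples, "embryo_set", tissue="embryo", mother=mother_name),
    )
    return m, truth


def simulate_embryo_scenario(
    config: SimConfig,
) -> tuple[GenotypeMatrix, TruthSet, np.ndarray]:
    """Mother with ancestral LOH tracts + her embryo set.

    Returns (matrix, truth, mother genotype vector). The mother carries
    homozygous (ancestral LOH) tracts covering ``ancestral_loh_fraction``
    of the genome, which every clonal embryo inherits; selfed embryos add
    novel LOH tracts on top.
    """
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    sites = _site_frame(rng, config, genome, config.polymorphism_density)
    pool_haps = 100
    freqs = _spectrum_counts(rng, config, len(sites), pool_haps) / pool_haps
    mhaps = _hw_haplotypes(rng, freqs)

    # impose ancestral LOH tracts on the mother
    mother_tracts: list[tuple[str, int, int]] = []
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    n_tracts = int(
        np.ceil(
            config.ancestral_loh_fraction * config.chrom_length
            / max(config.ancestral_loh_tract_bp, 1)
        )
    )
    for chrom in config.chrom_names():
        for _ in range(n_tracts):
            start = int(rng.integers(0, max(config.chrom_length - config.ancestral_loh_tract_bp, 1)))
            end = start + config.ancestral_loh_tract_bp
            sel = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end)
            mhaps[1, sel] = mhaps[0, sel]
            mother_tracts.append((chrom, start, end))

    m, truth = simulate_embryo_set(
        mhaps, config, config.n_embryos, sites, rng=rng, mother_name="M1"
    )
    truth.true_loh_tracts["M1"] = mother_tracts
    deg, cls = _classify_sites(rng, sites, genome, config.fractions_for("E"))
    truth.degeneracy, truth.site_class = deg, cls
    mother_genotype = _GT_FROM_DOSE[mhaps.sum(axis=0)]
    return m, truth, mother_genotype


# --------------------------------------------------------------------------- #
# sequencing model and outgroups


def apply_sequencing_model(
    m: GenotypeMatrix,
    config: SimConfig,
    tissue: str = "adult",
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Overlay depth, allele sampling, genotype error and missingness.

    Per call: depth ~ Poisson(depth_mean for the tissue); the genotype is
    flipped to one of the other two states with probability
    ``genotype_error`` (symmetric); calls are missing with probability
    ``missing_rate`` or when depth is 0. Allele depths are binomial(depth,
    1/2) at heterozygotes and concordant at homozygotes.
    """
    mean = {"adult": config.depth_mean_adult, "embryo": config.depth_mean_embryo}[tissue]
    if mean <= 0:
        raise ConfigurationError("depth mean must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    shape = m.calls.shape
    depth = rng.poisson(mean, size=shape).astype(np.int32)
    calls = m.calls.copy()

    flip = (calls != MISSING) & (rng.random(shape) < config.genotype_error)
    offset = rng.integers(1, 3, size=shape, dtype=np.int8)
    calls[flip] = (calls[flip] + offset[flip]) % 3

    drop = (depth == 0) | (rng.random(shape) < config.missing_rate)
    calls[drop] = MISSING

    ad_alt = np.zeros(shape, dtype=np.int32)
    het = calls == HET
    ad_alt[het] = rng.binomial(depth[het], 0.5)
    ad_alt[calls == HOM_ALT] = depth[calls == HOM_ALT]
    ad_ref = np.where(calls != MISSING, depth - ad_alt, 0).astype(np.int32)
    ad_alt[calls == MISSING] = 0
    dp = np.where(calls != MISSING, depth, 0).astype(np.int32)

    return GenotypeMatrix(
        sample_ids=m.sample_ids,
        sites=m.sites,
        calls=calls,
        depth=dp,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        all_sites=m.all_sites,
        chrom_lengths=m.chrom_lengths,
    )


def add_outgroups(
    m: GenotypeMatrix,
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    names: tuple[str, str] = ("OUT1", "OUT2"),
) -> GenotypeMatrix:
    """Append two outgroup samples: homozygous-ancestral calls with
    independent lineage-specific divergence (hom-derived) per outgroup."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    rows = []
    for _ in names:
        g = np.full(m.n_sites, HOM_REF, dtype=np.int8)
        flip = rng.random(m.n_sites) < config.outgroup_divergence
        g[flip] = HOM_ALT
        rows.append(g)
    og_calls = np.stack(rows)
    calls = np.vstack([m.calls, og_calls])
    depth = ad_ref = ad_alt = None
    if m.depth is not None:
        og_depth = rng.poisson(
            config.depth_mean_adult, size=og_calls.shape
        ).astype(np.int32)
        depth = np.vstack([m.depth, og_depth])
        if m.ad_ref is not None:
            og_alt = np.where(og_calls == HOM_ALT, og_depth, 0).astype(np.int32)
            ad_ref = np.vstack([m.ad_ref, og_depth - og_alt])
            ad_alt = np.vstack([m.ad_alt, og_alt])
    out = GenotypeMatrix(
        sample_ids=m.sample_ids + list(names),
        sites=m.sites,
        calls=calls,
        depth=depth,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        all_sites=m.all_sites,
        chrom_lengths=m.chrom_lengths,
    )
    for nm in names:
        truth.clone_assignment[nm] = "outgroup"
    truth.sample_meta = pd.concat(
        [truth.sample_meta, _meta(list(names), "outgroup")], ignore_index=True
    )
    return out


# --------------------------------------------------------------------------- #
# output


def truth_annotation(m: GenotypeMatrix, truth: TruthSet):
    """SiteAnnotation assembled from simulation ground truth."""
    from .load import SiteAnnotation

    return SiteAnnotation(
        pd.DataFrame(
            {
                "chrom": m.sites["chrom"],
                "pos": m.sites["pos"],
                "degeneracy": truth.degeneracy,
                "func_class": truth.site_class,
                "ancestral": truth.ancestral_allele,
                "haplotype_origin": truth.haplotype_origin,
            }
        )
    )


def all_sites_matrix(m: GenotypeMatrix, genome: Genome | None = None) -> GenotypeMatrix:
    """Expand a variant-only matrix to all positions (invariant = hom-ref).

    Intended for small simulated genomes; memory grows with genome size.
    """
    frames = []
    calls_cols = []
    chrom_arr = m.sites["chrom"].to_numpy()
    pos_arr = m.sites["pos"].to_numpy()
    for chrom in m.chroms():
        L = m.chrom_length(chrom)
        pos = np.arange(L)
        ref = np.full(L, "A", dtype=object)
        alt = np.full(L, ".", dtype=object)
        calls = np.zeros((m.n_samples, L), dtype=np.int8)
        on = chrom_arr == chrom
        p = pos_arr[on]
        ref[p] = m.sites.loc[on, "ref"].to_numpy()
        alt[p] = m.sites.loc[on, "alt"].to_numpy()
        calls[:, p] = m.calls[:, on]
        is_var = np.zeros(L, dtype=bool)
        is_var[p] = True
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "multiallelic": False, "is_variant": is_var}
            )
        )
        calls_cols.append(calls)
    return GenotypeMatrix(
        sample_ids=m.sample_ids,
        sites=pd.concat(frames, ignore_index=True),
        calls=np.concatenate(calls_cols, axis=1),
        all_sites=True,
        chrom_lengths=m.chrom_lengths,
    )


def write_reference_fasta(
    genome: Genome, sites: pd.DataFrame, path: str | Path,
    rng: np.random.Generator,
) -> None:
    """Random reference consistent with gene sequences and site ref alleles."""
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            seq = rng.choice(_BASES, size=genome.chrom_length)
            for (c, p), b in genome.coding_base.items():
                if c == chrom:
                    seq[p] = b
            on = sites["chrom"] == chrom
            seq[sites.loc[on, "pos"].to_numpy()] = sites.loc[on, "ref"].to_numpy()
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def write_gff3(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.cds_features:
            start, end = f["exons"][0][0], f["exons"][-1][1]
            fh.write(
                f"{f['chrom']}\tsim\tgene\t{start + 1}\t{end}\t.\t{f['strand']}\t.\t"
                f"ID={f['id']}\n"
            )
            fh.write(
                f"{f['chrom']}\tsim\tmRNA\t{start + 1}\t{end}\t.\t{f['strand']}\t.\t"
                f"ID={f['id']}.t1;Parent={f['id']}\n"
            )
            for (s, e) in f["exons"]:
                fh.write(
                    f"{f['chrom']}\tsim\tCDS\t{s + 1}\t{e}\t.\t{f['strand']}\t0\t"
                    f"ID={f['id']}.cds;Parent={f['id']}.t1\n"
                )


def write_simulation(
    m: GenotypeMatrix,
    truth: TruthSet,
    annotation,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Emit VCF + truth/annotation/metadata TSVs under ``out_prefix``.

    Files: ``<prefix>.vcf``, ``<prefix>.sites.tsv`` (annotation),
    ``<prefix>.truth_clones.tsv``, ``<prefix>.truth_loh.tsv``
    (BED-compatible columns), ``<prefix>.samples.tsv``.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["vcf"] = Path(f"{prefix}.vcf")
    write_vcf(m, paths["vcf"])
    paths["sites"] = Path(f"{prefix}.sites.tsv")
    annotation.write_tsv(paths["sites"])
    paths["clones"] = Path(f"{prefix}.truth_clones.tsv")
    pd.DataFrame(
        sorted(truth.clone_assignment.items()), columns=["sample", "clone_id"]
    ).to_csv(paths["clones"], sep="\t", index=False)
    paths["loh"] = Path(f"{prefix}.truth_loh.tsv")
    rows = [
        (chrom, start, end, s)
        for s, tr in sorted(truth.true_loh_tracts.items())
        for chrom, start, end in tr
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "sample"]).to_csv(
        paths["loh"], sep="\t", index=False
    )
    paths["samples"] = Path(f"{prefix}.samples.tsv")
    truth.sample_meta.to_csv(paths["samples"], sep="\t", index=False)
    return paths


__all__ = [
    "SimConfig",
    "TruthSet",
    "Genome",
    "ConfigurationError",
    "simulate_genome",
    "simulate_sexual_population",
    "simulate_clonal_complex",
    "simulate_hybrid_apomict",
    "simulate_embryo_set",
    "simulate_embryo_scenario",
    "apply_sequencing_model",
    "add_outgroups",
    "mendelian_child",
    "truth_annotation",
    "all_sites_matrix",
    "write_reference_fasta",
    "write_gff3",
    "write_simulation",
]
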