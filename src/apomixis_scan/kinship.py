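"""KING-robust kinship, relationship degrees, and clone detection.

The pairwise kinship coefficient is the between-family KING-robust
estimator,

    phi = (N_het,het - 2 * N_AA,aa) / (N_het(i) + N_het(j)),

where counts are taken over sites called in both samples: N_het,het is the
number of sites heterozygous in both, N_AA,aa the number of opposite
homozygotes, and N_het(i), N_het(j) the heterozygous-site counts of each
member. It is robust to population structure: duplicates/identical twins
sit at 0.5, parent-offspring near 0.25, half sibs near 0.125.

Relationship degrees follow the conventional thresholds: duplicate
(> 0.354), first degree (0.177-0.354], second (0.0884-0.177], third
(0.0442-0.0884], otherwise unrelated. Intervals are open at the lower
bound. Clones are the connected components of the graph whose edges are
duplicate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

DUPLICATE_THRESHOLD = 0.354
FIRST_DEGREE_THRESHOLD = 0.177
SECOND_DEGREE_THRESHOLD = 0.0884
THIRD_DEGREE_THRESHOLD = 0.0442

_DEGREE_ORDER = {"duplicate": 0, "first": 1, "second": 2, "third": 3, "unrelated": 4}


@dataclass
class KinshipResult:
    sample_i: str
    sample_j: str
    phi: float  # NaN when undefined (no hets in either member at shared sites)
    n_sites_used: int
    n_het_het: int
    n_opposite_hom: int
    n_het_i: int
    n_het_j: int
    degree_class: str


@dataclass
class CloneGraph:
    """Clone partition derived from duplicate-pair edges."""

    samples: list[str]
    duplicate_edges: list[tuple[str, str]]
    components: list[list[str]]  # sorted members; singletons included
    inter_degrees: dict[tuple[int, int], str]  # closest degree between components

    @property
    def component_of(self) -> dict[str, int]:
        return {s: i for i, comp in enumerate(self.components) for s in comp}

    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


def classify_degree(phi: float) -> str:
    """Relationship-degree class for a finite kinship coefficient."""
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    if phi > DUPLICATE_THRESHOLD:
        return "duplicate"
    if phi > FIRST_DEGREE_THRESHOLD:
        return "first"
    if phi > SECOND_DEGREE_THRESHOLD:
        return "second"
    if phi > THIRD_DEGREE_THRESHOLD:
        return "third"
    return "unrelated"


def king_robust(calls_i: np.ndarray, calls_j: np.ndarray) -> KinshipResult:
    """KING-robust kinship between two genotype vectors (codes 0/1/2/-1)."""
    shared = (calls_i != MISSING) & (calls_j != MISSING)
    gi = calls_i[shared]
    gj = calls_j[shared]
    het_i = gi == HET
    het_j = gj == HET
    n_het_het = int((het_i & het_j).sum())
    n_opp = int(
        (((gi == HOM_REF) & (gj == HOM_ALT)) | ((gi == HOM_ALT) & (gj == HOM_REF))).sum()
    )
    n_het_i = int(het_i.sum())
    n_het_j = int(het_j.sum())
    denom = n_het_i + n_het_j
    phi = (n_het_het - 2 * n_opp) / denom if denom > 0 else float("nan")
    return KinshipResult(
        sample_i="",
        sample_j="",
        phi=phi,
        n_sites_used=int(shared.sum()),
        n_het_het=n_het_het,
        n_opposite_hom=n_opp,
        n_het_i=n_het_i,
        n_het_j=n_het_j,
        degree_class=classify_degree(phi) if np.isfinite(phi) else "undefined",
    )


def kinship_matrix(m: GenotypeMatrix) -> list[KinshipResult]:
    """All unordered pairwise KING-robust kinship results."""
    if m.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    results = []
    for a in range(m.n_samples):
        for b in range(a + 1, m.n_samples):
            r = king_robust(m.calls[a], m.calls[b])
            r.sample_i = m.sample_ids[a]
            r.sample_j = m.sample_ids[b]
            results.append(r)
    return results


def clone_components(results: list[KinshipResult]) -> CloneGraph:
    """Group samples into clones: connected components of duplicate pairs.

    The inter-component relationship is the closest (minimum) degree over
    all cross-component pairs.
    """
    samples = sorted({r.sample_i for r in results} | {r.sample_j for r in results})
    g = nx.Graph()
    g.add_nodes_from(samples)
    dup_edges = [
        (r.sample_i, r.sample_j) for r in results if r.degree_class == "duplicate"
    ]
    g.add_edges_from(dup_edges)
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    comp_of = {s: i for i, comp in enumerate(components) for s in comp}
    inter: dict[tuple[int, int], str] = {}
    for r in results:
        ci, cj = comp_of[r.sample_i], comp_of[r.sample_j]
        if ci == cj:
            continue
        key = (min(ci, cj), max(ci, cj))
        deg = r.degree_class if r.degree_class != "undefined" else "unrelated"
        if key not in inter or _DEGREE_ORDER[deg] < _DEGREE_ORDER[inter[key]]:
            inter[key] = deg
    return CloneGraph(
        samples=samples,
        duplicate_edges=dup_edges,
        components=components,
        inter_degrees=inter,
    )


def kinship_table(results: list[KinshipResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sample_i, r.sample_j, r.phi, r.n_sites_used, r.degree_class)
            for r in results
        ],
        columns=["sample_i", "sample_j", "phi", "n_sites", "degree"],
    )


__all__ = [
    "KinshipResult",
    "CloneGraph",
    "classify_degree",
    "king_robust",
    "kinship_matrix",
    "clone_components",
    "kinship_table",
    "DUPLICATE_THRESHOLD",
    "FIRST_DEGREE_THRESHOLD",
    "SECOND_DEGREE_THRESHOLD",
    "THIRD_DEGREE_THRESHOLD",
]
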