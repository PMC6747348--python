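"""Probe→gene mapping and hypergeometric gene-set over-representation.

Selected probes are mapped to the union of their annotated gene symbols;
each catalogue term is tested for over-representation of the hit list within
a finite gene universe by the exact hypergeometric upper tail P(X ≥ k), and
p-values are adjusted by Benjamini–Hochberg.  Terms with FDR < 0.05
(strictly) are called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import ProbeAnnotation

__all__ = [
    "EnrichmentResult",
    "probes_to_genes",
    "hypergeom_p",
    "bh_fdr",
    "enrich",
]


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int
    hit_overlap: int
    universe_size: int
    p_value: float
    fdr: float
    significant: bool


def probes_to_genes(probes, annotation: ProbeAnnotation) -> set[str]:
    """Union of gene symbols over the given probes (deduplicated);
    unannotated probes contribute nothing."""
    genes: set[str] = set()
    for probe in probes:
        genes.update(annotation.genes.get(probe, []))
    return genes


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X ≥ k).

    Drawing n hits from a universe of N genes of which K belong to the term,
    the chance of observing at least k of them in the term.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if n > N or K > N:
        raise ValueError("hit list and term must fit inside the universe")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    hit_genes,
    catalogue: dict[str, set],
    universe,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every catalogue term for over-representation of the hit list.

    Hits and term sets are intersected with the universe first.  Returns one
    result per term, sorted by (FDR, p, term id); ``significant`` is
    FDR < alpha, strictly.
    """
    universe = set(universe)
    hits = set(hit_genes) & universe
    N, n = len(universe), len(hits)
    terms = sorted(catalogue)
    pvals = []
    sizes = []
    overlaps = []
    for term in terms:
        members = set(catalogue[term]) & universe
        K = len(members)
        k = len(members & hits)
        sizes.append(K)
        overlaps.append(k)
        pvals.append(hypergeom_p(k, n, K, N) if N else 1.0)
    fdrs = bh_fdr(pvals)
    results = [
        EnrichmentResult(
            term_id=term,
            term_size=sizes[i],
            hit_overlap=overlaps[i],
            universe_size=N,
            p_value=float(pvals[i]),
            fdr=float(fdrs[i]),
            significant=bool(fdrs[i] < alpha),
        )
        for i, term in enumerate(terms)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.term_id))
    return results
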