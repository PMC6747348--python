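"""Synthetic 450K-style datasets with planted subtype structure.

The generator emulates the statistical shape of a four-subtype breast-cancer
methylation cohort: beta values in [0, 1] drawn from Beta distributions,
imbalanced class sizes (default 34 basal / 37 Her2 / 120 LumA / 63 LumB), and
a planted subset of subtype-informative probes whose class means are shifted
apart.  A matching synthetic probe→gene annotation and gene-set catalogue
support enrichment tests, and the returned ground truth enables
parameter-recovery checks for the feature-selection stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, ProbeAnnotation

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_annotation",
    "generate_gene_sets",
    "REGION_TAGS",
]

REGION_TAGS = ("TSS1500", "TSS200", "5'UTR", "Body", "3'UTR")

DEFAULT_CLASS_SIZES = {"basal": 34, "her2": 37, "lumA": 120, "lumB": 63}

# Informative-probe class means are clipped into this open interval so the
# Beta parameterization stays proper.
_MEAN_LO, _MEAN_HI = 0.02, 0.98


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    class_sizes : subtype name → sample count. The default mirrors the
        imbalance of the study cohort (majority LumA at 120).
    n_probes : total probe count.
    n_informative : number of planted subtype-informative probes.
    effect : total spread of per-class mean beta shifts, in beta units
        (classes receive equally spaced offsets spanning ±effect/2).
    dispersion : Beta-distribution concentration (α+β); larger is less noisy.
        The default 10 gives a per-probe s.d. of roughly 0.15 at mean 0.5,
        matching the within-subtype heterogeneity of variable CpGs in tumor
        cohorts, so few-feature classifiers stay imperfect as they are on
        real data.
    lum_proximity : when True, the lumA and lumB offsets are placed close
        together so those two classes are hard to separate, emulating the
        luminal-subtype confusability seen in real cohorts.
    seed : RNG seed; identical configs produce byte-identical datasets.
    """

    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    n_probes: int = 2000
    n_informative: int = 100
    effect: float = 0.35
    dispersion: float = 10.0
    lum_proximity: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.class_sizes:
            raise ValueError("class_sizes must not be empty")
        for name, size in self.class_sizes.items():
            if size < 2:
                raise ValueError(f"class {name!r} needs ≥2 samples, got {size}")
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if not 0 <= self.n_informative <= self.n_probes:
            raise ValueError(
                f"n_informative ({self.n_informative}) must be in "
                f"[0, n_probes={self.n_probes}]"
            )
        if not 0.0 <= self.effect <= 0.5:
            raise ValueError("effect must lie in [0, 0.5]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class GroundTruth:
    """What the generator planted: which probes are informative and the
    target mean beta of each (class, informative probe) pair."""

    informative_probes: set[str]
    class_mean_beta: pd.DataFrame  # rows = informative probes, cols = classes


def _probe_id(i: int) -> str:
    return f"cg{i:08d}"


def generate_dataset(config: SimulationConfig) -> tuple[BetaMatrix, GroundTruth]:
    """Draw a labeled beta-value matrix with planted informative probes.

    Noise probes share one per-probe Beta distribution across classes;
    informative probes get class-specific means obtained by adding equally
    spaced offsets (total spread = ``effect``) to the probe's baseline mean,
    with the class→offset assignment permuted per probe so no class is
    systematically hyper- or hypo-methylated.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.class_sizes)
    C = len(classes)
    n_samples = sum(config.class_sizes.values())

    probe_ids = [_probe_id(i) for i in range(config.n_probes)]
    baseline = rng.uniform(0.15, 0.85, size=config.n_probes)
    informative_idx = np.sort(
        rng.choice(config.n_probes, size=config.n_informative, replace=False)
    )
    informative = set(informative_idx.tolist())

    # class → offset template; lum_proximity nudges lumB next to lumA
    offsets = np.linspace(-config.effect / 2.0, config.effect / 2.0, C)
    lum_pair = {"lumA", "lumB"} <= set(classes)
    spacing = config.effect / max(C - 1, 1)

    # per-(informative probe, class) target means
    mean_table = np.zeros((config.n_informative, C))
    for row, j in enumerate(informative_idx):
        if config.lum_proximity and lum_pair:
            assign = {c: offsets[i] for i, c in enumerate(classes)}
            assign["lumB"] = assign["lumA"] + 0.3 * spacing
            sign = 1.0 if rng.random() < 0.5 else -1.0
            probe_offsets = np.array([sign * assign[c] for c in classes])
        else:
            probe_offsets = rng.permutation(offsets)
        mean_table[row] = np.clip(baseline[j] + probe_offsets, _MEAN_LO, _MEAN_HI)

    labels = np.concatenate(
        [np.repeat(c, config.class_sizes[c]) for c in classes]
    ).astype(object)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    conc = config.dispersion
    values = np.empty((n_samples, config.n_probes))
    # noise probes: one shared distribution per probe across all classes
    mean_matrix = np.tile(baseline, (n_samples, 1))
    row_of_class = {c: np.flatnonzero(labels == c) for c in classes}
    for row, j in enumerate(informative_idx):
        for ci, c in enumerate(classes):
            mean_matrix[row_of_class[c], j] = mean_table[row, ci]
    alpha = mean_matrix * conc
    beta_par = (1.0 - mean_matrix) * conc
    values = rng.beta(alpha, beta_par)

    matrix = BetaMatrix(values, sample_ids, probe_ids, labels)
    truth = GroundTruth(
        informative_probes={probe_ids[j] for j in informative},
        class_mean_beta=pd.DataFrame(
            mean_table,
            index=[probe_ids[j] for j in informative_idx],
            columns=classes,
        ),
    )
    return matrix, truth


def generate_annotation(
    probe_ids,
    genes_per_probe_max: int = 2,
    seed: int = 0,
    gene_pool_size: int | None = None,
) -> ProbeAnnotation:
    """Random probe→gene annotation in the 450K manifest dialect.

    Each probe receives 0..genes_per_probe_max symbols (drawn with
    replacement from a synthetic gene pool, so duplicated symbols occur as
    they do in the real manifest) and a parallel region tag per symbol.
    """
    probe_ids = list(probe_ids)
    if not probe_ids:
        raise ValueError("probe_ids must not be empty")
    if genes_per_probe_max < 0:
        raise ValueError("genes_per_probe_max must be ≥ 0")
    rng = np.random.default_rng(seed)
    if gene_pool_size is None:
        gene_pool_size = max(10, len(probe_ids) // 2)
    pool = [f"GENE{i:05d}" for i in range(gene_pool_size)]
    genes: dict[str, list[str]] = {}
    regions: dict[str, list[str]] = {}
    for probe in probe_ids:
        k = int(rng.integers(0, genes_per_probe_max + 1))
        gs = [pool[int(i)] for i in rng.integers(0, gene_pool_size, size=k)]
        rs = [REGION_TAGS[int(i)] for i in rng.integers(0, len(REGION_TAGS), size=k)]
        genes[probe] = gs
        regions[probe] = rs
    return ProbeAnnotation(genes, regions)


def generate_gene_sets(
    genes,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (5, 25),
    planted_term: list[str] | None = None,
    planted_overlap: float = 0.8,
    seed: int = 0,
) -> dict[str, set]:
    """Random term→gene-set catalogue, optionally with one planted term.

    The planted term contains ``planted_overlap`` of ``planted_term`` (a hit
    gene list) topped up with random fillers, so enrichment recovery on a
    known hit list is testable.
    """
    genes = sorted(set(genes))
    lo, hi = set_size_range
    if n_sets < 0:
        raise ValueError("n_sets must be ≥ 0")
    if n_sets > 0 and (lo < 1 or hi < lo or hi > len(genes)):
        raise ValueError(
            f"set_size_range {set_size_range} invalid for a universe of "
            f"{len(genes)} genes"
        )
    rng = np.random.default_rng(seed)
    catalogue: dict[str, set] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        catalogue[f"TERM{i:04d}"] = {genes[int(j)] for j in members}
    if planted_term is not None:
        hits = [g for g in planted_term if g in set(genes)]
        n_hit = max(1, int(round(planted_overlap * len(hits)))) if hits else 0
        chosen = set(
            rng.choice(hits, size=n_hit, replace=False).tolist()
        ) if n_hit else set()
        target = min(max(hi, n_hit), len(genes))
        others = [g for g in genes if g not in chosen]
        fill = target - len(chosen)
        if fill > 0 and others:
            chosen |= {
                others[int(j)]
                for j in rng.choice(len(others), size=min(fill, len(others)), replace=False)
            }
        catalogue["PLANTED"] = chosen
    return catalogue
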