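"""Gene-by-individual variability matrices, top-gene ranking and the
gene-size correlation check.

The variability matrix counts retained rare/non-synonymous/deleterious
variants per candidate gene per individual, with individuals ordered so that
matched mother-infant rows align.  Top genes are ranked breadth-first: by
the number of individuals carrying any variant in the gene, then by total
variant count, then alphabetically — a deterministic total order.

The gene-size check regresses per-gene variant totals on coding length; a
low R-squared indicates the candidate-gene signal is not merely a gene-size
artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import FilteredProfile
from .model import GeneModel, GeneSet, Sample


@dataclass
class VariabilityMatrix:
    genes: list[str]
    individuals: list[Sample]
    counts: np.ndarray  # shape (n_genes, n_individuals), non-negative ints

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.genes, name="gene"),
            columns=[s.sample_id for s in self.individuals],
        )


def build_matrix(
    profiles: Sequence[FilteredProfile],
    gene_set: GeneSet,
    samples: Sequence[Sample],
) -> VariabilityMatrix:
    """Tally retained variants per candidate gene per individual.

    Column order follows ``samples`` (so duo pairing determines row
    alignment across infant/mother panels); every profile must correspond to
    a known sample.
    """
    by_id = {s.sample_id: s for s in samples}
    unknown = [p.sample_id for p in profiles if p.sample_id not in by_id]
    if unknown:
        raise ValueError(f"profiles for unknown samples: {sorted(set(unknown))}")
    profiled = {p.sample_id for p in profiles}
    individuals = [s for s in samples if s.sample_id in profiled]
    col = {s.sample_id: j for j, s in enumerate(individuals)}
    genes = sorted(gene_set.genes)
    row = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((len(genes), len(individuals)), dtype=np.int64)
    for p in profiles:
        j = col[p.sample_id]
        for v in p.variants:
            i = row.get(v.gene)
            if i is not None:
                counts[i, j] += 1
    return VariabilityMatrix(genes=genes, individuals=individuals, counts=counts)


def rank_top_genes(matrix: VariabilityMatrix, n: int = 50) -> list[str]:
    """Top-``n`` genes by individuals affected, then total count, then symbol.

    Genes with no variant in any individual are never returned, so fewer
    than ``n`` genes may come back.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    breadth = (matrix.counts >= 1).sum(axis=1)
    totals = matrix.counts.sum(axis=1)
    ranked = sorted(
        (i for i in range(len(matrix.genes)) if breadth[i] > 0),
        key=lambda i: (-int(breadth[i]), -int(totals[i]), matrix.genes[i]),
    )
    return [matrix.genes[i] for i in ranked[:n]]


def gene_size_correlation(
    per_gene_counts: Mapping[str, int],
    gene_models: Iterable[GeneModel],
) -> float:
    """R-squared of OLS regression of per-gene variant counts on coding length.

    Genes without a model are ignored; at least three genes with models and
    two distinct coding lengths are required.  Zero-variance counts make the
    fit degenerate and R-squared is defined as 0.
    """
    models = {m.gene: m.coding_length for m in gene_models}
    usable = [(g, c) for g, c in per_gene_counts.items() if g in models]
    if len(usable) < 3:
        raise ValueError(f"need >=3 genes with gene models, got {len(usable)}")
    lengths = np.array([models[g] for g, _ in usable], dtype=float)
    counts = np.array([c for _, c in usable], dtype=float)
    if np.unique(lengths).size < 2:
        raise ValueError("need >=2 distinct coding lengths")
    if np.all(counts == counts[0]):
        return 0.0
    # R^2 of simple OLS equals the squared Pearson correlation
    r = np.corrcoef(lengths, counts)[0, 1]
    return float(r * r)


def per_gene_totals(profiles: Iterable[FilteredProfile]) -> dict[str, int]:
    """Total retained variants per gene, summed over a group of samples."""
    totals: dict[str, int] = {}
    for p in profiles:
        for v in p.variants:
            if v.gene:
                totals[v.gene] = totals.get(v.gene, 0) + 1
    return totals


def plot_variability_matrix(matrix: VariabilityMatrix, path: str, top_n: int = 50) -> None:
    """Optional heatmap export of the top-``top_n`` genes (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = rank_top_genes(matrix, n=top_n)
    idx = [matrix.genes.index(g) for g in top]
    data = matrix.counts[idx, :]
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.2 * len(matrix.individuals)), max(3.0, 0.18 * len(top)))
    )
    im = ax.imshow(data, aspect="auto", cmap="Reds", interpolation="nearest")
    ax.set_yticks(range(len(top)), top, fontsize=5)
    ax.set_xticks(
        range(len(matrix.individuals)),
        [s.sample_id for s in matrix.individuals],
        rotation=90,
        fontsize=5,
    )
    fig.colorbar(im, ax=ax, label="variants")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
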