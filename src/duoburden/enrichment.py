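"""Candidate gene-set enrichment: exact hypergeometric tail and permutation nulls.

The question asked of a patient group is whether the genes carrying its
rare, non-synonymous, predicted-deleterious variation overlap a candidate
gene list more than chance draws from the exome would.  Two routes answer
it:

* the analytic upper tail P[X >= k] of a hypergeometric distribution over
  the exome gene universe, and
* an empirical null built by Monte-Carlo resampling — either drawing the
  observed number of variant genes from the exome universe and recording the
  overlap with the candidate list (``resample_variant_genes``), or drawing
  random gene lists of the candidate list's size and recording their overlap
  with the variant genes (``random_gene_lists``).

Empirical p-values use the add-one convention (r+1)/(n+1), so a permutation
p can never be exactly zero: when no permutation reaches the observed
statistic the result is reported as p <= 1/(n_iterations+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .filtering import FilteredProfile
from .model import GeneSet

SCHEMES = ("resample_variant_genes", "random_gene_lists")


@dataclass(frozen=True)
class EnrichmentConfig:
    """Permutation-test settings.

    ``n_iterations`` defaults to 100 000 draws; significance is declared at
    the stringent ``alpha`` of 0.005.
    """

    n_iterations: int = 100_000
    alpha: float = 0.005
    seed: int = 0
    scheme: str = "resample_variant_genes"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")


@dataclass
class EnrichmentResult:
    group_label: str
    gene_set_name: str
    observed: int
    universe_size: int
    candidate_size: int
    draw_size: int
    p_hypergeometric: float
    p_empirical: float
    null_mean: float
    null_sd: float
    n_iterations_run: int
    alpha: float = 0.005
    null_overlaps: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.p_empirical <= self.alpha


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    ``N`` genes in the urn, ``K`` of them candidates, ``n`` drawn without
    replacement, ``k`` the observed candidate overlap.  The sum
    sum_{j=k}^{min(K,n)} C(K,j) C(N-K, n-j) / C(N,n) is evaluated in log
    space for numerical stability at exome scale.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= n):
        raise ValueError(f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}")
    hi = min(K, n)
    lo = max(0, n - (N - K))  # minimum possible overlap
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    j = np.arange(k, hi + 1)
    log_pmf = (
        gammaln(K + 1) - gammaln(j + 1) - gammaln(K - j + 1)
        + gammaln(N - K + 1) - gammaln(n - j + 1) - gammaln(N - K - n + j + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def _random_subset_overlaps(
    rng: np.random.Generator,
    n_universe: int,
    draw_size: int,
    target_mask: np.ndarray,
    n_iterations: int,
) -> np.ndarray:
    """Overlap of ``n_iterations`` uniform ``draw_size``-subsets with a mask."""
    overlaps = np.empty(n_iterations, dtype=np.int64)
    if draw_size == 0:
        overlaps[:] = 0
        return overlaps
    if draw_size == n_universe:
        overlaps[:] = int(target_mask.sum())
        return overlaps
    # chunked so memory stays ~ 160 MB even at exome scale
    chunk = max(1, min(n_iterations, int(2e7) // max(n_universe, 1)))
    done = 0
    while done < n_iterations:
        m = min(chunk, n_iterations - done)
        keys = rng.random((m, n_universe))
        idx = np.argpartition(keys, draw_size - 1, axis=1)[:, :draw_size]
        overlaps[done : done + m] = target_mask[idx].sum(axis=1)
        done += m
    return overlaps


def permutation_enrichment(
    variant_gene_universe: set[str] | frozenset[str],
    candidate_set: GeneSet,
    observed: int,
    config: EnrichmentConfig,
    exome_gene_universe: set[str] | frozenset[str],
    group_label: str = "",
    keep_null: bool = False,
) -> EnrichmentResult:
    """Monte-Carlo enrichment test of candidate-gene overlap.

    ``observed`` must be the overlap statistic computed on the same universe
    definitions (normally ``len(variant_gene_universe & candidate_set.genes)``).
    With a fixed seed the null distribution and every summary are
    bit-reproducible.
    """
    exome = sorted(exome_gene_universe)
    exome_index = {g: i for i, g in enumerate(exome)}
    N = len(exome)
    missing = set(candidate_set.genes) - set(exome_index)
    if missing:
        raise ValueError(
            f"candidate set {candidate_set.name!r} contains {len(missing)} genes "
            f"outside the exome gene universe (e.g. {sorted(missing)[:3]})"
        )
    stray = set(variant_gene_universe) - set(exome_index)
    if stray:
        raise ValueError(
            f"variant gene universe contains {len(stray)} genes outside the exome "
            f"universe (e.g. {sorted(stray)[:3]})"
        )

    variant_mask = np.zeros(N, dtype=bool)
    variant_mask[[exome_index[g] for g in variant_gene_universe]] = True
    candidate_mask = np.zeros(N, dtype=bool)
    candidate_mask[[exome_index[g] for g in candidate_set.genes]] = True

    if config.scheme == "resample_variant_genes":
        draw_size, target_mask = len(variant_gene_universe), candidate_mask
    else:  # random_gene_lists
        draw_size, target_mask = len(candidate_set), variant_mask
    if draw_size > N:
        raise ValueError(f"draw size {draw_size} exceeds universe size {N}")

    rng = np.random.default_rng(config.seed)
    overlaps = _random_subset_overlaps(rng, N, draw_size, target_mask, config.n_iterations)
    r = int((overlaps >= observed).sum())
    p_emp = (r + 1) / (config.n_iterations + 1)
    # Both schemes share one analytic tail: the overlap of a uniform random
    # subset with a fixed set is hypergeometric, symmetric in the two sizes.
    p_hyp = hypergeometric_upper_tail(
        observed, len(candidate_set), len(variant_gene_universe), N
    )
    return EnrichmentResult(
        group_label=group_label,
        gene_set_name=candidate_set.name,
        observed=int(observed),
        universe_size=N,
        candidate_size=len(candidate_set),
        draw_size=draw_size,
        p_hypergeometric=p_hyp,
        p_empirical=float(p_emp),
        null_mean=float(overlaps.mean()),
        null_sd=float(overlaps.std(ddof=1)) if len(overlaps) > 1 else 0.0,
        n_iterations_run=int(config.n_iterations),
        alpha=config.alpha,
        null_overlaps=overlaps if keep_null else None,
    )


def aggregate_variant_genes(profiles: Iterable[FilteredProfile]) -> set[str]:
    """Distinct genes with >=1 retained variant across a sample group."""
    genes: set[str] = set()
    for p in profiles:
        genes.update(v.gene for v in p.variants if v.gene)
    return genes


def group_enrichment(
    profiles: Iterable[FilteredProfile],
    candidate_set: GeneSet,
    config: EnrichmentConfig,
    exome_gene_universe: set[str],
    group_label: str = "",
    keep_null: bool = False,
) -> EnrichmentResult:
    """Aggregate a group's variant genes and run the permutation test.

    The group-level statistic is the aggregate across samples: the number of
    distinct variant-carrying genes that lie on the candidate list.
    """
    universe = aggregate_variant_genes(profiles)
    observed = len(universe & candidate_set.genes)
    return permutation_enrichment(
        universe, candidate_set, observed, config, exome_gene_universe,
        group_label=group_label, keep_null=keep_null,
    )


def enrichment_rate_ratio(
    case_candidate: float,
    case_total: float,
    ctrl_candidate: float,
    ctrl_total: float,
) -> float:
    """Ratio of candidate-variant rates, cases over controls.

    ``(case_candidate/case_total) / (ctrl_candidate/ctrl_total)``; all four
    inputs must be positive.
    """
    for name, value in (
        ("case_candidate", case_candidate),
        ("case_total", case_total),
        ("ctrl_candidate", ctrl_candidate),
        ("ctrl_total", ctrl_total),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be > 0, got {value}")
    return (case_candidate / case_total) / (ctrl_candidate / ctrl_total)
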