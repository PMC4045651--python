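"""The quality and functional-rarity filter cascade.

Raw variant calls are reduced in two passes.  The quality pass keeps a call
only when all four caller metrics clear their floors: per-allele coverage
(>=5 reads supporting the alt allele), per-position coverage (>10 reads at
the site), genotype quality (>=10) and mapping quality (>=60) — each floor
inclusive.  The functional-rarity pass then keeps variants in protein-
altering or splice consequence classes that are rare (<1% minor allele
frequency) in the reference panels and predicted deleterious by in-silico
algorithms under a configurable vote rule.

Stage-by-stage survivor counts are recorded so the cascade can be audited;
counts are non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .model import (
    FUNCTIONAL_CONSEQUENCES,
    AnnotatedVariant,
    Consequence,
    GeneSet,
)

QUALITY_STAGES = ("allele_depth", "position_depth", "genotype_quality", "mapping_quality")
FUNCTIONAL_STAGES = ("consequence", "rarity", "deleteriousness")


@dataclass(frozen=True)
class FilterThresholds:
    """Filter floors; defaults are the stringent exome-calling values.

    ``rarity_mode="all_panels"`` requires every panel that reports the
    variant to show AF < ``max_maf`` (absence from all panels counts as
    rare); ``"any_panel"`` accepts a variant rare in at least one panel
    (or absent everywhere).  ``deleterious_rule`` combines the in-silico
    prediction votes; a variant with no predictions at all passes.
    """

    min_allele_depth: int = 5
    min_position_depth: int = 10
    min_genotype_quality: int = 10
    min_mapping_quality: int = 60
    max_maf: float = 0.01
    retained_consequences: frozenset[Consequence] = FUNCTIONAL_CONSEQUENCES
    deleterious_rule: str = "any_vote"  # any_vote | majority_vote | all_votes
    rarity_mode: str = "all_panels"  # all_panels | any_panel

    def __post_init__(self) -> None:
        for name in ("min_allele_depth", "min_position_depth", "min_genotype_quality",
                     "min_mapping_quality"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.max_maf <= 1:
            raise ValueError("max_maf must be in (0, 1]")
        if not self.retained_consequences:
            raise ValueError("retained_consequences must be non-empty")
        object.__setattr__(
            self,
            "retained_consequences",
            frozenset(Consequence(c) for c in self.retained_consequences),
        )
        if self.deleterious_rule not in {"any_vote", "majority_vote", "all_votes"}:
            raise ValueError(f"unknown deleterious_rule {self.deleterious_rule!r}")
        if self.rarity_mode not in {"all_panels", "any_panel"}:
            raise ValueError(f"unknown rarity_mode {self.rarity_mode!r}")


@dataclass
class FilteredProfile:
    """One sample's surviving variants plus per-stage survivor counts."""

    sample_id: str
    variants: list[AnnotatedVariant]
    counts: dict[str, int] = field(default_factory=dict)


def _check_single_sample(variants: list[AnnotatedVariant]) -> str | None:
    ids = {v.sample_id for v in variants}
    if len(ids) > 1:
        raise ValueError(f"variants span multiple samples: {sorted(ids)}")
    return next(iter(ids)) if ids else None


def passes_quality(v: AnnotatedVariant, t: FilterThresholds) -> bool:
    return (
        v.alt_depth >= t.min_allele_depth
        and v.total_depth >= t.min_position_depth
        and v.genotype_quality >= t.min_genotype_quality
        and v.mapping_quality >= t.min_mapping_quality
    )


def is_rare(v: AnnotatedVariant, t: FilterThresholds) -> bool:
    """Rarity under the configured panel-combination mode.

    Strict inequality: a variant at exactly ``max_maf`` is not rare.
    """
    if not v.pop_afs:
        return True  # never observed in any panel
    if t.rarity_mode == "all_panels":
        return all(af < t.max_maf for af in v.pop_afs.values())
    return any(af < t.max_maf for af in v.pop_afs.values())


def passes_deleterious(v: AnnotatedVariant, t: FilterThresholds) -> bool:
    if v.deleterious_total == 0:
        return True  # no prediction available
    if t.deleterious_rule == "any_vote":
        return v.deleterious_votes >= 1
    if t.deleterious_rule == "majority_vote":
        return 2 * v.deleterious_votes > v.deleterious_total
    return v.deleterious_votes == v.deleterious_total


def apply_quality_filters(
    variants: Iterable[AnnotatedVariant],
    thresholds: FilterThresholds | None = None,
) -> FilteredProfile:
    """Apply the four caller-metric floors, recording stage counts."""
    t = thresholds or FilterThresholds()
    variants = list(variants)
    sample_id = _check_single_sample(variants) or ""
    counts = {"input": len(variants)}
    stages = [
        ("allele_depth", lambda v: v.alt_depth >= t.min_allele_depth),
        ("position_depth", lambda v: v.total_depth >= t.min_position_depth),
        ("genotype_quality", lambda v: v.genotype_quality >= t.min_genotype_quality),
        ("mapping_quality", lambda v: v.mapping_quality >= t.min_mapping_quality),
    ]
    surviving = variants
    for name, pred in stages:
        surviving = [v for v in surviving if pred(v)]
        counts[name] = len(surviving)
    return FilteredProfile(sample_id=sample_id, variants=surviving, counts=counts)


def apply_functional_rarity_filters(
    profile: FilteredProfile,
    thresholds: FilterThresholds | None = None,
) -> FilteredProfile:
    """Apply consequence, rarity and deleteriousness filters to a profile."""
    t = thresholds or FilterThresholds()
    counts = dict(profile.counts)
    surviving = [v for v in profile.variants if v.consequence in t.retained_consequences]
    counts["consequence"] = len(surviving)
    surviving = [v for v in surviving if is_rare(v, t)]
    counts["rarity"] = len(surviving)
    surviving = [v for v in surviving if passes_deleterious(v, t)]
    counts["deleteriousness"] = len(surviving)
    return FilteredProfile(sample_id=profile.sample_id, variants=surviving, counts=counts)


def filter_variants(
    variants: Iterable[AnnotatedVariant],
    thresholds: FilterThresholds | None = None,
) -> FilteredProfile:
    """Run the full cascade (quality then functional/rarity) in one call."""
    t = thresholds or FilterThresholds()
    return apply_functional_rarity_filters(apply_quality_filters(variants, t), t)


def count_candidate_variants(
    profile: FilteredProfile, gene_set: GeneSet
) -> tuple[int, int, set[str]]:
    """Count retained variants falling in a candidate gene set.

    Returns ``(candidate_count, total_count, variant_gene_set)`` where the
    last element is the set of distinct genes carrying >=1 retained variant.
    """
    candidate = sum(1 for v in profile.variants if v.gene in gene_set)
    genes = {v.gene for v in profile.variants if v.gene}
    return candidate, len(profile.variants), genes
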