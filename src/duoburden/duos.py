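"""Maternal attribution and compound-heterozygote calling in mother-infant duos.

With no paternal sample, an infant's variant can only be classed as
*maternal* (also present, after normalization, in the matched mother's
filtered variant set) or *non-maternal* (de novo or paternally inherited —
indistinguishable here).  A gene is called a compound heterozygote when it
carries >=2 rare, non-synonymous, predicted-deleterious variants in the
infant with >=1 maternal and >=1 non-maternal among them.  Phase is unknown,
so this is the presence-based surrogate for true trans-configuration, not a
phased call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .filtering import FilteredProfile
from .model import AnnotatedVariant


class Origin(str, enum.Enum):
    MATERNAL = "maternal"
    NON_MATERNAL = "non_maternal"


@dataclass(frozen=True)
class AttributedVariant:
    variant: AnnotatedVariant
    origin: Origin


@dataclass
class CompoundHetCall:
    """A gene in one infant with its variants split by origin."""

    duo_id: str
    gene: str
    maternal_variants: list[AttributedVariant]
    non_maternal_variants: list[AttributedVariant]

    def __post_init__(self) -> None:
        if not self.maternal_variants or not self.non_maternal_variants:
            raise ValueError(
                f"compound-het call for {self.gene} needs >=1 maternal and "
                f">=1 non-maternal variant"
            )

    @property
    def n_variants(self) -> int:
        return len(self.maternal_variants) + len(self.non_maternal_variants)


def attribute_origin(
    infant_profile: FilteredProfile, mother_profile: FilteredProfile
) -> list[AttributedVariant]:
    """Label each retained infant variant maternal or non-maternal.

    A variant is maternal iff its normalized identity key occurs among the
    mother's retained variants.  Both profiles must come from the same filter
    thresholds for the comparison to be meaningful.
    """
    if infant_profile.sample_id == mother_profile.sample_id:
        raise ValueError(
            f"infant and mother profiles share sample_id {infant_profile.sample_id!r}"
        )
    maternal_keys = {v.key for v in mother_profile.variants}
    return [
        AttributedVariant(
            variant=v,
            origin=Origin.MATERNAL if v.key in maternal_keys else Origin.NON_MATERNAL,
        )
        for v in infant_profile.variants
    ]


def detect_compound_het(
    attributed: Iterable[AttributedVariant], duo_id: str
) -> list[CompoundHetCall]:
    """Call genes with >=2 distinct variants, >=1 maternal and >=1 non-maternal.

    The >=2 variants must be at distinct sites (distinct identity keys);
    a variant annotated to several genes counts toward each gene.  Output is
    sorted by gene symbol.
    """
    by_gene: dict[str, dict[str, AttributedVariant]] = {}
    for av in attributed:
        if not av.variant.gene:
            continue
        # distinct sites only: keep one record per (gene, key)
        by_gene.setdefault(av.variant.gene, {}).setdefault(
            "%s:%d:%s:%s" % av.variant.key, av
        )
    calls = []
    for gene in sorted(by_gene):
        site_variants = list(by_gene[gene].values())
        maternal = [av for av in site_variants if av.origin is Origin.MATERNAL]
        non_maternal = [av for av in site_variants if av.origin is Origin.NON_MATERNAL]
        if len(site_variants) >= 2 and maternal and non_maternal:
            calls.append(
                CompoundHetCall(
                    duo_id=duo_id,
                    gene=gene,
                    maternal_variants=maternal,
                    non_maternal_variants=non_maternal,
                )
            )
    return calls


def compound_het_recurrence(
    calls_by_infant: Mapping[str, list[CompoundHetCall]],
    cohort: str = "",
) -> pd.DataFrame:
    """Per gene, the fraction of a cohort's infants carrying a call.

    Returns a DataFrame with columns ``gene``, ``n_infants``, ``fraction``,
    sorted by descending fraction then gene symbol.
    """
    n_infants = len(calls_by_infant)
    if n_infants == 0:
        raise ValueError("cohort contains no infants")
    gene_hits: dict[str, int] = {}
    for calls in calls_by_infant.values():
        for gene in {c.gene for c in calls}:
            gene_hits[gene] = gene_hits.get(gene, 0) + 1
    rows = [
        {
            "gene": gene,
            "cohort": cohort,
            "n_infants": hits,
            "fraction": hits / n_infants,
        }
        for gene, hits in gene_hits.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "cohort", "n_infants", "fraction"])
    return df.sort_values(
        ["fraction", "gene"], ascending=[False, True], ignore_index=True
    )


def attribution_frame(attributed: Iterable[AttributedVariant]) -> pd.DataFrame:
    """Flat table of attributed infant variants, one row per variant/gene."""
    rows = [
        {
            "sample_id": av.variant.sample_id,
            "chrom": av.variant.chrom,
            "pos": av.variant.pos,
            "ref": av.variant.ref,
            "alt": av.variant.alt,
            "gene": av.variant.gene,
            "consequence": av.variant.consequence.value,
            "origin": av.origin.value,
        }
        for av in attributed
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence", "origin"],
    )
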