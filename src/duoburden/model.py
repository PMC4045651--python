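"""Core domain types for duo-based germline rare-variant analysis.

The unit of analysis is a single called, annotated variant observed in a
single individual (infant, mother or unaffected control).  Variants are
identified by ``(chrom, pos, ref, alt)`` after normalization — leading
``chr`` prefixes are stripped and indel alleles are trimmed/left-shifted —
because maternal-vs-non-maternal attribution relies on exact allelic
identity between an infant's table and the matched mother's table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

VariantKey = tuple[str, int, str, str]


class Consequence(str, enum.Enum):
    """Functional consequence class of a coding/splice variant."""

    NONSYNONYMOUS_SNV = "nonsynonymous_snv"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequence classes treated as potentially protein-altering; everything
#: else is dropped by the functional filter.
FUNCTIONAL_CONSEQUENCES = frozenset(
    {
        Consequence.NONSYNONYMOUS_SNV,
        Consequence.STOPGAIN,
        Consequence.STOPLOSS,
        Consequence.FRAMESHIFT_INDEL,
        Consequence.NONFRAMESHIFT_INDEL,
        Consequence.SPLICE_SITE,
    }
)


class Role(str, enum.Enum):
    INFANT = "infant"
    MOTHER = "mother"
    CONTROL = "control"


class Cohort(str, enum.Enum):
    ALL = "ALL"
    AML = "AML"
    CONTROL = "control"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix so builds agree on naming."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared allele suffix then prefix, adjusting ``pos``.

    This is the parsimonious left-alignment used before keying variants;
    without it the same indel written two ways would fail to match between
    a mother and her infant.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim common suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant in one sample, with annotations joined on.

    ``pop_afs`` maps a reference-panel name (e.g. ``"1000g"``) to the allele
    frequency observed there; a missing key means the variant was not seen in
    that panel.  ``deleterious_votes``/``deleterious_total`` summarize how
    many in-silico prediction algorithms called the variant deleterious out
    of how many produced a prediction at all.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    alt_depth: int
    total_depth: int
    genotype_quality: int
    mapping_quality: int
    pop_afs: Mapping[str, float] = field(default_factory=dict)
    deleterious_votes: int = 0
    deleterious_total: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"alt_depth must satisfy 0 <= alt_depth <= total_depth, got "
                f"{self.alt_depth}/{self.total_depth} at {self.chrom}:{self.pos}"
            )
        for panel, af in self.pop_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency for panel {panel!r} outside [0,1]: {af}")
        if self.deleterious_votes > self.deleterious_total:
            raise ValueError(
                f"deleterious_votes ({self.deleterious_votes}) exceeds "
                f"deleterious_total ({self.deleterious_total})"
            )
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(self, "consequence", Consequence(self.consequence))

    @property
    def key(self) -> VariantKey:
        """Normalized positional/allelic identity used for all matching."""
        pos, ref, alt = normalize_alleles(self.pos, self.ref, self.alt)
        return (normalize_chrom(self.chrom), pos, ref, alt)


@dataclass(frozen=True)
class Sample:
    """An individual with its cohort label and optional duo pairing."""

    sample_id: str
    role: Role
    cohort: Cohort
    duo_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.role, Role):
            object.__setattr__(self, "role", Role(self.role))
        if not isinstance(self.cohort, Cohort):
            object.__setattr__(self, "cohort", Cohort(self.cohort))
        if (self.role is Role.CONTROL) != (self.cohort is Cohort.CONTROL):
            raise ValueError(
                f"sample {self.sample_id}: role=control iff cohort=control "
                f"(got role={self.role.value}, cohort={self.cohort.value})"
            )


def validate_duo_pairing(samples: list[Sample]) -> dict[str, tuple[Sample, Sample]]:
    """Check that each duo_id links exactly one infant and one mother.

    Returns a mapping duo_id -> (infant, mother).
    """
    by_duo: dict[str, list[Sample]] = {}
    for s in samples:
        if s.duo_id is not None:
            by_duo.setdefault(s.duo_id, []).append(s)
    duos: dict[str, tuple[Sample, Sample]] = {}
    for duo_id, members in by_duo.items():
        roles = sorted(m.role.value for m in members)
        if len(members) != 2 or roles != ["infant", "mother"]:
            raise ValueError(
                f"duo {duo_id!r} must pair exactly one infant with one mother, "
                f"got roles {roles}"
            )
        infant = next(m for m in members if m.role is Role.INFANT)
        mother = next(m for m in members if m.role is Role.MOTHER)
        duos[duo_id] = (infant, mother)
    return duos


@dataclass(frozen=True)
class GeneModel:
    """A gene symbol with its coding length in bases."""

    gene: str
    coding_length: int

    def __post_init__(self) -> None:
        if self.coding_length <= 0:
            raise ValueError(f"coding_length must be > 0 for gene {self.gene!r}")


@dataclass(frozen=True)
class GeneSet:
    """A named candidate gene list (e.g. leukemia-associated genes)."""

    name: str
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes
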