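"""Synthetic mother-infant duo cohorts with full ground truth.

The generator emulates post-annotation exome variant tables for a duo-cohort
study: per-gene variant counts scale with coding length (Poisson with mean
``coding_length_kb * baseline_rate * multiplier``), candidate genes in cases
carry a configurable enrichment multiplier, roughly half of each infant's
variants are maternally transmitted (and then appear verbatim in the
mother's table), and designated genes are planted as compound heterozygotes.
Decoy variants that fail each filter stage — low quality metrics, synonymous
consequence, common allele frequency, benign predictions — are mixed in at
configurable fractions so the whole cascade is exercised.

Mechanically, each gene owns a catalog of candidate variant *sites* on a
single synthetic chromosome; a sample carries each site independently with
probability ``lambda_gene / n_sites_gene``, which makes per-gene counts
Binomial ~ Poisson(lambda) while guaranteeing distinct sites within a
sample and shared site annotations across carriers.  Quality metrics of a
transmitted variant are drawn once per duo and shared by the infant and
mother copies, so transmission truth and filtered-profile attribution
coincide exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .filtering import FilterThresholds, filter_variants
from .model import (
    AnnotatedVariant,
    Consequence,
    GeneModel,
    GeneSet,
    Sample,
    VariantKey,
)
from .variant_io import write_variant_table

_GENE_BLOCK = 1_000_000  # one coordinate block per gene on chromosome "1"

# consequence mix among functional (non-synonymous-or-splice) sites
_FUNCTIONAL_CLASSES = [
    (Consequence.NONSYNONYMOUS_SNV, 0.70),
    (Consequence.STOPGAIN, 0.08),
    (Consequence.STOPLOSS, 0.02),
    (Consequence.FRAMESHIFT_INDEL, 0.08),
    (Consequence.NONFRAMESHIFT_INDEL, 0.06),
    (Consequence.SPLICE_SITE, 0.06),
]
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class QualityNoise:
    """Distributions for per-observation quality metrics and decoy fractions.

    ``fail_quality_fraction`` of observations fail exactly one randomly
    chosen caller-metric floor; the remainder are drawn safely above every
    floor (total depth ~ Poisson around the study-like 43x, alt depth about
    half of it, GQ around 60, MQ at the caller's 60 cap).
    ``synonymous_fraction`` of catalog sites are synonymous decoys,
    ``benign_fraction`` carry unanimous benign predictions, and
    ``no_prediction_fraction`` have no prediction at all (which passes).
    """

    fail_quality_fraction: float = 0.15
    synonymous_fraction: float = 0.15
    benign_fraction: float = 0.10
    no_prediction_fraction: float = 0.05
    mean_total_depth: float = 43.0
    mean_genotype_quality: float = 60.0

    def __post_init__(self) -> None:
        for name in ("fail_quality_fraction", "synonymous_fraction", "benign_fraction",
                     "no_prediction_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the duo-study design: 12 ALL + 11 AML mother-infant
    pairs and 12 unaffected controls; infants enriched for candidate-gene
    variation with mothers enriched to a lesser degree; half of infant
    variants maternally transmitted; two genes planted as compound
    heterozygotes (one in every infant, one in half), echoing the
    recurrently compound-heterozygous genes the duo design is built to find.
    """

    seed: int = 0
    n_duos_all: int = 12
    n_duos_aml: int = 11
    n_controls: int = 12
    n_genes: int = 2000
    candidate_fraction: float = 0.05
    gene_length_distribution: tuple[float, float] = (7.2, 0.6)  # (log-mean, log-sd), bases
    # Raw variants per coding kb per exome.  Sized so that the 23 infants'
    # aggregate leaves ~40-60% of the gene universe variant — the geometry
    # the group-level overlap statistic operates on — rather than saturating
    # it; per-exome counts are correspondingly scaled down.
    baseline_rate: float = 0.05
    enrichment_multiplier_infant: float = 2.0
    enrichment_multiplier_mother: float = 1.5
    transmission_prob: float = 0.5
    planted_compound_het_genes: tuple[tuple[str, float], ...] = (
        ("G0001", 1.0),
        ("G0002", 0.5),
    )
    quality_noise: QualityNoise = field(default_factory=QualityNoise)
    common_variant_fraction: float = 0.30
    site_density: float = 0.05  # catalog sites per coding base

    def __post_init__(self) -> None:
        for name in ("candidate_fraction", "transmission_prob", "common_variant_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        for name in ("enrichment_multiplier_infant", "enrichment_multiplier_mother"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        planted = tuple(tuple(p) for p in self.planted_compound_het_genes)
        object.__setattr__(self, "planted_compound_het_genes", planted)
        if len({g for g, _ in planted}) < len(planted):
            raise ValueError("planted_compound_het_genes contains duplicate genes")
        if self.n_genes < len(planted):
            raise ValueError("n_genes must be >= number of planted genes")
        for _, frac in planted:
            if not 0 <= frac <= 1:
                raise ValueError("planted fractions must be in [0,1]")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the variant tables.

    ``origin`` records, for every infant variant, whether it was transmitted
    by the mother; ``qualifying`` records whether each emitted variant was
    generated to survive the default filter cascade (no quality failure, a
    functional consequence, rare in every panel, not unanimously benign).
    ``realized_gene_counts`` tallies qualifying infant variants per gene.
    """

    candidate_genes: frozenset[str]
    origin: dict[tuple[str, VariantKey], str]
    qualifying: dict[tuple[str, VariantKey], bool]
    planted_compound_het: dict[str, list[str]]
    realized_gene_counts: dict[str, int]


@dataclass
class SyntheticCohort:
    variants: dict[str, list[AnnotatedVariant]]  # sample_id -> raw variant table
    samples: list[Sample]
    gene_models: list[GeneModel]
    gene_sets: dict[str, GeneSet]
    truth: TruthRecord
    config: SimulationConfig


class _SiteCatalog:
    """Per-gene site pools with fixed site-level annotations."""

    def __init__(self, rng: np.random.Generator, config: SimulationConfig):
        noise = config.quality_noise
        width = max(4, len(str(config.n_genes)))
        self.gene_names = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
        mu, sigma = config.gene_length_distribution
        self.lengths = np.maximum(
            200, rng.lognormal(mu, sigma, config.n_genes).astype(np.int64)
        )
        n_candidates = int(round(config.candidate_fraction * config.n_genes))
        cand_idx = rng.choice(config.n_genes, size=n_candidates, replace=False)
        self.candidate_mask = np.zeros(config.n_genes, dtype=bool)
        self.candidate_mask[cand_idx] = True

        self.n_sites_per_gene = np.maximum(
            3, np.round(self.lengths * config.site_density).astype(np.int64)
        )
        self.n_sites_per_gene = np.minimum(self.n_sites_per_gene, self.lengths)
        S = int(self.n_sites_per_gene.sum())
        self.site_gene = np.repeat(np.arange(config.n_genes), self.n_sites_per_gene)
        # distinct positions inside each gene's coordinate block
        pos = np.empty(S, dtype=np.int64)
        start = 0
        for g in range(config.n_genes):
            k = int(self.n_sites_per_gene[g])
            offsets = rng.choice(int(self.lengths[g]), size=k, replace=False)
            pos[start : start + k] = (g + 1) * _GENE_BLOCK + np.sort(offsets) + 1
            start += k
        self.pos = pos

        # consequence classes
        cons = np.empty(S, dtype=object)
        syn = rng.random(S) < noise.synonymous_fraction
        cons[syn] = Consequence.SYNONYMOUS
        classes, probs = zip(*_FUNCTIONAL_CLASSES)
        picks = rng.choice(len(classes), size=S, p=np.array(probs) / sum(probs))
        for i, c in enumerate(classes):
            cons[(~syn) & (picks == i)] = c
        self.consequence = cons

        # alleles: SNVs everywhere except indel consequence classes
        ref_i = rng.integers(0, 4, S)
        alt_i = (ref_i + rng.integers(1, 4, S)) % 4
        ref = _BASES[ref_i].astype(object)
        alt = _BASES[alt_i].astype(object)
        ins1 = _BASES[rng.integers(0, 4, S)]
        for i in range(S):
            if cons[i] is Consequence.FRAMESHIFT_INDEL:
                alt[i] = ref[i] + ins1[i]
            elif cons[i] is Consequence.NONFRAMESHIFT_INDEL:
                alt[i] = ref[i] + 3 * ins1[i]
        self.ref, self.alt = ref, alt

        # population allele frequencies
        common = rng.random(S) < config.common_variant_fraction
        af1 = np.full(S, np.nan)
        af2 = np.full(S, np.nan)
        af1[common] = rng.uniform(0.01, 0.5, int(common.sum()))
        in_dbsnp = common & (rng.random(S) < 0.7)
        af2[in_dbsnp] = rng.uniform(0.01, 0.5, int(in_dbsnp.sum()))
        rare = ~common
        seen1 = rare & (rng.random(S) < 0.5)
        seen2 = rare & (rng.random(S) < 0.5)
        af1[seen1] = rng.uniform(1e-4, 0.0095, int(seen1.sum()))
        af2[seen2] = rng.uniform(1e-4, 0.0095, int(seen2.sum()))
        self.af_1000g, self.af_dbsnp = af1, af2
        self.common = common

        # deleteriousness predictions (4 algorithms)
        u = rng.random(S)
        self.del_total = np.full(S, 4, dtype=np.int64)
        self.del_votes = rng.integers(1, 5, S)
        no_pred = u < noise.no_prediction_fraction
        benign = (~no_pred) & (u < noise.no_prediction_fraction + noise.benign_fraction)
        self.del_total[no_pred] = 0
        self.del_votes[no_pred] = 0
        self.del_votes[benign] = 0

        functional = np.array([c in _RETAINED for c in cons])
        votes_pass = (self.del_total == 0) | (self.del_votes >= 1)
        self.qualifying = functional & (~common) & votes_pass

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def force_qualifying(self, s: int) -> None:
        """Make catalog site ``s`` pass every annotation-level filter."""
        self.consequence[s] = Consequence.NONSYNONYMOUS_SNV
        if len(str(self.ref[s])) != 1 or len(str(self.alt[s])) != 1:
            self.alt[s] = "ACGT"[("ACGT".index(str(self.ref[s])[0]) + 1) % 4]
            self.ref[s] = str(self.ref[s])[0]
        self.af_1000g[s] = np.nan
        self.af_dbsnp[s] = np.nan
        self.common[s] = False
        self.del_total[s] = 4
        self.del_votes[s] = 3
        self.qualifying[s] = True


_RETAINED = frozenset(
    {
        Consequence.NONSYNONYMOUS_SNV,
        Consequence.STOPGAIN,
        Consequence.STOPLOSS,
        Consequence.FRAMESHIFT_INDEL,
        Consequence.NONFRAMESHIFT_INDEL,
        Consequence.SPLICE_SITE,
    }
)


def _carrier_probabilities(cat: _SiteCatalog, config: SimulationConfig, multiplier: float
                           ) -> np.ndarray:
    lam = (
        (cat.lengths / 1000.0)
        * config.baseline_rate
        * np.where(cat.candidate_mask, multiplier, 1.0)
    )
    p_gene = np.minimum(1.0, lam / cat.n_sites_per_gene)
    return p_gene[cat.site_gene]


def _draw_quality(rng: np.random.Generator, n: int, noise: QualityNoise):
    """Quality metrics for ``n`` observations; a fraction fail one floor."""
    total = np.maximum(10, rng.poisson(noise.mean_total_depth, n))
    alt = np.clip(rng.binomial(total, 0.5), 5, total)
    gq = np.clip(rng.poisson(noise.mean_genotype_quality, n), 10, 99)
    mq = np.full(n, 60, dtype=np.int64)
    fail = rng.random(n) < noise.fail_quality_fraction
    which = rng.integers(0, 4, n)
    m = fail & (which == 0)  # allele depth below floor
    alt[m] = rng.integers(0, 5, int(m.sum()))
    m = fail & (which == 1)  # position depth below floor
    total[m] = rng.integers(2, 10, int(m.sum()))
    alt[m] = (rng.random(int(m.sum())) * (total[m] + 1)).astype(np.int64)
    m = fail & (which == 2)
    gq[m] = rng.integers(0, 10, int(m.sum()))
    m = fail & (which == 3)
    mq[m] = rng.integers(20, 60, int(m.sum()))
    return alt, total, gq, mq, fail


def _passing_quality(rng: np.random.Generator, n: int, noise: QualityNoise):
    total = np.maximum(10, rng.poisson(noise.mean_total_depth, n))
    alt = np.clip(rng.binomial(total, 0.5), 5, total)
    gq = np.clip(rng.poisson(noise.mean_genotype_quality, n), 10, 99)
    mq = np.full(n, 60, dtype=np.int64)
    return alt, total, gq, mq, np.zeros(n, dtype=bool)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a duo cohort with controls; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    cat = _SiteCatalog(rng, config)
    gene_names = cat.gene_names
    name_to_idx = {g: i for i, g in enumerate(gene_names)}

    # reserve and force two qualifying sites per planted gene
    reserved = np.zeros(cat.n_sites, dtype=bool)
    planted_sites: dict[str, tuple[int, int]] = {}
    for gene, _frac in config.planted_compound_het_genes:
        gi = name_to_idx.get(gene)
        if gi is None:
            raise ValueError(f"planted gene {gene!r} not among generated genes")
        sites = np.flatnonzero(cat.site_gene == gi)
        if len(sites) < 2:
            raise ValueError(
                f"planted gene {gene!r} too short to host 2 distinct variant sites"
            )
        s1, s2 = int(sites[0]), int(sites[1])
        cat.force_qualifying(s1)
        cat.force_qualifying(s2)
        reserved[[s1, s2]] = True
        planted_sites[gene] = (s1, s2)

    samples: list[Sample] = []
    duos: list[tuple[Sample, Sample]] = []
    for cohort, n_duos in (("ALL", config.n_duos_all), ("AML", config.n_duos_aml)):
        for k in range(n_duos):
            duo_id = f"{cohort}{k + 1:02d}"
            infant = Sample(f"{duo_id}-I", "infant", cohort, duo_id)
            mother = Sample(f"{duo_id}-M", "mother", cohort, duo_id)
            samples.extend([infant, mother])
            duos.append((infant, mother))
    controls = [
        Sample(f"CTRL{k + 1:02d}", "control", "control") for k in range(config.n_controls)
    ]
    samples.extend(controls)

    infants = [inf for inf, _ in duos]
    planted_assignment: dict[str, list[str]] = {g: [] for g, _ in config.planted_compound_het_genes}
    for gene, frac in config.planted_compound_het_genes:
        k = int(round(frac * len(infants)))
        if k > 0:
            chosen = rng.choice(len(infants), size=k, replace=False)
            planted_assignment[gene] = sorted(infants[i].sample_id for i in chosen)

    p_infant = _carrier_probabilities(cat, config, config.enrichment_multiplier_infant)
    p_mother = _carrier_probabilities(cat, config, config.enrichment_multiplier_mother)
    p_control = _carrier_probabilities(cat, config, 1.0)

    noise = config.quality_noise
    variants: dict[str, list[AnnotatedVariant]] = {}
    origin: dict[tuple[str, VariantKey], str] = {}
    qualifying: dict[tuple[str, VariantKey], bool] = {}
    realized: dict[str, int] = {}

    def materialize(sample_id: str, site_idx: np.ndarray, qual) -> list[AnnotatedVariant]:
        alt_d, tot_d, gq, mq, fail = qual
        out = []
        for j, s in enumerate(site_idx):
            afs = {}
            if not np.isnan(cat.af_1000g[s]):
                afs["1000g"] = float(cat.af_1000g[s])
            if not np.isnan(cat.af_dbsnp[s]):
                afs["dbsnp"] = float(cat.af_dbsnp[s])
            v = AnnotatedVariant(
                sample_id=sample_id,
                chrom="1",
                pos=int(cat.pos[s]),
                ref=str(cat.ref[s]),
                alt=str(cat.alt[s]),
                gene=gene_names[cat.site_gene[s]],
                consequence=cat.consequence[s],
                alt_depth=int(alt_d[j]),
                total_depth=int(max(tot_d[j], alt_d[j])),
                genotype_quality=int(gq[j]),
                mapping_quality=int(mq[j]),
                pop_afs=afs,
                deleterious_votes=int(cat.del_votes[s]),
                deleterious_total=int(cat.del_total[s]),
            )
            out.append(v)
            qualifying[(sample_id, v.key)] = bool(cat.qualifying[s] and not fail[j])
        return out

    for infant, mother in duos:
        carry = (rng.random(cat.n_sites) < p_infant) & ~reserved
        maternal_flag = rng.random(cat.n_sites) < config.transmission_prob
        transmitted = carry & maternal_flag
        non_maternal = carry & ~maternal_flag
        mother_own = (rng.random(cat.n_sites) < p_mother) & ~reserved & ~non_maternal

        # planted compound-het sites for this infant: s1 maternal, s2 non-maternal
        plant_mat, plant_non = [], []
        for gene, assigned in planted_assignment.items():
            if infant.sample_id in assigned:
                s1, s2 = planted_sites[gene]
                plant_mat.append(s1)
                plant_non.append(s2)

        inf_idx = np.concatenate(
            [np.flatnonzero(carry), np.array(plant_mat + plant_non, dtype=np.int64)]
        ).astype(np.int64)
        inf_qual = _draw_quality(rng, len(inf_idx), noise)
        # force planted observations to pass every quality floor
        n_plant = len(plant_mat) + len(plant_non)
        if n_plant:
            pq = _passing_quality(rng, n_plant, noise)
            for arr, parr in zip(inf_qual, pq):
                arr[-n_plant:] = parr
        variants[infant.sample_id] = materialize(infant.sample_id, inf_idx, inf_qual)

        maternal_sites = set(np.flatnonzero(transmitted).tolist()) | set(plant_mat)
        for s, v in zip(inf_idx, variants[infant.sample_id]):
            origin[(infant.sample_id, v.key)] = (
                "maternal" if int(s) in maternal_sites else "non_maternal"
            )

        # mother: transmitted copies share the infant's quality metrics
        trans_pos = [j for j, s in enumerate(inf_idx) if int(s) in maternal_sites]
        trans_idx = inf_idx[trans_pos]
        trans_qual = tuple(arr[trans_pos] for arr in inf_qual)
        own_idx = np.flatnonzero(mother_own)
        own_qual = _draw_quality(rng, len(own_idx), noise)
        variants[mother.sample_id] = materialize(
            mother.sample_id, np.concatenate([trans_idx, own_idx]),
            tuple(np.concatenate([t, o]) for t, o in zip(trans_qual, own_qual)),
        )

    for ctrl in controls:
        carry = (rng.random(cat.n_sites) < p_control) & ~reserved
        idx = np.flatnonzero(carry)
        variants[ctrl.sample_id] = materialize(ctrl.sample_id, idx, _draw_quality(rng, len(idx), noise))

    for infant, _ in duos:
        for v in variants[infant.sample_id]:
            if qualifying[(infant.sample_id, v.key)]:
                realized[v.gene] = realized.get(v.gene, 0) + 1

    candidate_genes = frozenset(
        gene_names[i] for i in np.flatnonzero(cat.candidate_mask)
    )
    gene_sets = {
        "candidates": GeneSet(
            name="candidates", genes=candidate_genes, provenance="synthetic candidate list"
        )
    }
    gene_models = [
        GeneModel(gene=gene_names[i], coding_length=int(cat.lengths[i]))
        for i in range(config.n_genes)
    ]
    truth = TruthRecord(
        candidate_genes=candidate_genes,
        origin=origin,
        qualifying=qualifying,
        planted_compound_het=planted_assignment,
        realized_gene_counts=realized,
    )
    return SyntheticCohort(
        variants=variants,
        samples=samples,
        gene_models=gene_models,
        gene_sets=gene_sets,
        truth=truth,
        config=config,
    )


def filtered_profiles(
    cohort: SyntheticCohort, thresholds: Optional[FilterThresholds] = None
) -> dict[str, "FilteredProfile"]:
    """Run the full filter cascade on every sample of a cohort."""
    return {
        sid: filter_variants(vs, thresholds) for sid, vs in cohort.variants.items()
    }


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort in the pipeline's external input formats.

    Emits per-sample VCFs, one shared annotation TSV, per-sample variant
    tables, a samples table, the candidate gene list, the gene-model table
    and the ground truth as JSON.  Reading the VCF + annotation TSV back
    through :func:`duoburden.variant_io.read_vcf` reproduces the in-memory
    variants exactly.
    """
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    (out / "variant_tables").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    import pandas as pd

    samples_df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "role": s.role.value,
                "cohort": s.cohort.value,
                "duo_id": s.duo_id or "",
            }
            for s in cohort.samples
        ]
    )
    paths["samples"] = out / "samples.tsv"
    samples_df.to_csv(paths["samples"], sep="\t", index=False)

    models_df = pd.DataFrame(
        [{"gene": m.gene, "coding_length": m.coding_length} for m in cohort.gene_models]
    )
    paths["gene_models"] = out / "gene_models.tsv"
    models_df.to_csv(paths["gene_models"], sep="\t", index=False)

    for name, gs in cohort.gene_sets.items():
        p = out / f"genes_{name}.txt"
        p.write_text("\n".join(sorted(gs.genes)) + "\n")
        paths[f"gene_set_{name}"] = p

    # shared site-level annotation table (only sites carried by someone)
    ann_rows = {}
    for vs in cohort.variants.values():
        for v in vs:
            ann_rows[(v.chrom, v.pos, v.ref, v.alt, v.gene)] = {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "consequence": v.consequence.value,
                "af_1000g": v.pop_afs.get("1000g", float("nan")),
                "af_dbsnp": v.pop_afs.get("dbsnp", float("nan")),
                "deleterious_votes": v.deleterious_votes,
                "deleterious_total": v.deleterious_total,
            }
    ann_df = pd.DataFrame(
        [ann_rows[k] for k in sorted(ann_rows)],
    )
    paths["annotation"] = out / "annotation.tsv"
    ann_df.to_csv(paths["annotation"], sep="\t", index=False, na_rep="")

    contig_len = (cohort.config.n_genes + 2) * _GENE_BLOCK
    for sid, vs in cohort.variants.items():
        vcf_path = out / "vcf" / f"{sid}.vcf"
        _write_sample_vcf(vcf_path, sid, vs, contig_len)
        paths[f"vcf_{sid}"] = vcf_path
        table_path = out / "variant_tables" / f"{sid}.tsv"
        write_variant_table(vs, table_path)
        paths[f"variant_table_{sid}"] = table_path

    truth_json = {
        "candidate_genes": sorted(cohort.truth.candidate_genes),
        "planted_compound_het": cohort.truth.planted_compound_het,
        "origin": {
            f"{sid}|{c}:{p}:{r}:{a}": o
            for (sid, (c, p, r, a)), o in cohort.truth.origin.items()
        },
        "qualifying": {
            f"{sid}|{c}:{p}:{r}:{a}": q
            for (sid, (c, p, r, a)), q in cohort.truth.qualifying.items()
        },
        "realized_gene_counts": cohort.truth.realized_gene_counts,
        "config": _config_to_json(cohort.config),
    }
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    return paths


def _config_to_json(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["quality_noise"] = dataclasses.asdict(config.quality_noise)
    d["planted_compound_het_genes"] = [list(p) for p in config.planted_compound_het_genes]
    d["gene_length_distribution"] = list(config.gene_length_distribution)
    return d


def _write_sample_vcf(
    path: Path, sample_id: str, variants: list[AnnotatedVariant], contig_len: int
) -> None:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID=1,length={contig_len}>")
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda x: (x.pos, x.ref, x.alt)):
            rec = vf.new_record(
                contig="1",
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["MQ"] = v.mapping_quality
            call = rec.samples[sample_id]
            call["GT"] = (0, 1)
            call["AD"] = (v.total_depth - v.alt_depth, v.alt_depth)
            call["DP"] = v.total_depth
            call["GQ"] = v.genotype_quality
            vf.write(rec)
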