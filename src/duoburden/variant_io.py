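"""Readers and writers for variant tables, gene lists and result files.

Three external formats are understood:

* **VCF v4.x** (via :mod:`pysam`) — the caller's output; FORMAT fields
  ``GT``/``AD``/``DP``/``GQ`` and INFO ``MQ`` are consumed.  Multi-allelic
  records are decomposed into one row per alt allele.
* **Annotation TSV** — a tab-separated site table with the columns
  ``chrom pos ref alt gene consequence af_1000g af_dbsnp deleterious_votes
  deleterious_total`` (missing allele frequencies encoded as empty strings).
  It is joined onto VCF records by normalized ``(chrom, pos, ref, alt)``.
* **Variant-table TSV** — this package's own per-sample flat export, a
  lossless round-trippable join of both of the above.

All result tables are written as TSV next to a JSON run manifest that records
the configuration, seed and SHA-256 checksums of every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import pysam

from .model import (
    AnnotatedVariant,
    Consequence,
    GeneModel,
    GeneSet,
    Sample,
    normalize_alleles,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "af_1000g",
    "af_dbsnp",
    "deleterious_votes",
    "deleterious_total",
]

VARIANT_TABLE_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "alt_depth",
    "total_depth",
    "genotype_quality",
    "mapping_quality",
    "af_1000g",
    "af_dbsnp",
    "deleterious_votes",
    "deleterious_total",
]

class VariantParseError(ValueError):
    """A malformed record in a variant input file."""


class IntegrityError(RuntimeError):
    """A written result no longer matches its manifest checksum."""


# ---------------------------------------------------------------------------
# annotation table


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the annotation TSV dialect, validating allele frequencies.

    Returns a DataFrame with normalized keys; a single site may appear on
    several rows when annotated to more than one gene.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
        float_precision="round_trip",
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise VariantParseError(f"annotation table {path} missing columns: {missing}")
    for col in ("af_1000g", "af_dbsnp"):
        af = pd.to_numeric(df[col], errors="coerce")
        bad = af.notna() & ((af < 0) | (af > 1))
        if bad.any():
            row = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise VariantParseError(
                f"annotation table {path}: {col} outside [0,1] at line {row}"
            )
        df[col] = af
    # normalize identity keys once, up front
    norm = [
        normalize_alleles(int(p), str(r), str(a))
        for p, r, a in zip(df["pos"], df["ref"], df["alt"])
    ]
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = [n[0] for n in norm]
    df["ref"] = [n[1] for n in norm]
    df["alt"] = [n[2] for n in norm]
    return df


def _annotation_index(annotation: pd.DataFrame) -> dict[tuple, list[dict]]:
    idx: dict[tuple, list[dict]] = {}
    for row in annotation.itertuples(index=False):
        idx.setdefault((row.chrom, row.pos, row.ref, row.alt), []).append(
            {
                "gene": str(row.gene),
                "consequence": str(row.consequence),
                "af_1000g": row.af_1000g,
                "af_dbsnp": row.af_dbsnp,
                "deleterious_votes": int(row.deleterious_votes),
                "deleterious_total": int(row.deleterious_total),
            }
        )
    return idx


def _pop_afs(af_1000g: float, af_dbsnp: float) -> dict[str, float]:
    afs = {}
    if af_1000g is not None and not (isinstance(af_1000g, float) and math.isnan(af_1000g)):
        afs["1000g"] = float(af_1000g)
    if af_dbsnp is not None and not (isinstance(af_dbsnp, float) and math.isnan(af_dbsnp)):
        afs["dbsnp"] = float(af_dbsnp)
    return afs


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | Path,
    sample_id: str,
    annotation_table_path: str | Path | None = None,
) -> list[AnnotatedVariant]:
    """Read one sample's variants from a VCF, joining annotations from TSV.

    Multi-allelic records are decomposed into one :class:`AnnotatedVariant`
    per alt allele carried by the sample's genotype.  Records with no row in
    the annotation table get ``consequence=other`` and empty ``pop_afs``.
    Per-allele depth comes from FORMAT ``AD``; when ``AD`` is absent the
    alt depth is unknown and recorded as 0, so such variants fail the
    per-allele coverage floor downstream (conservative).
    """
    ann_idx: dict[tuple, list[dict]] = {}
    if annotation_table_path is not None:
        ann_idx = _annotation_index(read_annotation_table(annotation_table_path))

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VariantParseError(f"cannot open VCF {path}: {exc}") from exc
    if sample_id not in vcf.header.samples:
        raise VariantParseError(f"sample {sample_id!r} not present in VCF {path}")

    out: list[AnnotatedVariant] = []
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            out.extend(_decompose_record(rec, sample_id, ann_idx))
    except (ValueError, OSError) as exc:
        raise VariantParseError(
            f"malformed VCF record #{record_no + 1} in {path}: {exc}"
        ) from exc
    finally:
        vcf.close()
    return out


def _decompose_record(
    rec: "pysam.VariantRecord", sample_id: str, ann_idx: dict[tuple, list[dict]]
) -> list[AnnotatedVariant]:
    call = rec.samples[sample_id]
    gt = call.get("GT") or ()
    alts = rec.alts or ()
    ad = call.get("AD")
    dp = call.get("DP")
    gq = call.get("GQ")
    mq = rec.info.get("MQ", 0)
    if isinstance(mq, tuple):
        mq = mq[0] if mq else 0
    total_depth = None
    if ad is not None and all(a is not None for a in ad):
        total_depth = int(sum(ad))
    elif dp is not None:
        total_depth = int(dp)

    rows = []
    for alt_index, alt in enumerate(alts, start=1):
        if gt and alt_index not in gt:
            continue  # sample does not carry this alt allele
        if alt is None or alt in {"*", "<NON_REF>"}:
            continue
        if ad is not None and len(ad) > alt_index and ad[alt_index] is not None:
            alt_depth = int(ad[alt_index])
            total = int(sum(a for a in ad if a is not None))
        else:
            alt_depth = 0  # AD unavailable: cannot certify per-allele coverage
            total = total_depth or 0
        pos, ref, nalt = normalize_alleles(rec.pos, rec.ref, alt)
        chrom = normalize_chrom(rec.chrom)
        key = (chrom, pos, ref, nalt)
        annotations = ann_idx.get(key) or [
            {
                "gene": "",
                "consequence": Consequence.OTHER.value,
                "af_1000g": float("nan"),
                "af_dbsnp": float("nan"),
                "deleterious_votes": 0,
                "deleterious_total": 0,
            }
        ]
        for ann in annotations:  # one row per annotated gene
            rows.append(
                AnnotatedVariant(
                    sample_id=sample_id,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=nalt,
                    gene=ann["gene"],
                    consequence=Consequence(ann["consequence"]),
                    alt_depth=alt_depth,
                    total_depth=max(total, alt_depth),
                    genotype_quality=int(gq) if gq is not None else 0,
                    mapping_quality=int(mq) if mq is not None else 0,
                    pop_afs=_pop_afs(ann["af_1000g"], ann["af_dbsnp"]),
                    deleterious_votes=ann["deleterious_votes"],
                    deleterious_total=ann["deleterious_total"],
                )
            )
    return rows


# ---------------------------------------------------------------------------
# variant-table TSV (this package's flat per-sample export)


def variants_to_frame(variants: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "consequence": v.consequence.value,
                "alt_depth": v.alt_depth,
                "total_depth": v.total_depth,
                "genotype_quality": v.genotype_quality,
                "mapping_quality": v.mapping_quality,
                "af_1000g": v.pop_afs.get("1000g", float("nan")),
                "af_dbsnp": v.pop_afs.get("dbsnp", float("nan")),
                "deleterious_votes": v.deleterious_votes,
                "deleterious_total": v.deleterious_total,
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)


def write_variant_table(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    df = variants_to_frame(variants)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="")


def read_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
        float_precision="round_trip",
    )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AnnotatedVariant(
                sample_id=str(row.sample_id),
                chrom=normalize_chrom(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gene="" if pd.isna(row.gene) else str(row.gene),
                consequence=Consequence(row.consequence),
                alt_depth=int(row.alt_depth),
                total_depth=int(row.total_depth),
                genotype_quality=int(row.genotype_quality),
                mapping_quality=int(row.mapping_quality),
                pop_afs=_pop_afs(row.af_1000g, row.af_dbsnp),
                deleterious_votes=int(row.deleterious_votes),
                deleterious_total=int(row.deleterious_total),
            )
        )
    return out


# ---------------------------------------------------------------------------
# gene lists and gene models


def read_gene_set(path: str | Path, name: str, provenance: str = "") -> GeneSet:
    """Read a gene list (one symbol per line, optional single-column header).

    Symbols are upper-cased and de-duplicated.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    symbols = [ln for ln in lines if ln]
    if symbols and symbols[0].lower() in {"gene", "symbol", "gene_symbol"}:
        symbols = symbols[1:]
    genes = {s.upper() for s in symbols}
    if not genes:
        raise ValueError(f"gene list {path} contains no symbols")
    logger.info("gene set %s: %d unique symbols from %s", name, len(genes), path)
    return GeneSet(name=name, genes=frozenset(genes), provenance=provenance or str(path))


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV with columns ``gene`` and ``coding_length``."""
    df = pd.read_csv(path, sep="\t")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"gene model table {path}: duplicate gene symbol {dup!r}")
    return [
        GeneModel(gene=str(r.gene).upper(), coding_length=int(r.coding_length))
        for r in df.itertuples(index=False)
    ]


def read_samples_table(path: str | Path) -> list[Sample]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        duo = getattr(r, "duo_id", None)
        if duo is not None and (pd.isna(duo) or duo == ""):
            duo = None
        out.append(
            Sample(sample_id=str(r.sample_id), role=str(r.role), cohort=str(r.cohort), duo_id=duo)
        )
    return out


# ---------------------------------------------------------------------------
# results + manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
    input_paths: Optional[Iterable[str | Path]] = None,
) -> dict:
    """Write result tables as TSV plus a JSON run manifest.

    File names are deterministic (``<name>.tsv``); the manifest records the
    configuration, the seed, checksums of the inputs and of every table
    written, so identical inputs and seed reproduce byte-identical output.
    Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in sorted(results):
        path = out / f"{name}.tsv"
        results[name].to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")
        files[name] = {
            "path": path.name,
            "sha256": _sha256(path),
            "n_rows": int(len(results[name])),
        }
    manifest = {
        "config": dict(config) if config else {},
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in (input_paths or [])},
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def verify_manifest(out_dir: str | Path) -> dict:
    """Re-check every checksum in a run manifest; raise on any mismatch."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    for name, entry in manifest["files"].items():
        path = out / entry["path"]
        if not path.exists():
            raise IntegrityError(f"result table {name} missing: {path}")
        digest = _sha256(path)
        if digest != entry["sha256"]:
            raise IntegrityError(
                f"checksum mismatch for {name}: manifest {entry['sha256'][:12]}…, "
                f"file {digest[:12]}…"
            )
    return manifest
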