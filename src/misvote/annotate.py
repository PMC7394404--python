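"""Read missense variants from VCF and join per-variant feature annotations.

Variants enter the pipeline from VCF v4.x files whose INFO field carries the
predicted consequence and amino-acid change under configurable keys.
Feature values are joined from tab-separated annotation tables keyed by
``(chrom, pos, ref, alt)`` — the layout produced by tools that flatten
dbNSFP/CADD-style databases.  Amino-acid substitution features are computed
on the fly from AAindex matrices when the amino-acid change is known.

Missing annotations are tracked in a coverage mask rather than imputed;
training keeps only fully covered variants (``filter_full_coverage``), while
clinical scoring may opt into median imputation (``impute_missing``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .features import (
    AAindexMatrix,
    FeatureManifest,
    FeatureMatrix,
    VariantKey,
    aaindex_substitution_value,
    normalize_chrom,
)

__all__ = [
    "VcfDialect",
    "VcfFormatError",
    "read_missense_vcf",
    "read_annotation_table",
    "join_features",
    "filter_full_coverage",
    "impute_missing",
]

KEY_COLUMNS = ["CHROM", "POS", "REF", "ALT"]


class VcfFormatError(ValueError):
    """Malformed VCF content, reported with the offending line number."""


@dataclass(frozen=True)
class VcfDialect:
    """Which INFO keys carry the consequence annotation.

    ``permissive=True`` accepts records lacking the consequence key (useful
    for pre-filtered files that contain only missense variants).
    ``transcript_choice`` selects among multiple comma-separated
    transcript annotations: "first" takes the first, "canonical" prefers an
    entry flagged with ``|CANONICAL``.
    """

    consequence_key: str = "CONSEQUENCE"
    aa_key: str = "AA"
    gene_key: str = "GENE"
    missense_term: str = "missense"
    permissive: bool = False
    transcript_choice: str = "first"


def _prescan(path) -> None:
    """Cheap structural validation so format errors carry line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfFormatError(
                    f"line {lineno}: expected >= 8 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                int(fields[1])
            except ValueError:
                raise VcfFormatError(
                    f"line {lineno}: POS field {fields[1]!r} is not an integer"
                ) from None


def _pick_transcript(raw: str, dialect: VcfDialect) -> str:
    entries = raw.split(",")
    if dialect.transcript_choice == "canonical":
        for e in entries:
            if "|CANONICAL" in e:
                return e.split("|")[0]
    return entries[0].split("|")[0]


def read_missense_vcf(path, dialect: VcfDialect | None = None) -> list[VariantKey]:
    """Read all missense records from a VCF file.

    Multi-allelic records are split into one :class:`VariantKey` per ALT
    allele.  A record is missense when its consequence annotation contains
    ``dialect.missense_term``; per-alt consequence values are supported as
    comma-separated lists aligned with the ALT alleles.
    """
    dialect = dialect or VcfDialect()
    _prescan(path)
    variants: list[VariantKey] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            csq_raw = rec.INFO.get(dialect.consequence_key)
            if csq_raw is None and not dialect.permissive:
                raise VcfFormatError(
                    f"record {rec.CHROM}:{rec.POS} lacks INFO key "
                    f"{dialect.consequence_key!r} (set permissive=True to accept)"
                )
            aa_raw = rec.INFO.get(dialect.aa_key)
            gene = rec.INFO.get(dialect.gene_key)
            alts = rec.ALT
            csq_per_alt = _split_per_alt(csq_raw, len(alts))
            aa_per_alt = _split_per_alt(aa_raw, len(alts))
            for alt, csq, aa in zip(alts, csq_per_alt, aa_per_alt):
                if csq is not None:
                    csq = _pick_transcript(csq, dialect)
                    if dialect.missense_term not in csq:
                        continue
                ref_aa = alt_aa = None
                if aa:
                    parts = aa.split("/")
                    if len(parts) == 2 and all(len(p) == 1 for p in parts):
                        ref_aa, alt_aa = parts
                variants.append(
                    VariantKey(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        gene=gene,
                    )
                )
    finally:
        vcf.close()
    return variants


def _split_per_alt(raw, n_alts: int) -> list:
    """INFO values may be scalar (applies to all alts) or per-alt lists."""
    if raw is None:
        return [None] * n_alts
    if isinstance(raw, (tuple, list)):
        vals = list(raw)
    else:
        vals = str(raw).split(",") if n_alts > 1 and str(raw).count(",") == n_alts - 1 else [raw]
    if len(vals) == n_alts:
        return vals
    return [raw] * n_alts


def read_annotation_table(path) -> pd.DataFrame:
    """Read a tab-separated annotation table keyed by CHROM/POS/REF/ALT."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks key columns {missing}")
    return df


def _index_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["CHROM"] = out["CHROM"].astype(str).map(normalize_chrom)
    out = out.set_index(["CHROM", "POS", "REF", "ALT"])
    # duplicate keys: keep first (transcript collapsing happens upstream)
    return out[~out.index.duplicated(keep="first")]


def join_features(
    variants: Sequence[VariantKey],
    tables: Sequence[pd.DataFrame],
    manifest: FeatureManifest,
    aaindex_set: Mapping[str, AAindexMatrix] | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix for ``variants`` from annotation tables.

    Each manifest feature resolves either to a column of one of the tables
    (first table containing it wins) or, for AAindex features, to a matrix
    lookup on the variant's amino-acid change.  Absent values leave the
    coverage mask False at that cell; the output always has one row per
    input variant.
    """
    aaindex_set = aaindex_set or {}
    indexed = [_index_table(t) for t in tables]

    resolvers: list[tuple[str, object]] = []  # (kind, payload) per feature
    unresolved: list[str] = []
    for spec in manifest:
        if spec.is_aaindex:
            mid = spec.aaindex_id
            if mid not in aaindex_set:
                unresolved.append(f"{spec.name} (aaindex matrix {mid!r})")
                continue
            resolvers.append(("aaindex", aaindex_set[mid]))
        else:
            for t in indexed:
                if spec.source_column in t.columns:
                    resolvers.append(("column", (t, spec.source_column)))
                    break
            else:
                unresolved.append(f"{spec.name} (column {spec.source_column!r})")
    if unresolved:
        raise KeyError(
            "manifest features unresolvable in the supplied tables/matrices: "
            + "; ".join(unresolved)
        )

    n, m = len(variants), len(manifest)
    values = np.zeros((n, m), dtype=float)
    coverage = np.zeros((n, m), dtype=bool)
    for i, v in enumerate(variants):
        key = v.site
        for j, (kind, payload) in enumerate(resolvers):
            if kind == "aaindex":
                if v.ref_aa is not None and v.alt_aa is not None:
                    values[i, j] = aaindex_substitution_value(payload, v.ref_aa, v.alt_aa)
                    coverage[i, j] = True
            else:
                table, col = payload
                try:
                    val = table.at[key, col]
                except KeyError:
                    continue
                if pd.notna(val):
                    values[i, j] = float(val)
                    coverage[i, j] = True
    return FeatureMatrix(list(variants), manifest, values, coverage)


def filter_full_coverage(matrix: FeatureMatrix) -> FeatureMatrix:
    """Keep exactly the rows with complete annotation coverage, in order."""
    mask = matrix.fully_covered_mask()
    return matrix.take(np.flatnonzero(mask))


def impute_missing(matrix: FeatureMatrix) -> tuple[FeatureMatrix, np.ndarray]:
    """Median-impute uncovered cells (for scoring user exomes, not training).

    Returns the imputed matrix (coverage all True) and the per-row count of
    imputed cells so downstream reports can flag degraded predictions.
    Columns with no covered value at all impute to 0.
    """
    values = matrix.values.copy()
    imputed_per_row = (~matrix.coverage).sum(axis=1)
    for j in range(matrix.n_features):
        col_mask = matrix.coverage[:, j]
        fill = float(np.median(matrix.values[col_mask, j])) if col_mask.any() else 0.0
        values[~col_mask, j] = fill
    full = np.ones_like(matrix.coverage)
    return FeatureMatrix(matrix.variants, matrix.manifest, values, full), imputed_per_row
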