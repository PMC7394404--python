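"""Synthetic variants, feature tables and background exomes.

The training sources this pipeline was designed around — clinical variant
archives for positives, population sequencing databases for negatives —
are licensed or too large to redistribute, so this module generates data
with the same statistical structure:

* **class-conditional MAF**: benign variants carry small positive allele
  frequencies (scaled-Beta on (0, 0.01), consistent allele counts so that
  "singleton" is well defined); deleterious variants are mostly absent
  from the population (MAF 0), with the residual mass at very low
  frequency.  The separation shrinks with ``effect_size`` and vanishes at
  ``effect_size = 0`` so null controls are truly label-independent.
* **per-population MAF columns** correlated with the global frequency via
  a shared latent frequency plus multiplicative population noise —
  informative but mutually redundant, as real multi-ethnic columns are.
* **conservation / functional / predictor features**: Gaussian,
  class-shifted by ``effect_size`` standard deviations; a configurable
  ``noise_fraction`` of them is label-independent.
* **amino-acid substitution features**: looked up from (synthetic) AAindex
  matrices on random missense substitutions, label-independent — realistic
  correlated nuisance structure.
* **background exomes**: benign-profile variants with depth and MAF drawn
  so that a realistic fraction survives the clinical DP > 10X, MAF < 1 %
  filters (the post-filter target being a few hundred missense variants
  per exome).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import LabeledDataset
from .features import (
    AMINO_ACIDS,
    AAindexMatrix,
    FeatureManifest,
    FeatureMatrix,
    VariantKey,
    default_manifest,
)

__all__ = [
    "synthetic_aaindex_set",
    "generate_labeled_features",
    "generate_background_exome",
    "write_fixture_vcf",
]

_BASES = "ACGT"
#: fixed allele number for synthetic population frequencies (MAF = AC/AN)
DEFAULT_AN = 250_000


def synthetic_aaindex_set(
    ids: Sequence[str] | None = None, seed: int = 0
) -> dict[str, AAindexMatrix]:
    """Random symmetric 20x20 property matrices standing in for AAindex data.

    These are synthetic matrices (standard-normal symmetric), not real
    AAindex accessions; they give substitution features realistic shared
    structure without redistributing the database.
    """
    if ids is None:
        ids = default_manifest().aaindex_ids()
    rng = np.random.default_rng(seed)
    out: dict[str, AAindexMatrix] = {}
    for mid in ids:
        raw = rng.normal(size=(20, 20))
        out[mid] = AAindexMatrix(mid, (raw + raw.T) / np.sqrt(2))
    return out


def _random_keys(rng: np.random.Generator, n: int, start_pos: int = 1) -> list[VariantKey]:
    chroms = rng.integers(1, 23, size=n)
    positions = start_pos + np.cumsum(rng.integers(1, 5000, size=n))
    keys = []
    aa = list(AMINO_ACIDS)
    for c, p in zip(chroms, positions):
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        ref_aa, alt_aa = rng.choice(aa, size=2, replace=False)
        keys.append(VariantKey(str(c), int(p), str(ref), str(alt), ref_aa, alt_aa))
    return keys


def _sample_maf(
    rng: np.random.Generator, n: int, deleterious: bool, effect_size: float
) -> np.ndarray:
    """Latent global allele frequency per variant.

    Benign: scaled Beta(0.5, 20) on (0, 0.01).  Deleterious: absent (0)
    with probability 0.8 * min(1, effect_size / 3), else a 10x rarer Beta.
    At effect_size = 0 both classes share the benign distribution.
    """
    benign_draw = rng.beta(0.5, 20, size=n) * 0.01
    if not deleterious:
        return benign_draw
    strength = min(1.0, effect_size / 3.0)
    p_absent = 0.8 * strength
    rare_draw = rng.beta(0.5, 20, size=n) * 0.001
    latent = np.where(rng.random(n) < strength, rare_draw, benign_draw)
    latent[rng.random(n) < p_absent] = 0.0
    return latent


def _population_columns(
    rng: np.random.Generator, latent: np.ndarray, n_pops: int
) -> np.ndarray:
    """Per-population frequencies: shared latent x lognormal noise, in [0, 1]."""
    noise = rng.lognormal(mean=0.0, sigma=0.5, size=(len(latent), n_pops))
    return np.clip(latent[:, None] * noise, 0.0, 1.0)


def _consistent_counts(latent: np.ndarray, an: int) -> tuple[np.ndarray, np.ndarray]:
    """Round latent frequencies to allele counts and recompute exact MAF."""
    ac = np.rint(latent * an).astype(int)
    ac[(latent > 0) & (ac == 0)] = 1  # observed variants have AC >= 1
    return ac, ac / an


def generate_labeled_features(
    n_per_class: int,
    manifest: FeatureManifest | None = None,
    effect_size: float = 3.0,
    noise_fraction: float = 0.1,
    seed: int = 0,
    aaindex_set: Mapping[str, AAindexMatrix] | None = None,
    an: int = DEFAULT_AN,
) -> LabeledDataset:
    """Generate a balanced labeled dataset with class-conditional features.

    Parameters
    ----------
    n_per_class
        Number of deleterious and of benign variants.
    effect_size
        Class separation of the informative conservation/functional/
        predictor features in standard deviations; also scales the MAF
        separation.  0 produces fully label-independent features.
    noise_fraction
        Fraction of the Gaussian features made label-independent.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 0 <= noise_fraction <= 1:
        raise ValueError(f"noise_fraction must be in [0, 1], got {noise_fraction}")
    manifest = manifest or default_manifest()
    if aaindex_set is None:
        aaindex_set = synthetic_aaindex_set(manifest.aaindex_ids(), seed=seed)

    rng = np.random.default_rng(seed)
    maf_specs = [f for f in manifest if f.category == "MAF"]
    gauss_specs = [
        f for f in manifest
        if f.category in ("conservation", "functional", "predictor") and not f.is_aaindex
    ]
    noise_flags = rng.random(len(gauss_specs)) < noise_fraction

    blocks = []
    metas = []
    all_keys: list[VariantKey] = []
    for label, deleterious in ((1, True), (0, False)):
        keys = _random_keys(rng, n_per_class, start_pos=1 if deleterious else 10_000_000)
        all_keys.extend(keys)
        latent = _sample_maf(rng, n_per_class, deleterious, effect_size)
        ac, global_maf = _consistent_counts(latent, an)
        pops = _population_columns(rng, global_maf, max(len(maf_specs) - 1, 0))

        values = np.zeros((n_per_class, len(manifest)))
        pop_i = 0
        gauss_i = 0
        for j, spec in enumerate(manifest):
            if spec.category == "MAF":
                if spec.population == "global":
                    values[:, j] = global_maf
                else:
                    values[:, j] = pops[:, pop_i]
                    pop_i += 1
            elif spec.is_aaindex:
                mat = aaindex_set[spec.aaindex_id].values
                ridx = [AMINO_ACIDS.index(k.ref_aa) for k in keys]
                aidx = [AMINO_ACIDS.index(k.alt_aa) for k in keys]
                values[:, j] = mat[ridx, aidx]
            else:
                shift = 0.0
                if deleterious and not noise_flags[gauss_i]:
                    shift = effect_size
                values[:, j] = rng.normal(loc=shift, scale=1.0, size=n_per_class)
                gauss_i += 1
        blocks.append(values)
        depth = np.clip(rng.normal(45, 10, size=n_per_class), 12, None)
        metas.append(
            pd.DataFrame(
                {"MAF": global_maf, "AC": ac, "AN": an, "DP": depth, "label": label}
            )
        )

    values = np.vstack(blocks)
    coverage = np.ones_like(values, dtype=bool)
    labels = np.concatenate(
        [np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    )
    meta = pd.concat(metas, ignore_index=True).drop(columns="label")
    matrix = FeatureMatrix(all_keys, manifest, values, coverage)
    return LabeledDataset(matrix, labels, ["synthetic"] * len(all_keys), meta)


def generate_background_exome(
    n_variants: int,
    manifest: FeatureManifest | None = None,
    maf_profile: Mapping[str, float] | None = None,
    depth_profile: Mapping[str, float] | None = None,
    seed: int = 0,
    aaindex_set: Mapping[str, AAindexMatrix] | None = None,
) -> tuple[pd.DataFrame, LabeledDataset]:
    """One healthy individual's missense background.

    Returns a variant table (keys, DP, MAF, AC, AN) and the matching
    benign-profile feature dataset for scoring.  Default profiles put
    ~90 % of the variants past the DP > 10X, MAF < 1 % clinical filters:
    depth is Normal(45, 12) so a small tail drops below 10X, and a small
    fraction of variants carries a common (> 1 %) frequency.

    ``maf_profile`` keys: ``p_absent`` (no MAF annotation), ``p_common``
    (MAF above 1 %).  ``depth_profile`` keys: ``mean``, ``sd``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    maf_profile = dict(maf_profile or {})
    depth_profile = dict(depth_profile or {})
    p_absent = maf_profile.get("p_absent", 0.03)
    p_common = maf_profile.get("p_common", 0.04)
    depth_mean = depth_profile.get("mean", 45.0)
    depth_sd = depth_profile.get("sd", 12.0)

    base = generate_labeled_features(
        n_per_class=n_variants,
        manifest=manifest,
        effect_size=0.0,  # background exomes are benign-profile
        noise_fraction=0.0,
        seed=seed,
        aaindex_set=aaindex_set,
    )
    benign = base.take(np.flatnonzero(base.labels == 0))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    depth = np.maximum(rng.normal(depth_mean, depth_sd, size=n_variants), 0.0)
    maf = benign.meta["MAF"].to_numpy().copy()
    ac = benign.meta["AC"].to_numpy().copy()
    common = rng.random(n_variants) < p_common
    maf[common] = rng.uniform(0.01, 0.3, size=int(common.sum()))
    ac[common] = np.rint(maf[common] * DEFAULT_AN).astype(int)
    absent = rng.random(n_variants) < p_absent
    maf_col = maf.astype(object)
    maf_col[absent] = np.nan

    variants = pd.DataFrame(
        {
            "CHROM": [v.chrom for v in benign.matrix.variants],
            "POS": [v.pos for v in benign.matrix.variants],
            "REF": [v.ref for v in benign.matrix.variants],
            "ALT": [v.alt for v in benign.matrix.variants],
            "DP": depth,
            "MAF": pd.to_numeric(maf_col),
            "AC": ac,
            "AN": DEFAULT_AN,
        }
    )
    benign.meta = variants[["MAF", "AC", "AN", "DP"]].copy()
    return variants, benign


# ---------------------------------------------------------------------------
# Fixture VCF writing

_INFO_DEFS = {
    "CONSEQUENCE": ("String", "Predicted consequence"),
    "AA": ("String", "Amino-acid change ref/alt"),
    "GENE": ("String", "Gene symbol"),
    "CLNSIG": ("String", "Clinical significance"),
    "CLNREVSTAT": ("String", "Review status"),
    "STATUS": ("String", "Curation status tag"),
    "MAF": ("Float", "Global minor allele frequency"),
    "AC": ("Integer", "Allele count"),
    "AN": ("Integer", "Allele number"),
    "DP": ("Integer", "Site depth"),
}

#: preset INFO layouts selecting which keys the header declares
INFO_LAYOUTS = {
    "plain": ("CONSEQUENCE", "AA", "GENE"),
    "clinvar": ("CONSEQUENCE", "AA", "GENE", "CLNSIG", "CLNREVSTAT"),
    "hgmd": ("CONSEQUENCE", "AA", "GENE", "STATUS"),
    "population": ("CONSEQUENCE", "AA", "GENE", "MAF", "AC", "AN", "DP"),
}


def write_fixture_vcf(
    variants: Sequence[VariantKey | tuple],
    info_layout: str = "plain",
    path=None,
) -> None:
    """Write a well-formed VCF v4.2 exercising the dataset filters.

    ``variants`` items are either bare :class:`VariantKey` (annotated as
    missense) or ``(VariantKey, info_dict)`` pairs whose dict entries
    override or extend the INFO field (e.g. ``{"CLNSIG": "Pathogenic"}``,
    or ``{"CONSEQUENCE": "synonymous"}`` for negative fixtures).
    """
    if path is None:
        raise ValueError("path is required")
    if info_layout not in INFO_LAYOUTS:
        raise ValueError(
            f"unknown info layout {info_layout!r}; choose from {sorted(INFO_LAYOUTS)}"
        )
    keys = INFO_LAYOUTS[info_layout]
    lines = ["##fileformat=VCFv4.2"]
    for k in keys:
        typ, desc = _INFO_DEFS[k]
        num = "1"
        lines.append(
            f'##INFO=<ID={k},Number={num},Type={typ},Description="{desc}">'
        )
    contigs = []
    rows = []
    for item in variants:
        if isinstance(item, VariantKey):
            v, extra = item, {}
        else:
            v, extra = item
        info: dict[str, object] = {"CONSEQUENCE": "missense"}
        if v.ref_aa and v.alt_aa:
            info["AA"] = f"{v.ref_aa}/{v.alt_aa}"
        if v.gene:
            info["GENE"] = v.gene
        info.update(extra)
        # only keys declared in the layout's header are emitted
        info_str = ";".join(
            f"{k}={info[k]}" for k in keys if k in info and info[k] is not None
        )
        if v.chrom not in contigs:
            contigs.append(v.chrom)
        rows.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info_str or '.'}"
        )
    header = lines[:1] + [f"##contig=<ID={c}>" for c in contigs] + lines[1:]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    with open(path, "w") as fh:
        fh.write("\n".join(header + rows) + "\n")
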