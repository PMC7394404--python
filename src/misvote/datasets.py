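"""Construction of high-confidence training and evaluation sets.

The classifier is trained on a balanced positive/negative design:

* positives — clinically curated deleterious missense variants, admitted
  only at the highest review confidence (a ``Pathogenic`` clinical
  significance with multi-submitter/expert-panel/practice-guideline review
  and no conflicting interpretations, or a curated disease-mutation
  ``DM`` status tag);
* negatives — rare missense variants from population sequencing
  (global MAF < 1 %, site depth > 30X), assumed benign because highly
  penetrant Mendelian disease variants cannot be common in healthy cohorts.

Both sides pass a circularity filter that removes any variant present in
the training data of a component predictor, so evaluation is not inflated
by variants a feature has already memorised (type 1 circularity).
Negatives are then subsampled to match the positive count and each class is
split 90/10 into train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix, VariantKey, normalize_chrom

__all__ = [
    "LabeledDataset",
    "ExclusionList",
    "select_clinvar_positives",
    "select_hgmd_positives",
    "select_population_negatives",
    "apply_circularity_filter",
    "balance_and_split",
    "maf_bin_subsets",
    "MAF_BINS",
    "read_exclusion_list",
    "write_exclusion_list",
    "write_dataset_table",
    "dataset_from_table",
    "read_dataset_table",
]

#: Benign-variant rarity bins used by the evaluation scenarios; "singleton"
#: means allele count exactly 1.
MAF_BINS = ("<0.01", "<0.005", "<0.001", "<0.0001", "singleton")

#: Review-status terms that qualify a Pathogenic assertion as high confidence.
HIGH_CONFIDENCE_REVIEW = (
    "criteria_provided,_multiple_submitters",
    "reviewed_by_expert_panel",
    "practice_guideline",
)

_CONFLICT_TERM = "conflicting"


@dataclass
class LabeledDataset:
    """A feature matrix with binary labels and per-variant provenance.

    ``labels[i]`` is 1 for deleterious, 0 for benign.  ``meta`` optionally
    carries per-variant columns (MAF, AC, DP, ...) needed by downstream
    subsetting operations.
    """

    matrix: FeatureMatrix
    labels: np.ndarray
    provenance: list[str]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.matrix)
        if self.labels.shape != (n,):
            raise ValueError(f"labels length {self.labels.shape} != {n} variants")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        if len(self.provenance) != n:
            raise ValueError("provenance length mismatch")
        if self.meta is not None and len(self.meta) != n:
            raise ValueError("meta length mismatch")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())

    def take(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            self.matrix.take(idx),
            self.labels[idx],
            [self.provenance[i] for i in idx],
            self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None,
        )

    def to_table(self) -> pd.DataFrame:
        """Flatten to a tab-separable table: keys, features, label, provenance.

        Meta columns are carried with a ``meta_`` prefix so the table round
        trips through :func:`dataset_from_table`.
        """
        rows = {
            "CHROM": [v.chrom for v in self.matrix.variants],
            "POS": [v.pos for v in self.matrix.variants],
            "REF": [v.ref for v in self.matrix.variants],
            "ALT": [v.alt for v in self.matrix.variants],
        }
        df = pd.DataFrame(rows)
        feat = pd.DataFrame(self.matrix.values, columns=self.matrix.manifest.names)
        df = pd.concat([df, feat], axis=1)
        df["label"] = self.labels
        df["provenance"] = self.provenance
        if self.meta is not None:
            for col in self.meta.columns:
                df[f"meta_{col}"] = self.meta[col].to_numpy()
        return df


@dataclass
class ExclusionList:
    """Named set of variant keys to subtract (a tool's training set)."""

    name: str
    keys: set[tuple]

    @classmethod
    def from_variants(cls, name: str, variants: Iterable[VariantKey]) -> "ExclusionList":
        return cls(name, {v.site for v in variants})


def _require_column(records: pd.DataFrame, column: str) -> pd.Series:
    if column not in records.columns:
        raise KeyError(f"records lack required column {column!r}")
    return records[column]


def _keys_from_frame(records: pd.DataFrame, mask) -> set[tuple]:
    sel = records.loc[mask]
    return {
        (normalize_chrom(str(c)), int(p), str(r), str(a))
        for c, p, r, a in zip(sel["CHROM"], sel["POS"], sel["REF"], sel["ALT"])
    }


def select_clinvar_positives(records: pd.DataFrame) -> set[tuple]:
    """High-confidence pathogenic selection from ClinVar-style records.

    Keeps variants whose CLNSIG is exactly ``Pathogenic`` (not
    Likely_pathogenic, not combined assertions) with a review status
    containing one of the multi-submitter / expert-panel / practice-guideline
    terms and no conflicting-interpretation flag.
    """
    clnsig = _require_column(records, "CLNSIG").astype(str)
    revstat = _require_column(records, "CLNREVSTAT").astype(str)
    sig_ok = clnsig == "Pathogenic"
    rev_ok = revstat.map(
        lambda s: any(term in s for term in HIGH_CONFIDENCE_REVIEW)
        and _CONFLICT_TERM not in s.lower()
    )
    return _keys_from_frame(records, sig_ok & rev_ok)


def select_hgmd_positives(records: pd.DataFrame) -> set[tuple]:
    """Curated disease-mutation selection: STATUS exactly ``DM`` (``DM?`` excluded)."""
    if len(records) == 0:
        return set()
    status = _require_column(records, "STATUS").astype(str)
    return _keys_from_frame(records, status == "DM")


def select_population_negatives(
    records: pd.DataFrame,
    maf_max: float = 0.01,
    min_depth: float = 30,
    exclusion: set[tuple] | None = None,
) -> set[tuple]:
    """Rare-benign selection from population-database records.

    Keeps variants with global MAF strictly below ``maf_max`` (default 1 %),
    depth strictly above ``min_depth`` (default 30X), and not present in
    ``exclusion`` (the merged positive-source keys).  Both inequalities are
    strict: MAF exactly 1 % or depth exactly 30 are dropped.
    """
    exclusion = exclusion or set()
    maf = pd.to_numeric(_require_column(records, "MAF"))
    depth = pd.to_numeric(_require_column(records, "DP"))
    keys = _keys_from_frame(records, (maf < maf_max) & (depth > min_depth))
    return keys - exclusion


def apply_circularity_filter(
    keys: set[tuple], exclusions: Sequence[ExclusionList]
) -> tuple[set[tuple], dict[str, int]]:
    """Remove keys present in any component predictor's training set.

    Returns the surviving keys and a per-list count of removals (a key
    present in several lists is counted in each).
    """
    removed_counts: dict[str, int] = {}
    union: set[tuple] = set()
    for excl in exclusions:
        removed_counts[excl.name] = len(keys & excl.keys)
        union |= excl.keys
    return keys - union, removed_counts


def balance_and_split(
    pos: LabeledDataset,
    neg_pool: LabeledDataset,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Subsample negatives to the positive count, then split each class.

    Negatives are drawn without replacement from ``neg_pool`` to exactly
    match the positive count; each class is then partitioned into train and
    test with ``floor(n * train_fraction)`` training variants.  Fully
    deterministic under ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_pos = len(pos)
    if len(neg_pool) < n_pos:
        raise ValueError(
            f"insufficient negatives: need {n_pos}, pool has {len(neg_pool)}"
        )
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(neg_pool), size=n_pos, replace=False)
    neg = neg_pool.take(np.sort(neg_idx))

    n_train = int(np.floor(n_pos * train_fraction))
    perm_pos = rng.permutation(n_pos)
    perm_neg = rng.permutation(n_pos)

    def _merge(a: LabeledDataset, b: LabeledDataset) -> LabeledDataset:
        from .features import FeatureMatrix as FM

        matrix = FM(
            a.matrix.variants + b.matrix.variants,
            a.matrix.manifest,
            np.vstack([a.matrix.values, b.matrix.values]),
            np.vstack([a.matrix.coverage, b.matrix.coverage]),
        )
        meta = None
        if a.meta is not None and b.meta is not None:
            meta = pd.concat([a.meta, b.meta], ignore_index=True)
        return LabeledDataset(
            matrix,
            np.concatenate([a.labels, b.labels]),
            a.provenance + b.provenance,
            meta,
        )

    train = _merge(pos.take(perm_pos[:n_train]), neg.take(perm_neg[:n_train]))
    test = _merge(pos.take(perm_pos[n_train:]), neg.take(perm_neg[n_train:]))
    return train, test


def maf_bin_subsets(
    benign: LabeledDataset, bins: Sequence[str] = MAF_BINS
) -> dict[str, LabeledDataset]:
    """Partition a benign set into nested rarity bins.

    Threshold bins (``"<0.01"`` etc.) select variants with global MAF
    strictly below the threshold; the ``"singleton"`` bin selects variants
    with allele count exactly 1.  Requires ``meta`` columns ``MAF`` and,
    for the singleton bin, ``AC``.
    """
    if benign.meta is None or "MAF" not in benign.meta.columns:
        raise KeyError("benign dataset lacks a MAF meta column")
    maf = pd.to_numeric(benign.meta["MAF"]).to_numpy()
    out: dict[str, LabeledDataset] = {}
    for b in bins:
        if b == "singleton":
            if "AC" not in benign.meta.columns:
                raise KeyError("singleton bin requested but meta lacks an AC column")
            mask = pd.to_numeric(benign.meta["AC"]).to_numpy() == 1
        else:
            if not b.startswith("<"):
                raise ValueError(f"unrecognised bin spec {b!r}")
            mask = maf < float(b[1:])
        out[b] = benign.take(np.flatnonzero(mask))
    return out


def write_dataset_table(ds: LabeledDataset, path) -> None:
    ds.to_table().to_csv(path, sep="\t", index=False)


def dataset_from_table(df: pd.DataFrame, manifest) -> LabeledDataset:
    """Rebuild a fully covered LabeledDataset from a flattened table."""
    from .features import FeatureMatrix, VariantKey

    missing = [n for n in manifest.names if n not in df.columns]
    if missing:
        raise KeyError(f"table lacks feature columns: {missing}")
    variants = [
        VariantKey(str(c), int(p), str(r), str(a))
        for c, p, r, a in zip(df["CHROM"], df["POS"], df["REF"], df["ALT"])
    ]
    values = df[manifest.names].to_numpy(dtype=float)
    matrix = FeatureMatrix(variants, manifest, values, np.ones_like(values, dtype=bool))
    labels = df["label"].to_numpy(dtype=int) if "label" in df.columns else np.zeros(len(df), int)
    prov = (
        df["provenance"].astype(str).tolist()
        if "provenance" in df.columns
        else ["table"] * len(df)
    )
    meta_cols = [c for c in df.columns if c.startswith("meta_")]
    meta = None
    if meta_cols:
        meta = df[meta_cols].rename(columns=lambda c: c[len("meta_"):]).reset_index(drop=True)
    return LabeledDataset(matrix, labels, prov, meta)


def read_dataset_table(path, manifest) -> LabeledDataset:
    return dataset_from_table(pd.read_csv(path, sep="\t", dtype={"CHROM": str}), manifest)


# ---------------------------------------------------------------------------
# Exclusion-list text I/O (one chrom:pos:ref:alt per line)

def read_exclusion_list(path, name: str | None = None) -> ExclusionList:
    keys: set[tuple] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split(":")
            keys.add((normalize_chrom(chrom), int(pos), ref, alt))
    return ExclusionList(name or str(path), keys)


def write_exclusion_list(excl: ExclusionList, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, ref, alt in sorted(excl.keys):
            fh.write(f"{chrom}:{pos}:{ref}:{alt}\n")
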