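"""Feature taxonomy for missense-variant classification.

A missense variant is described by four categories of features:

* **MAF** — minor allele frequencies in six populations (global plus five
  continental groups).  Deleterious Mendelian variants are expected to be
  rare or absent from population databases, so low or missing frequency is
  itself informative.
* **conservation** — site-level evolutionary conservation scores
  (PhastCons and PhyloP at three phylogenetic depths, SiPhy, GERP++).
* **functional** — regional constraint scores (CCRS, MPC) and 90
  amino-acid substitution features read out of AAindex-style 20x20
  physicochemical property matrices.
* **predictor** — scores of seven upstream deleteriousness predictors,
  consumed as plain numeric columns.

The default manifest has 113 features: 6 MAF + 8 conservation +
92 functional (CCRS, MPC, 90 AAindex) + 7 predictors.  Manifest order is
significant: it defines the column order of every feature matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "CATEGORIES",
    "MAF_POPULATIONS",
    "VariantKey",
    "FeatureSpec",
    "FeatureManifest",
    "AAindexMatrix",
    "FeatureMatrix",
    "default_manifest",
    "aaindex_substitution_value",
    "validate_manifest",
    "read_aaindex_flat",
    "write_manifest",
    "read_manifest",
]

#: Standard amino acids in fixed alphabetical one-letter order.  This order
#: is used for matrix serialization and is never inferred from input files.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CATEGORIES = ("MAF", "conservation", "functional", "predictor")

#: Population codes admissible for MAF features.  The default manifest uses
#: six of these (ASJ and FIN are part of the taxonomy but were pruned from
#: the default feature set during feature selection).
MAF_POPULATIONS = ("global", "AFR", "AMR", "ASJ", "EAS", "FIN", "NFE", "SAS")

_AA_SET = frozenset(AMINO_ACIDS)


class UnknownAminoAcidError(ValueError):
    """Raised when a residue letter is not one of the 20 standard amino acids."""


@dataclass(frozen=True)
class VariantKey:
    """Genomic identity of a missense variant.

    ``(chrom, pos, ref, alt)`` uniquely identifies the variant within any
    one set; the amino-acid substitution and gene symbol are optional
    annotations carried along for substitution-matrix features.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_aa: str | None = None
    alt_aa: str | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref!r}")
        if self.ref_aa is not None and self.alt_aa is not None:
            if self.ref_aa == self.alt_aa:
                raise ValueError(
                    f"synonymous substitution {self.ref_aa}->{self.alt_aa} "
                    "is not missense"
                )

    @property
    def site(self) -> tuple[str, int, str, str]:
        """The ``(chrom, pos, ref, alt)`` identity tuple, chr-prefix stripped."""
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so b37 and hg19 dialects compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class FeatureSpec:
    """One feature definition: a name, its category, and where values come from.

    ``source_column`` is the column name to look up in annotation tables, or
    the AAindex matrix identifier for substitution features.  ``population``
    is nonempty exactly for MAF features.
    """

    name: str
    category: str
    population: str = ""
    source_column: str = ""

    @property
    def is_aaindex(self) -> bool:
        return self.category == "functional" and self.source_column.startswith("aaindex:")

    @property
    def aaindex_id(self) -> str:
        if not self.is_aaindex:
            raise ValueError(f"{self.name} is not an AAindex feature")
        return self.source_column.split(":", 1)[1]


@dataclass
class FeatureManifest:
    """Ordered list of feature definitions; order defines matrix columns."""

    features: list[FeatureSpec]
    version: str = "default"

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.category] = counts.get(f.category, 0) + 1
        return counts

    def aaindex_ids(self) -> list[str]:
        return [f.aaindex_id for f in self.features if f.is_aaindex]

    def subset(self, names: Iterable[str]) -> "FeatureManifest":
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise KeyError(f"features not in manifest: {sorted(missing)}")
        return FeatureManifest(
            [f for f in self.features if f.name in wanted],
            version=f"{self.version}/subset",
        )


@dataclass
class AAindexMatrix:
    """A 20x20 real-valued amino-acid substitution property matrix."""

    id: str
    values: np.ndarray  # (20, 20), rows=ref, cols=alt, AMINO_ACIDS order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError(
                f"matrix {self.id}: expected 20x20, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"matrix {self.id}: non-finite entries")


def _aa_index(aa: str) -> int:
    if not isinstance(aa, str) or len(aa) != 1 or aa not in _AA_SET:
        raise UnknownAminoAcidError(
            f"unknown amino-acid letter {aa!r}; expected one of {AMINO_ACIDS}"
        )
    return AMINO_ACIDS.index(aa)


def aaindex_substitution_value(matrix: AAindexMatrix, ref_aa: str, alt_aa: str) -> float:
    """Look up the substitution property value for ``ref_aa -> alt_aa``.

    Both residues must be standard amino acids and must differ (a
    same-residue substitution is synonymous, not missense).
    """
    i = _aa_index(ref_aa)
    j = _aa_index(alt_aa)
    if ref_aa == alt_aa:
        raise ValueError(
            f"substitution {ref_aa}->{alt_aa} is synonymous, not missense"
        )
    return float(matrix.values[i, j])


@dataclass
class FeatureMatrix:
    """Per-variant feature values with an annotation-coverage mask.

    ``values[i, j]`` is the value of manifest feature ``j`` for variant
    ``i``; it is only meaningful where ``coverage[i, j]`` is True.
    """

    variants: list[VariantKey]
    manifest: FeatureManifest
    values: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=bool)
        n, m = len(self.variants), len(self.manifest)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} != ({n} variants, {m} features)"
            )
        if self.coverage.shape != (n, m):
            raise ValueError(
                f"coverage shape {self.coverage.shape} != ({n}, {m})"
            )
        if not np.all(np.isfinite(self.values[self.coverage])):
            raise ValueError("non-finite values under covered entries")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def n_features(self) -> int:
        return len(self.manifest)

    def fully_covered_mask(self) -> np.ndarray:
        if len(self.variants) == 0:
            return np.zeros(0, dtype=bool)
        return self.coverage.all(axis=1)

    def take(self, row_idx: np.ndarray) -> "FeatureMatrix":
        row_idx = np.asarray(row_idx)
        return FeatureMatrix(
            [self.variants[i] for i in row_idx],
            self.manifest,
            self.values[row_idx],
            self.coverage[row_idx],
        )

    def column_values(self, names: Iterable[str]) -> np.ndarray:
        """Dense value block for the named features, in the order given."""
        idx = [self.manifest.names.index(n) for n in names]
        return self.values[:, idx]


# ---------------------------------------------------------------------------
# Default manifest

_CONSERVATION = [
    ("phastcons_vertebrate", "phastCons100way_vertebrate"),
    ("phastcons_mammalian", "phastCons30way_mammalian"),
    ("phastcons_primate", "phastCons17way_primate"),
    ("phylop_vertebrate", "phyloP100way_vertebrate"),
    ("phylop_mammalian", "phyloP30way_mammalian"),
    ("phylop_primate", "phyloP17way_primate"),
    ("siphy_29way_logodds", "SiPhy_29way_logOdds"),
    ("gerp_rs", "GERP++_RS"),
]

_PREDICTORS = [
    ("sift", "SIFT_score"),
    ("polyphen2", "Polyphen2_score"),
    ("vest4", "VEST4_score"),
    ("condel", "Condel_score"),
    ("cadd_phred", "CADD_PHRED"),
    ("metalr", "MetaLR_score"),
    ("metasvm", "MetaSVM_score"),
]

#: Populations retained in the default manifest (ASJ and FIN pruned).
DEFAULT_MAF_POPULATIONS = ("global", "AFR", "AMR", "EAS", "NFE", "SAS")

#: Identifiers of the 90 AAindex matrix slots shipped by default.  The slot
#: ids are placeholders (``AAX001``..``AAX090``); any AAindex-format flat
#: file can rebind them to real matrix accessions via ``aaindex_ids=``.
DEFAULT_AAINDEX_IDS = tuple(f"AAX{i:03d}" for i in range(1, 91))


def default_manifest(aaindex_ids: Iterable[str] | None = None) -> FeatureManifest:
    """Build the default 113-feature manifest.

    Counts per category: 6 MAF (global, AFR, AMR, EAS, NFE, SAS),
    8 conservation, 92 functional (CCRS + MPC + 90 AAindex), 7 predictors.

    Parameters
    ----------
    aaindex_ids
        Optional replacement identifiers for the 90 AAindex matrix slots
        (must be exactly 90 unique ids).
    """
    ids = tuple(aaindex_ids) if aaindex_ids is not None else DEFAULT_AAINDEX_IDS
    if len(ids) != 90 or len(set(ids)) != 90:
        raise ValueError(f"need exactly 90 unique AAindex ids, got {len(ids)}")

    features: list[FeatureSpec] = []
    for pop in DEFAULT_MAF_POPULATIONS:
        col = "MAF" if pop == "global" else f"MAF_{pop}"
        features.append(FeatureSpec(f"maf_{pop.lower()}", "MAF", pop, col))
    for name, col in _CONSERVATION:
        features.append(FeatureSpec(name, "conservation", "", col))
    features.append(FeatureSpec("ccrs", "functional", "", "CCRS"))
    features.append(FeatureSpec("mpc", "functional", "", "MPC"))
    for mid in ids:
        features.append(FeatureSpec(f"aaindex_{mid}", "functional", "", f"aaindex:{mid}"))
    for name, col in _PREDICTORS:
        features.append(FeatureSpec(name, "predictor", "", col))
    return FeatureManifest(features, version="default-113")


def validate_manifest(manifest: FeatureManifest) -> list[str]:
    """Return a list of violation messages; empty iff the manifest is valid."""
    violations: list[str] = []
    seen: set[str] = set()
    for f in manifest.features:
        if f.name in seen:
            violations.append(f"duplicate name: {f.name}")
        seen.add(f.name)
        if f.category not in CATEGORIES:
            violations.append(f"unknown category {f.category!r} on feature {f.name}")
        if f.category == "MAF" and not f.population:
            violations.append(f"MAF feature {f.name} lacks a population code")
        if f.category == "MAF" and f.population and f.population not in MAF_POPULATIONS:
            violations.append(
                f"MAF feature {f.name} has unknown population {f.population!r}"
            )
        if f.category != "MAF" and f.population:
            violations.append(
                f"non-MAF feature {f.name} carries population {f.population!r}"
            )
    return violations


# ---------------------------------------------------------------------------
# AAindex flat-file I/O

def read_aaindex_flat(path) -> dict[str, AAindexMatrix]:
    """Read AAindex-style matrix blocks from a flat text file.

    Each block starts with an ``H <identifier>`` line, followed by an
    ``M rows = <order>`` line naming the amino-acid order, then 20 rows of
    numbers — either full 20-column rows or a lower triangle (row *i* has
    *i*+1 values), which is mirrored to a full symmetric matrix.  Blocks
    end with ``//``.
    """
    matrices: dict[str, AAindexMatrix] = {}
    with open(path) as fh:
        block_id: str | None = None
        order: str = AMINO_ACIDS
        rows: list[list[float]] = []
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("H "):
                block_id = line[2:].strip()
                rows = []
                order = AMINO_ACIDS
            elif line.startswith("M "):
                m = re.search(r"rows\s*=\s*([A-Z]+)", line)
                if m:
                    order = m.group(1)
                    if sorted(order) != sorted(AMINO_ACIDS):
                        raise ValueError(
                            f"matrix {block_id}: row order {order!r} is not a "
                            "permutation of the 20 standard amino acids"
                        )
            elif line.strip() == "//":
                if block_id is None:
                    raise ValueError("matrix block terminator without a header")
                matrices[block_id] = _assemble_matrix(block_id, order, rows)
                block_id = None
            elif line.strip() and block_id is not None:
                rows.append([float(tok) for tok in line.split()])
        if block_id is not None:
            matrices[block_id] = _assemble_matrix(block_id, order, rows)
    return matrices


def _assemble_matrix(block_id: str, order: str, rows: list[list[float]]) -> AAindexMatrix:
    if len(rows) != 20:
        raise ValueError(f"matrix {block_id}: expected 20 rows, got {len(rows)}")
    lengths = [len(r) for r in rows]
    full = np.empty((20, 20), dtype=float)
    if lengths == [i + 1 for i in range(20)]:
        # lower triangle: mirror to symmetric
        for i, r in enumerate(rows):
            for j, v in enumerate(r):
                full[i, j] = v
                full[j, i] = v
    elif all(l == 20 for l in lengths):
        full[:] = rows
    else:
        raise ValueError(
            f"matrix {block_id}: rows are neither full 20-column nor lower-triangle"
        )
    # reorder into canonical AMINO_ACIDS order
    perm = [order.index(a) for a in AMINO_ACIDS]
    full = full[np.ix_(perm, perm)]
    return AAindexMatrix(block_id, full)


def write_aaindex_flat(matrices: Mapping[str, AAindexMatrix] | Iterable[AAindexMatrix], path) -> None:
    """Write matrices as full 20x20 blocks in canonical residue order."""
    if isinstance(matrices, Mapping):
        matrices = list(matrices.values())
    with open(path, "w") as fh:
        for m in matrices:
            fh.write(f"H {m.id}\n")
            fh.write(f"M rows = {AMINO_ACIDS}, cols = {AMINO_ACIDS}\n")
            for row in m.values:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Manifest I/O (columnar text)

_MANIFEST_HEADER = "name\tcategory\tpopulation\tsource_column"


def write_manifest(manifest: FeatureManifest, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest version: {manifest.version}\n")
        fh.write(_MANIFEST_HEADER + "\n")
        for f in manifest.features:
            fh.write(f"{f.name}\t{f.category}\t{f.population}\t{f.source_column}\n")


def read_manifest(path) -> FeatureManifest:
    version = "unknown"
    features: list[FeatureSpec] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                m = re.search(r"version:\s*(.+)", line)
                if m:
                    version = m.group(1).strip()
                continue
            if not line or line == _MANIFEST_HEADER:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"malformed manifest line: {line!r}")
            features.append(FeatureSpec(*parts))
    return FeatureManifest(features, version=version)
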