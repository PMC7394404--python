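"""Spike-in disease-exome simulation and causative-variant ranking.

A simulated Mendelian disease exome is a healthy individual's background
missense variants plus one known deleterious ("causative") variant.  After
the community-standard clinical filters (depth > 10X, MAF < 1 % in control
populations, circularity exclusions), the classifier scores every variant
and the exome is judged on two axes:

* how short the deleterious shortlist is (``percent_deleterious``), and
* where the causative variant lands when variants are sorted by score
  (``causative_rank`` — rank 1 is best).

Ranks use optimistic competition ranking by default: the rank is one plus
the number of variants scoring strictly higher, so tied variants share the
best rank.  Rank distributions of two tools are compared with a two-sided
Mann-Whitney test (exact permutation enumeration for small samples, normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .features import VariantKey, normalize_chrom

__all__ = [
    "SimulatedExome",
    "RankingResult",
    "apply_exome_filters",
    "choose_causative",
    "spike_causative",
    "rank_causative",
    "summarize_rankings",
    "compare_rank_distributions",
    "write_ranking_report",
]

KEY_COLUMNS = ["CHROM", "POS", "REF", "ALT"]


def _site_index(df: pd.DataFrame) -> pd.Index:
    return pd.Index(
        zip(
            df["CHROM"].astype(str).map(normalize_chrom),
            df["POS"].astype(int),
            df["REF"],
            df["ALT"],
        )
    )


@dataclass
class SimulatedExome:
    """One spiked exome: the variant table plus the causative's identity.

    ``variants`` holds the background and the causative (present exactly
    once) with at least the key columns; a ``score`` column is added when
    the exome is scored.
    """

    variants: pd.DataFrame
    causative: tuple
    filters_applied: dict = field(default_factory=dict)
    exome_id: str = "exome"

    def __post_init__(self) -> None:
        hits = (_site_index(self.variants) == self.causative).sum()
        if hits != 1:
            raise ValueError(
                f"causative {self.causative} present {hits} times; expected exactly 1"
            )


@dataclass(frozen=True)
class RankingResult:
    exome_id: str
    causative_rank: int
    n_variants: int
    percent_deleterious: float

    def __post_init__(self) -> None:
        if not 1 <= self.causative_rank <= self.n_variants:
            raise ValueError(
                f"rank {self.causative_rank} outside [1, {self.n_variants}]"
            )
        if not 0 <= self.percent_deleterious <= 100:
            raise ValueError("percent_deleterious outside [0, 100]")


def apply_exome_filters(
    variants: pd.DataFrame,
    min_depth: float = 10,
    maf_max: float = 0.01,
    exclusions: set[tuple] | None = None,
) -> pd.DataFrame:
    """Clinical best-practice filters: depth strictly above ``min_depth``,
    MAF strictly below ``maf_max`` (a variant with no MAF annotation is
    novel/rare and passes), and not on any exclusion list."""
    depth = pd.to_numeric(variants["DP"])
    keep = depth > min_depth
    if "MAF" in variants.columns:
        maf = pd.to_numeric(variants["MAF"])
        keep &= maf.isna() | (maf < maf_max)
    if exclusions:
        keep &= ~_site_index(variants).isin(exclusions)
    out = variants.loc[keep.to_numpy()].reset_index(drop=True)
    return out


def choose_causative(pool: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Draw one causative variant from a deleterious pool, seeded."""
    if len(pool) == 0:
        raise ValueError("causative pool is empty")
    rng = np.random.default_rng(seed)
    return pool.iloc[int(rng.integers(len(pool)))]


def spike_causative(
    background: pd.DataFrame,
    causative: VariantKey | pd.Series,
    exome_id: str = "exome",
    filters_applied: dict | None = None,
) -> SimulatedExome:
    """Insert the causative variant into a background exome.

    The causative may be a :class:`VariantKey` or a table row; it must not
    already be present in the background.
    """
    if isinstance(causative, VariantKey):
        row = {"CHROM": causative.chrom, "POS": causative.pos,
               "REF": causative.ref, "ALT": causative.alt}
        key = causative.site
    else:
        row = causative.to_dict()
        key = (
            normalize_chrom(str(row["CHROM"])), int(row["POS"]),
            row["REF"], row["ALT"],
        )
    if (_site_index(background) == key).any():
        raise ValueError(f"causative {key} already present in background exome")
    variants = pd.concat([background, pd.DataFrame([row])], ignore_index=True)
    return SimulatedExome(variants, key, filters_applied or {}, exome_id)


def rank_causative(
    exome: SimulatedExome,
    threshold: float = 0.5,
    tie_policy: str = "optimistic",
) -> RankingResult:
    """Rank the causative variant within the scored exome.

    ``optimistic``: rank = 1 + number of variants scoring strictly higher
    (tied variants share the best rank).  ``pessimistic``: tied variants are
    counted ahead, so ties share the worst rank.
    """
    if "score" not in exome.variants.columns:
        raise ValueError("exome is not scored: no score column")
    scores = pd.to_numeric(exome.variants["score"])
    if scores.isna().any():
        raise ValueError(
            f"{int(scores.isna().sum())} variants lack a score; score the exome first"
        )
    s = scores.to_numpy(dtype=float)
    causative_pos = int(np.flatnonzero(_site_index(exome.variants) == exome.causative)[0])
    c_score = s[causative_pos]
    if tie_policy == "optimistic":
        rank = 1 + int((s > c_score).sum())
    elif tie_policy == "pessimistic":
        rank = int((s >= c_score).sum())
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    pct = 100.0 * float((s > threshold).sum()) / len(s)
    return RankingResult(exome.exome_id, rank, len(s), pct)


def summarize_rankings(results: list[RankingResult]) -> dict[str, float]:
    """Median/mean +- sd of causative ranks and of percent deleterious."""
    if not results:
        raise ValueError("no ranking results to summarize")
    ranks = np.array([r.causative_rank for r in results], dtype=float)
    pcts = np.array([r.percent_deleterious for r in results], dtype=float)

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    return {
        "n_exomes": len(results),
        "median_rank": float(np.median(ranks)),
        "mean_rank": float(np.mean(ranks)),
        "sd_rank": _sd(ranks),
        "mean_percent_deleterious": float(np.mean(pcts)),
        "sd_percent_deleterious": _sd(pcts),
    }


#: combined sample size up to which the exact permutation distribution of
#: the Mann-Whitney U statistic is enumerated
EXACT_MAX_N = 12


def compare_rank_distributions(ranksA, ranksB) -> float:
    """Two-sided Mann-Whitney p-value comparing two rank samples.

    For combined n <= 12 the permutation distribution of U is enumerated
    exhaustively (valid under ties); otherwise the normal approximation
    with tie correction is used.
    """
    a = np.asarray(ranksA, dtype=float)
    b = np.asarray(ranksB, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both rank samples must be nonempty")
    n1, n2 = len(a), len(b)
    if n1 + n2 <= EXACT_MAX_N:
        combined = np.concatenate([a, b])
        ranks = rankdata(combined)
        mu = n1 * n2 / 2.0
        obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        obs_dev = abs(obs_u - mu)
        count = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            if abs(u - mu) >= obs_dev - 1e-12:
                count += 1
        return count / comb(n1 + n2, n1)
    return float(mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


def simulate_spiked_exomes(
    model,
    n_exomes: int = 50,
    exome_size: int = 460,
    seed: int = 0,
    manifest=None,
    aaindex_set=None,
    causative_pool_size: int = 200,
    causative_effect_size: float = 3.0,
    min_depth: float = 10,
    maf_max: float = 0.01,
) -> list[RankingResult]:
    """Run the full spike-in study on synthetic exomes.

    Draws a pool of synthetic deleterious variants, then for each exome
    generates a benign background, applies the clinical filters
    (depth > ``min_depth``, MAF < ``maf_max``), scores all variants with
    ``model``, spikes one causative variant from the pool, and ranks it.
    Fully deterministic under ``seed``.
    """
    from .ensemble import predict_score
    from .features import default_manifest
    from .synthdata import (
        generate_background_exome,
        generate_labeled_features,
        synthetic_aaindex_set,
    )

    manifest = manifest or default_manifest()
    if aaindex_set is None:
        aaindex_set = synthetic_aaindex_set(manifest.aaindex_ids(), seed=seed)
    children = np.random.SeedSequence(seed).spawn(n_exomes + 1)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    pool_seed, exome_seeds = child_seeds[0], child_seeds[1:]

    pool = generate_labeled_features(
        causative_pool_size,
        manifest,
        effect_size=causative_effect_size,
        seed=pool_seed,
        aaindex_set=aaindex_set,
    )
    del_ds = pool.take(np.flatnonzero(pool.labels == 1))
    del_scores = predict_score(model, del_ds.matrix)

    results: list[RankingResult] = []
    for i, es in enumerate(exome_seeds):
        variants, benign = generate_background_exome(
            exome_size, manifest, seed=es, aaindex_set=aaindex_set
        )
        variants = variants.assign(_row=np.arange(len(variants)))
        filtered = apply_exome_filters(variants, min_depth=min_depth, maf_max=maf_max)
        sub = benign.take(filtered["_row"].to_numpy())
        scores = predict_score(model, sub.matrix)
        filtered = filtered.drop(columns="_row").assign(score=scores)

        rng = np.random.default_rng(np.random.SeedSequence([es, 7]))
        ci = int(rng.integers(len(del_ds)))
        cv = del_ds.matrix.variants[ci]
        causative = pd.Series(
            {
                "CHROM": cv.chrom,
                "POS": cv.pos,
                "REF": cv.ref,
                "ALT": cv.alt,
                "score": float(del_scores[ci]),
            }
        )
        exome = spike_causative(
            filtered,
            causative,
            exome_id=f"exome{i:03d}",
            filters_applied={"min_depth": min_depth, "maf_max": maf_max},
        )
        results.append(rank_causative(exome, threshold=model.threshold))
    return results


def write_ranking_report(results: list[RankingResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("exome_id\tcausative_rank\tn_variants\tpercent_deleterious\n")
        for r in results:
            fh.write(
                f"{r.exome_id}\t{r.causative_rank}\t{r.n_variants}\t"
                f"{r.percent_deleterious:.3f}\n"
            )
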