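"""Incidence-based beta diversity against a mock-community null model.

Between-experiment dissimilarity is the Jaccard dissimilarity of ASV
presence/absence at matched time categories (Before / After / Furthest
relative to the first H2 injection). Because two communities drawn from
different species pools are trivially dissimilar, each observed value is
normalized against a null distribution built by resampling: the two
experiments' total observed ASV sets (union over all their samples,
regardless of time) are pooled, mock communities are drawn uniformly
without replacement from the pool with richness matched to the two real
samples, and the Jaccard dissimilarities of mock pairs form the null.
The observed value is expressed as a z-score; z < -1.96 (outside the 95%
band, lower tail) marks a pair sharing more ASVs than random assembly
from their joint pool predicts -- taxonomic convergence.

A pair's three z-scores are classified into the four convergence
patterns: persistent (significant at all three categories), progressive
(not significant Before but significant Furthest), transient (significant
only After), or null-like.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._rng import child_rng
from .io import CATEGORIES, CommunityTable, ExperimentDesign, assign_timepoints

__all__ = [
    "PresenceSet",
    "NullDistribution",
    "BetaResult",
    "PatternLabel",
    "BiasCheck",
    "PairwiseBetaResult",
    "jaccard_dissimilarity",
    "build_null",
    "zscore",
    "classify_pattern",
    "pairwise_beta",
    "within_experiment_beta",
    "time_differential_bias_check",
    "pair_label",
]

PATTERNS = (
    "null_like",
    "persistent_convergence",
    "progressive_convergence",
    "transient_convergence",
)


@dataclass(frozen=True)
class PresenceSet:
    """ASVs present (count > 0) in the sample representing one category."""

    experiment_id: str
    category: str
    asv_ids: frozenset[str]
    day: int | None = None
    sample_id: str | None = None


def jaccard_dissimilarity(a: PresenceSet | Iterable[str], b: PresenceSet | Iterable[str]) -> float:
    """1 - |A intersect B| / |A union B| on presence sets; symmetric, in [0, 1]."""
    sa = frozenset(a.asv_ids if isinstance(a, PresenceSet) else a)
    sb = frozenset(b.asv_ids if isinstance(b, PresenceSet) else b)
    union = len(sa | sb)
    if union == 0:
        raise ValueError("Jaccard dissimilarity undefined for two empty sets")
    return 1.0 - len(sa & sb) / union


def pair_label(a: str, b: str) -> str:
    """Canonical unordered pair label, e.g. 'exp1~exp2'."""
    return "~".join(sorted((str(a), str(b))))


@dataclass
class NullDistribution:
    """Mock-pair Jaccard dissimilarities for one experiment pair (one category)."""

    pair: str
    draws: np.ndarray
    n_mock: int
    n_pairs: int
    seed: int | None
    richness_a: int
    richness_b: int
    pool_size: int

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1))

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0


def _draw_mock_matrix(rng: np.random.Generator, n: int, pool_size: int, k: int) -> np.ndarray:
    """n uniform without-replacement k-subsets of range(pool_size), as a bool matrix."""
    if k > pool_size:
        raise ValueError(f"mock richness {k} exceeds pool size {pool_size}")
    keys = rng.random((n, pool_size))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    out = np.zeros((n, pool_size), dtype=bool)
    np.put_along_axis(out, idx, True, axis=1)
    return out


def build_null(
    pool_a: Iterable[str],
    pool_b: Iterable[str],
    richness_a: int,
    richness_b: int,
    n_mock: int = 10_000,
    n_pairs: int = 1_000,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    richness_rule: str = "matched",
    pair: str = "",
) -> NullDistribution:
    """Null distribution of Jaccard dissimilarity for one experiment pair.

    The two experiments' total observed ASV sets are pooled (union,
    regardless of time). ``n_mock`` mock communities are conceptually drawn
    with richness alternately ``richness_a`` and ``richness_b`` and paired
    disjointly in order of drawing; only ``n_pairs`` pairs (the first
    ``2 * n_pairs`` draws) are materialized, surplus draws are discarded.
    Deterministic given ``seed``.

    ``richness_rule='matched'`` (default) matches each mock community's
    richness to the corresponding real sample; ``'uniform'`` draws each
    mock's richness uniformly between the two observed richness values.
    """
    pool = sorted(frozenset(pool_a) | frozenset(pool_b))
    pool_size = len(pool)
    if richness_a < 1 or richness_b < 1:
        raise ValueError("mock richness must be >= 1")
    if max(richness_a, richness_b) > pool_size:
        raise ValueError(
            f"richness ({richness_a}, {richness_b}) exceeds pooled ASV count {pool_size}"
        )
    if 2 * n_pairs > n_mock:
        raise ValueError(f"n_pairs={n_pairs} needs 2*n_pairs <= n_mock={n_mock}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if richness_rule == "matched":
        mocks_a = _draw_mock_matrix(rng, n_pairs, pool_size, richness_a)
        mocks_b = _draw_mock_matrix(rng, n_pairs, pool_size, richness_b)
    elif richness_rule == "uniform":
        lo, hi = min(richness_a, richness_b), max(richness_a, richness_b)
        sizes = rng.integers(lo, hi + 1, size=2 * n_pairs)
        rows = np.zeros((2 * n_pairs, pool_size), dtype=bool)
        keys = rng.random((2 * n_pairs, pool_size))
        order = np.argsort(keys, axis=1)
        for i, k in enumerate(sizes):
            rows[i, order[i, :k]] = True
        mocks_a, mocks_b = rows[0::2], rows[1::2]
    else:
        raise ValueError(f"unknown richness_rule {richness_rule!r}")
    inter = (mocks_a & mocks_b).sum(axis=1)
    union = (mocks_a | mocks_b).sum(axis=1)
    draws = 1.0 - inter / union
    return NullDistribution(
        pair, draws, n_mock, n_pairs, seed, richness_a, richness_b, pool_size
    )


@dataclass
class BetaResult:
    """Observed Jaccard dissimilarity and its z-score against the null."""

    pair: str
    category: str
    observed: float
    z: float  # NaN when the null is degenerate
    significant: bool  # |z| > threshold (strict)
    threshold: float = 1.96
    day_a: int | None = None
    day_b: int | None = None
    reason: str | None = None  # set when z is missing

    @property
    def convergent(self) -> bool:
        """Lower-tail call: dissimilarity below the null band (z < -threshold)."""
        return (not np.isnan(self.z)) and self.z < -self.threshold


def zscore(
    observed: float,
    null: NullDistribution,
    category: str = "",
    threshold: float = 1.96,
    day_a: int | None = None,
    day_b: int | None = None,
) -> BetaResult:
    """Center/scale an observed dissimilarity by the null mean and sd.

    Significance is two-sided at the 95% band (|z| > threshold, strict
    inequality); substantive convergence calls use the lower tail only.
    A degenerate null (sd = 0) yields a missing z with a reason code.
    """
    if null.degenerate:
        return BetaResult(
            null.pair, category, float(observed), float("nan"), False, threshold,
            day_a, day_b, reason="degenerate null (sd = 0)"
        )
    z = (float(observed) - null.mean) / null.sd
    return BetaResult(
        null.pair, category, float(observed), z, abs(z) > threshold, threshold, day_a, day_b
    )


@dataclass
class PatternLabel:
    """Convergence pattern for one experiment pair, from its three z-scores."""

    pair: str
    label: str
    partial: bool = False  # some category was missing
    atypical: bool = False  # significant Before without persisting -- outside
    #                         the four narrative cases, mapped to null_like


def classify_pattern(
    before: BetaResult | None,
    after: BetaResult | None,
    furthest: BetaResult | None,
    threshold: float = 1.96,
) -> PatternLabel:
    """Map a pair's (Before, After, Furthest) z-scores to one of four patterns.

    A category is "significant" when z < -threshold (lower tail: less
    dissimilar than the null). Precedence: persistent > progressive >
    transient > null_like.
    """
    results = [before, after, furthest]
    pair = next((r.pair for r in results if r is not None), "")

    def sig(r: BetaResult | None) -> bool:
        return r is not None and not np.isnan(r.z) and r.z < -threshold

    s_before, s_after, s_furthest = (sig(r) for r in results)
    partial = any(r is None or np.isnan(r.z) for r in results)
    if s_before and s_after and s_furthest:
        return PatternLabel(pair, "persistent_convergence", partial)
    if not s_before and s_furthest:
        return PatternLabel(pair, "progressive_convergence", partial)
    if not s_before and s_after and not s_furthest:
        return PatternLabel(pair, "transient_convergence", partial)
    return PatternLabel(pair, "null_like", partial, atypical=s_before)


@dataclass
class BiasCheck:
    """Spearman check of z against the day gap between the paired samples."""

    rho: float
    p_value: float
    n: int
    biased: bool
    note: str | None = None


def time_differential_bias_check(
    z_values: Sequence[float], day_gaps: Sequence[float], alpha: float = 0.05
) -> BiasCheck:
    """Spearman rank correlation between |day_a - day_b| and z (two-sided).

    Matched categories can sit at different absolute days in different
    experiments; a correlation between that time differential and the
    normalized dissimilarity would flag the category matching as biased.
    """
    z = np.asarray(z_values, dtype=float)
    g = np.asarray(day_gaps, dtype=float)
    keep = ~np.isnan(z) & ~np.isnan(g)
    z, g = z[keep], g[keep]
    if len(z) < 5:
        raise ValueError(f"need >= 5 (z, gap) pairs with defined values, got {len(z)}")
    if len(set(g)) == 1 or len(set(z)) == 1:
        return BiasCheck(float("nan"), float("nan"), len(z), False,
                         note="constant input: correlation undefined")
    rho, p = stats.spearmanr(g, z)
    return BiasCheck(float(rho), float(p), len(z), bool(p <= alpha))


# ---------------------------------------------------------------------------
# orchestration over experiment tables


@dataclass
class PairwiseBetaResult:
    """All between-experiment results: per-(pair, category) z plus patterns."""

    results: list[BetaResult]
    patterns: dict[str, PatternLabel]
    nulls: dict[tuple[str, str], NullDistribution] = field(default_factory=dict)

    def bias_check(self, alpha: float = 0.05) -> BiasCheck:
        zs = [r.z for r in self.results]
        gaps = [
            abs(r.day_a - r.day_b) if r.day_a is not None and r.day_b is not None else np.nan
            for r in self.results
        ]
        return time_differential_bias_check(zs, gaps, alpha=alpha)


def _category_presence(
    table: CommunityTable, design: ExperimentDesign
) -> dict[str, PresenceSet]:
    out = {}
    for tp in assign_timepoints(table, design):
        out[tp.category] = PresenceSet(
            table.experiment_id, tp.category, table.presence(tp.sample_id),
            tp.day, tp.sample_id
        )
    return out


def pairwise_beta(
    tables: Mapping[str, CommunityTable],
    designs: Mapping[str, ExperimentDesign],
    n_mock: int = 10_000,
    n_pairs: int = 1_000,
    seed: int = 0,
    threshold: float = 1.96,
    richness_rule: str = "matched",
    keep_nulls: bool = False,
) -> PairwiseBetaResult:
    """Between-experiment Jaccard + z for every unordered pair and category.

    One null distribution is built per (pair, category) because mock
    richness is matched to the two category samples; the pool is always the
    pair's time-pooled ASV union. Per-pair random streams are derived from
    the pair label, so adding an experiment never perturbs existing pairs.
    """
    exp_ids = sorted(tables)
    presence = {e: _category_presence(tables[e], designs[e]) for e in exp_ids}
    pools = {e: tables[e].total_pool() for e in exp_ids}
    results: list[BetaResult] = []
    patterns: dict[str, PatternLabel] = {}
    nulls: dict[tuple[str, str], NullDistribution] = {}
    for ea, eb in itertools.combinations(exp_ids, 2):
        label = pair_label(ea, eb)
        by_cat: dict[str, BetaResult] = {}
        for ci, cat in enumerate(CATEGORIES):
            pa, pb = presence[ea].get(cat), presence[eb].get(cat)
            if pa is None or pb is None or not pa.asv_ids or not pb.asv_ids:
                continue
            rng = child_rng(seed, "null", label, cat)
            null = build_null(
                pools[ea], pools[eb], len(pa.asv_ids), len(pb.asv_ids),
                n_mock=n_mock, n_pairs=n_pairs, rng=rng,
                richness_rule=richness_rule, pair=label,
            )
            obs = jaccard_dissimilarity(pa, pb)
            res = zscore(obs, null, cat, threshold, pa.day, pb.day)
            by_cat[cat] = res
            results.append(res)
            if keep_nulls:
                nulls[(label, cat)] = null
        patterns[label] = classify_pattern(
            by_cat.get("Before"), by_cat.get("After"), by_cat.get("Furthest"), threshold
        )
    return PairwiseBetaResult(results, patterns, nulls)


def within_experiment_beta(
    table: CommunityTable,
    n_mock: int = 10_000,
    n_pairs: int = 1_000,
    seed: int = 0,
    threshold: float = 1.96,
    mode: str = "consecutive",
) -> list[BetaResult]:
    """Jaccard + z for sample pairs within one experiment.

    The null for each sample pair is built from the experiment's own
    time-pooled ASV set with mock richness matched to the two samples.
    ``mode='consecutive'`` (default) compares successive samples in day
    order; ``'all'`` compares every sample pair.
    """
    ordered = table.sorted_by_day()
    sids = ordered.sample_ids
    if len(sids) < 2:
        return []
    if mode == "consecutive":
        index_pairs = [(i, i + 1) for i in range(len(sids) - 1)]
    elif mode == "all":
        index_pairs = list(itertools.combinations(range(len(sids)), 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pool = ordered.total_pool()
    results = []
    for i, j in index_pairs:
        sa, sb = sids[i], sids[j]
        pa, pb = ordered.presence(sa), ordered.presence(sb)
        if not pa or not pb:
            continue
        rng = child_rng(seed, "within", table.experiment_id, sa, sb)
        null = build_null(
            pool, pool, len(pa), len(pb), n_mock=n_mock, n_pairs=n_pairs,
            rng=rng, pair=pair_label(sa, sb),
        )
        obs = jaccard_dissimilarity(pa, pb)
        results.append(
            zscore(obs, null, "Within", threshold, int(ordered.day[sa]), int(ordered.day[sb]))
        )
    return results
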