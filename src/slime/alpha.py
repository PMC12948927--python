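"""Per-sample alpha diversity: richness, Stoddart, Shannon, Pielou.

The Stoddart index is the reciprocal of Simpson's concentration,
``1 / sum_i p_i**2`` (Stoddart & Taylor's genotypic diversity) -- the
standard reading of "an analog of the Simpson index". It equals the
effective number of equally-abundant taxa, so it corrects apparent ASV
richness for dominance. A Gini-Simpson variant (``1 - sum p**2``) is
available for sensitivity analyses. Shannon uses the natural logarithm so
that Pielou evenness is exactly ``H / ln(S)``.

Indices are computed on counts as given (fixed sequencing depth upstream);
all are invariant to rescaling a sample's counts by a positive factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CommunityTable, ExperimentDesign

__all__ = ["richness", "stoddart", "shannon", "pielou", "alpha_trajectory", "AlphaSeries"]

INDEX_NAMES = ("richness", "stoddart", "shannon", "pielou")


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector of counts for one sample")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return arr


def _proportions(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero sample: relative abundances undefined")
    return counts[counts > 0] / total


def richness(counts) -> int:
    """Number of ASVs with count > 0."""
    arr = _as_counts(counts)
    s = int((arr > 0).sum())
    if s == 0:
        warnings.warn("all-zero sample: richness is 0", stacklevel=2)
    return s


def stoddart(counts, variant: str = "inverse") -> float:
    """Inverse Simpson concentration 1 / sum(p^2) (or Gini-Simpson 1 - sum(p^2))."""
    p = _proportions(_as_counts(counts))
    concentration = float(np.sum(p * p))
    if variant == "inverse":
        return 1.0 / concentration
    if variant == "gini":
        return 1.0 - concentration
    raise ValueError(f"unknown variant {variant!r} (expected 'inverse' or 'gini')")


def shannon(counts) -> float:
    """Shannon entropy -sum(p ln p), natural log."""
    p = _proportions(_as_counts(counts))
    return float(-np.sum(p * np.log(p)))


def pielou(counts) -> float:
    """Evenness H / ln(S); NaN (reported missing) when S < 2."""
    arr = _as_counts(counts)
    s = int((arr > 0).sum())
    if s == 0:
        raise ValueError("all-zero sample: Pielou undefined")
    if s == 1:
        return float("nan")
    return shannon(arr) / float(np.log(s))


_FUNCS = {"richness": richness, "stoddart": stoddart, "shannon": shannon, "pielou": pielou}


@dataclass
class AlphaSeries:
    """One index's trajectory through an experiment, ordered by day."""

    experiment_id: str
    index_name: str
    days: np.ndarray
    values: np.ndarray
    injection_days: tuple[int, ...] = ()
    refill_days: tuple[int, ...] = ()


def alpha_trajectory(
    table: CommunityTable,
    index_name: str,
    design: ExperimentDesign | None = None,
) -> AlphaSeries:
    """One index value per sample, ordered by day.

    Injection and refill days from ``design`` are passed through for
    plotting/reporting; they do not affect the values.
    """
    if index_name not in _FUNCS:
        raise ValueError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    func = _FUNCS[index_name]
    ordered = table.sorted_by_day()
    days = ordered.day.to_numpy()
    values = np.array(
        [func(ordered.counts.loc[sid].to_numpy()) for sid in ordered.sample_ids], dtype=float
    )
    return AlphaSeries(
        table.experiment_id,
        index_name,
        days,
        values,
        design.injection_days if design else (),
        design.refill_days if design else (),
    )
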