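"""Pairwise association statistics: the ratiometric measure and its baselines.

The ratiometric association (RA) between two genes A and B is built from the
coefficient of variation (CV = sd / mean) of the two per-sample expression
ratios A/B and B/A.  When the pair follows ``a_i ≈ c · b_i`` both ratios are
nearly constant, both CVs are small, and they are nearly equal.  Two derived
quantities summarise this:

* ``delta_cv = |CV(A/B) - CV(B/A)|`` — the stringency of fit.  A pair is
  called *ratiometric* when ``delta_cv`` falls below a gate (default 0.01
  for bulk panels, 0.025 for noisier single-cell data).
* *stability* — the magnitude of the two CVs (default: their maximum),
  used to rank gate-passing pairs; smaller is stronger.

Baselines computed alongside: Pearson r and R², squared Spearman rank
correlation, and a plug-in mutual information on equal-frequency bins
(default 4 bins, log base 2, so the statistic lives in [0, 2] bits).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "MeasureConfig",
    "PairMeasure",
    "InsufficientDataError",
    "DegenerateInputError",
    "cv_ratio",
    "delta_cv",
    "is_ratiometric",
    "pearson_association",
    "spearman_association",
    "equal_frequency_bins",
    "mutual_information",
    "pair_measures",
]


class InsufficientDataError(ValueError):
    """Too few usable samples to evaluate a statistic."""


class DegenerateInputError(ValueError):
    """Constant or otherwise degenerate input for a statistic."""


@dataclass(frozen=True)
class MeasureConfig:
    """Settings shared by all pairwise statistics.

    Parameters
    ----------
    delta_cv_threshold
        Gate on ``|CV(A/B) - CV(B/A)|`` below which a pair is called
        ratiometric.  0.01 for bulk panels; 0.025 recommended for
        single-cell data.
    stability_rule
        How CV(A/B) and CV(B/A) combine into one stability scalar:
        ``"max"`` (conservative, default) or ``"mean"``.
    stability_bound
        Optional upper bound on the stability conjoined with the gate in
        :func:`is_ratiometric` (``None`` disables it).
    mi_bins
        Number of equal-frequency bins per margin for mutual information.
    cv_ddof
        Delta degrees of freedom for the standard deviation in the CV
        (1 = sample SD, default).
    min_used_fraction
        Minimum fraction of samples with strictly positive values in both
        genes for the ratio statistics to be evaluable.
    """

    delta_cv_threshold: float = 0.01
    stability_rule: Literal["max", "mean"] = "max"
    stability_bound: float | None = None
    mi_bins: int = 4
    cv_ddof: int = 1
    min_used_fraction: float = 0.95

    mi_log_base: int = 2  # fixed; exposed for provenance only

    def __post_init__(self) -> None:
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.delta_cv_threshold < 0:
            raise ValueError("delta_cv_threshold must be >= 0")
        if self.stability_rule not in ("max", "mean"):
            raise ValueError("stability_rule must be 'max' or 'mean'")
        if self.cv_ddof not in (0, 1):
            raise ValueError("cv_ddof must be 0 or 1")

    def for_single_cell(self) -> "MeasureConfig":
        """Copy with the single-cell gate (0.025)."""
        return replace(self, delta_cv_threshold=0.025)


@dataclass(frozen=True)
class PairMeasure:
    """All statistics for one unordered gene pair."""

    gene_a: str
    gene_b: str
    cv_ab: float
    cv_ba: float
    delta_cv: float
    mean_ab: float
    mean_ba: float
    pearson_r: float
    pearson_r2: float
    spearman_r2: float
    mi: float
    n_used: int
    ra_evaluable: bool = True

    def swapped(self) -> "PairMeasure":
        """The same pair with gene roles exchanged."""
        return PairMeasure(
            gene_a=self.gene_b,
            gene_b=self.gene_a,
            cv_ab=self.cv_ba,
            cv_ba=self.cv_ab,
            delta_cv=self.delta_cv,
            mean_ab=self.mean_ba,
            mean_ba=self.mean_ab,
            pearson_r=self.pearson_r,
            pearson_r2=self.pearson_r2,
            spearman_r2=self.spearman_r2,
            mi=self.mi,
            n_used=self.n_used,
            ra_evaluable=self.ra_evaluable,
        )


def _validate_pair(a: np.ndarray, b: np.ndarray, min_len: int = 3) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expression vectors must be 1-D and of equal length")
    if a.size < min_len:
        raise InsufficientDataError(f"need at least {min_len} samples, got {a.size}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("expression values must be non-negative")
    return a, b


# ---------------------------------------------------------------------------
# Ratiometric statistics
# ---------------------------------------------------------------------------

def cv_ratio(
    a: np.ndarray,
    b: np.ndarray,
    config: MeasureConfig = MeasureConfig(),
) -> tuple[float, float, float, float, int]:
    """CV and mean of the ratios A/B and B/A across samples.

    Samples where either gene is zero are excluded (the ratio is
    undefined there); if fewer than ``min_used_fraction`` of the samples
    remain, the pair is not evaluable and an
    :class:`InsufficientDataError` is raised.

    Returns ``(cv_ab, cv_ba, mean_ab, mean_ba, n_used)``.
    """
    a, b = _validate_pair(a, b)
    used = (a > 0) & (b > 0)
    n_used = int(used.sum())
    if n_used < 3 or n_used < config.min_used_fraction * a.size:
        raise InsufficientDataError(
            f"only {n_used}/{a.size} samples have positive values in both genes"
        )
    ratio_ab = a[used] / b[used]
    ratio_ba = b[used] / a[used]
    mean_ab = float(np.mean(ratio_ab))
    mean_ba = float(np.mean(ratio_ba))
    cv_ab = float(np.std(ratio_ab, ddof=config.cv_ddof) / mean_ab)
    cv_ba = float(np.std(ratio_ba, ddof=config.cv_ddof) / mean_ba)
    return cv_ab, cv_ba, mean_ab, mean_ba, n_used


def delta_cv(cv_ab: float, cv_ba: float) -> float:
    """Stringency of fit to a ratiometric relationship: ``|cv_ab - cv_ba|``.

    Order-invariant; 0 when the two ratio CVs agree exactly.
    """
    if cv_ab < 0 or cv_ba < 0:
        raise ValueError("CV values must be non-negative")
    return abs(cv_ab - cv_ba)


def stability(cv_ab: float, cv_ba: float, rule: str = "max") -> float:
    """Combine the two ratio CVs into a single stability scalar."""
    if rule == "max":
        return max(cv_ab, cv_ba)
    if rule == "mean":
        return 0.5 * (cv_ab + cv_ba)
    raise ValueError("rule must be 'max' or 'mean'")


def is_ratiometric(
    pm: PairMeasure,
    config: MeasureConfig = MeasureConfig(),
) -> tuple[bool, float]:
    """Gate a pair on delta_cv (and optionally a stability bound).

    Returns ``(flag, stability)``.  The flag requires
    ``delta_cv < delta_cv_threshold``; when ``config.stability_bound`` is
    set the stability must also be at or below that bound.  Smaller
    stability means a stronger ratiometric association.
    """
    if not pm.ra_evaluable:
        return False, float("nan")
    stab = stability(pm.cv_ab, pm.cv_ba, config.stability_rule)
    flag = pm.delta_cv < config.delta_cv_threshold
    if config.stability_bound is not None:
        flag = flag and stab <= config.stability_bound
    return flag, stab


# ---------------------------------------------------------------------------
# Baseline statistics
# ---------------------------------------------------------------------------

def pearson_association(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation r and its square."""
    a, b = _validate_pair(a, b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(a, b).statistic)
    return r, r * r


def spearman_association(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Spearman rank correlation (average ranks for ties)."""
    a, b = _validate_pair(a, b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("rank correlation undefined for a constant vector")
    rho = float(stats.spearmanr(a, b).statistic)
    return rho * rho


def equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` equal-frequency bins.

    Binning is by average rank, so tied values always share a bin; a tie
    group spanning a nominal boundary is placed in the lower bin.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("cannot bin a constant vector")
    # min-rank assignment sends a tie group spanning a boundary to the
    # lower bin; for distinct values it coincides with plain ranking.
    ranks = stats.rankdata(x, method="min")
    bins = np.ceil(ranks * n_bins / x.size).astype(int) - 1
    return np.clip(bins, 0, n_bins - 1)


def mutual_information(
    a: np.ndarray,
    b: np.ndarray,
    config: MeasureConfig = MeasureConfig(),
) -> float:
    """Plug-in mutual information of equal-frequency-binned vectors, in bits.

    Both margins are discretised into ``config.mi_bins`` equal-frequency
    bins and the joint bin histogram gives the plug-in estimate with log
    base 2, so the result lies in ``[0, log2(mi_bins)]`` (0–2 bits with
    the 4-bin default).
    """
    a, b = _validate_pair(a, b, min_len=config.mi_bins)
    bins_a = equal_frequency_bins(a, config.mi_bins)
    bins_b = equal_frequency_bins(b, config.mi_bins)
    joint = np.zeros((config.mi_bins, config.mi_bins))
    np.add.at(joint, (bins_a, bins_b), 1.0)
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI (bits) from a joint count table."""
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pa * pb))
    return float(np.nansum(terms))


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def pair_measures(
    a: np.ndarray,
    b: np.ndarray,
    config: MeasureConfig = MeasureConfig(),
    gene_a: str = "A",
    gene_b: str = "B",
) -> PairMeasure:
    """All statistics for one pair in a single record.

    The ratio statistics exclude zero samples; Pearson, Spearman and MI
    use all samples.  A pair with too many zeros is returned with
    ``ra_evaluable=False`` and NaN ratio fields rather than dropped.
    """
    a, b = _validate_pair(a, b)
    try:
        cv_ab, cv_ba, mean_ab, mean_ba, n_used = cv_ratio(a, b, config)
        dcv = delta_cv(cv_ab, cv_ba)
        evaluable = True
    except InsufficientDataError:
        cv_ab = cv_ba = dcv = mean_ab = mean_ba = float("nan")
        n_used = int(np.sum((a > 0) & (b > 0)))
        evaluable = False
    r, r2 = pearson_association(a, b)
    sp2 = spearman_association(a, b)
    mi = mutual_information(a, b, config)
    return PairMeasure(
        gene_a=gene_a,
        gene_b=gene_b,
        cv_ab=cv_ab,
        cv_ba=cv_ba,
        delta_cv=dcv,
        mean_ab=mean_ab,
        mean_ba=mean_ba,
        pearson_r=r,
        pearson_r2=r2,
        spearman_r2=sp2,
        mi=mi,
        n_used=n_used,
        ra_evaluable=evaluable,
    )
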