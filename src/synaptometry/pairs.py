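"""Axon-coupled pair statistics.

Spines contacted by the same axon — and especially pairs also on the same
dendrite — share pre- and postsynaptic activity histories, so the spread of
their sizes bounds the variability of synaptic plasticity. This module
finds such pairs in a connectivity-labelled spine table, computes the
per-pair coefficient of variation (sample sd of the two values over their
mean) and its median, builds disjoint random-pairing null distributions,
and provides the two-sample KS test and log-log regression used to compare
groups and metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import (DataError, DomainError, InsufficientDataError, SizingError)
from .records import SpinePair, SpineRecord

__all__ = [
    "pair_cv",
    "find_axon_coupled_pairs",
    "median_pair_cv",
    "PairingNull",
    "random_pairing_null",
    "ks_two_sample",
    "loglog_regression",
    "cv_size_trend",
]


def pair_cv(a: float, b: float) -> float:
    """Coefficient of variation of a pair: sample sd (ddof=1) / mean.

    Equals (|a−b|/√2)/((a+b)/2); symmetric in its arguments and invariant
    under a common rescaling of both.
    """
    if not (a > 0 and b > 0):
        raise DomainError(f"pair values must be > 0, got ({a}, {b})")
    return (abs(a - b) / np.sqrt(2.0)) / ((a + b) / 2.0)


def find_axon_coupled_pairs(records: list[SpineRecord]) -> list[SpinePair]:
    """All unordered pairs of spines sharing an axon.

    Pairs whose members also share a dendrite are flagged ``same_dendrite``.
    When an axon contacts k > 2 spines on one dendrite (a multi-synaptic
    bouton configuration), all k·(k−1)/2 pairs are returned with
    ``multi_contact=True`` so downstream medians can exclude them.
    """
    seen: set[str] = set()
    by_axon: dict[str, list[SpineRecord]] = {}
    for rec in records:
        if rec.spine_id in seen:
            raise DataError(f"duplicate spine_id {rec.spine_id!r}")
        seen.add(rec.spine_id)
        by_axon.setdefault(rec.axon_id, []).append(rec)

    pairs: list[SpinePair] = []
    for axon_records in by_axon.values():
        if len(axon_records) < 2:
            continue
        dendrite_counts: dict[str, int] = {}
        for rec in axon_records:
            dendrite_counts[rec.dendrite_id] = dendrite_counts.get(rec.dendrite_id, 0) + 1
        for a, b in combinations(axon_records, 2):
            same = a.dendrite_id == b.dendrite_id
            multi = same and dendrite_counts[a.dendrite_id] > 2
            pairs.append(SpinePair(spine_a=a, spine_b=b, same_dendrite=same,
                                   multi_contact=multi))
    return pairs


def median_pair_cv(pairs: list[SpinePair], *, exclude_multi_contact: bool = True,
                   same_dendrite_only: bool = True, metric: str = "head_volume",
                   ) -> float:
    """Median over eligible pairs of the per-pair CV of a metric.

    By default restricted to same-dendrite pairs with multi-contact (bouton
    triplet) pairs excluded, matching the headline precision statistic.
    """
    cvs = [p.metric_cvs[metric] for p in pairs
           if (p.same_dendrite or not same_dendrite_only)
           and not (exclude_multi_contact and p.multi_contact)]
    if not cvs:
        raise InsufficientDataError("no eligible pairs for median CV")
    return float(np.median(cvs))


@dataclass
class PairingNull:
    """Null distribution of per-pair CVs from repeated disjoint random pairings."""

    statistic_name: str
    null_samples: np.ndarray      # per-pair CVs, length n_resamples * n_pairs
    resample_medians: np.ndarray  # per-resample median CV, length n_resamples
    n_resamples: int
    n_pairs: int
    seed: int

    def empirical_p(self, observed_median: float) -> float:
        """P(null median <= observed), add-one corrected."""
        hits = int(np.sum(self.resample_medians <= observed_median))
        return (hits + 1) / (self.n_resamples + 1)


def random_pairing_null(records: list[SpineRecord], n_pairs: int, n_resamples: int,
                        seed: int, *, metric: str = "head_volume") -> PairingNull:
    """Per-pair CVs of ``n_pairs`` disjoint random pairs, resampled ``n_resamples`` times.

    Within each resample every spine is used at most once (pairs are drawn
    without replacement from the population), mimicking drawing the same
    number of random pairs from the full reconstruction.
    """
    if 2 * n_pairs > len(records):
        raise SizingError(
            f"need {2 * n_pairs} records for {n_pairs} disjoint pairs, "
            f"have {len(records)}")
    if n_pairs < 1 or n_resamples < 1:
        raise SizingError("n_pairs and n_resamples must be >= 1")
    values = np.array([getattr(r, metric) for r in records], dtype=float)
    rng = np.random.default_rng(seed)
    cvs = np.empty((n_resamples, n_pairs))
    for r in range(n_resamples):
        idx = rng.permutation(len(values))[: 2 * n_pairs]
        a = values[idx[0::2]]
        b = values[idx[1::2]]
        cvs[r] = (np.abs(a - b) / np.sqrt(2.0)) / ((a + b) / 2.0)
    return PairingNull(statistic_name=f"pair_cv[{metric}]",
                       null_samples=cvs.ravel(),
                       resample_medians=np.median(cvs, axis=1),
                       n_resamples=n_resamples, n_pairs=n_pairs, seed=seed)


def ks_two_sample(x, y, *, method: str = "asymp") -> dict[str, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D = sup|ECDF_x − ECDF_y|; the p-value comes from the asymptotic
    Kolmogorov distribution at the effective sample size n_x·n_y/(n_x+n_y)
    (``method="asymp"``), or from the exact small-sample distribution
    (``method="exact"``), appropriate when comparing a handful of pairs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("KS test needs two non-empty samples")
    res = stats.ks_2samp(x, y, method=method)
    return {"D": float(res.statistic), "p": float(min(res.pvalue, 1.0))}


def loglog_regression(x, y) -> dict[str, float]:
    """OLS of log(y) on log(x): slope, intercept, r², p, slope stderr.

    The standard treatment of power-law-coupled, right-skewed morphometric
    metrics: Pearson regression after log transformation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("log-log regression requires strictly positive values")
    if x.size < 3:
        raise InsufficientDataError(f"need >=3 points, got {x.size}")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise DomainError("x values are all identical: regression variance degenerate")
    res = stats.linregress(lx, ly)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "p": float(res.pvalue),
            "stderr": float(res.stderr)}


def cv_size_trend(pairs: list[SpinePair], *, metric: str = "head_volume",
                  exclude_multi_contact: bool = True) -> dict[str, float]:
    """Regress per-pair CV on log mean pair size: is precision size-dependent?

    A non-significant slope means small pairs are matched as precisely as
    large ones. Returns the slope and its two-sided p-value.
    """
    eligible = [p for p in pairs if not (exclude_multi_contact and p.multi_contact)]
    if len(eligible) < 3:
        raise InsufficientDataError(f"need >=3 pairs, got {len(eligible)}")
    x = np.array([p.mean(metric) for p in eligible])
    y = np.array([p.metric_cvs[metric] for p in eligible])
    if np.any(x <= 0):
        raise DomainError("pair mean sizes must be > 0")
    lx = np.log(x)
    if np.ptp(lx) == 0:
        raise DomainError("all pair means identical: regression variance degenerate")
    res = stats.linregress(lx, y)
    return {"slope": float(res.slope), "p": float(res.pvalue)}
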