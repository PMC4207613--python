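"""Binomial maturation model linking crossover-designated foci to chiasmata.

In C. elegans oogenesis each of the six chromosome pairs normally
receives exactly one crossover-designated site, marked cytologically by
a COSA-1 focus, and each such site normally matures into a chiasma that
holds the homolog pair together as one bivalent at diakinesis.  A
nucleus with ``c`` chiasmata therefore shows ``12 - c`` DAPI-stained
bodies (6 bivalents when all succeed, 12 univalents when none do).

When maturation is unreliable, the observed chiasma distribution is a
*binomial thinning* of the focus-count distribution: if every focus
independently matures with probability ``p``, a nucleus with ``m`` foci
contributes ``C(m, k) p^k (1-p)^(m-k)`` of a nucleus to the class with
``k`` chiasmata.  This module implements that forward map and the grid
search that estimates the per-focus success probability by minimizing
the sum of squared differences (SSD) between the thinned focus
distribution and the chiasma distribution inferred from DAPI-body
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "CountDistribution",
    "MaturationFit",
    "chiasmata_from_dapi",
    "clamp_counts",
    "normalize_total",
    "adjust_distribution",
    "estimate_p_success",
    "mean_count",
]

#: Diploid chromosome count of C. elegans: 6 homolog pairs, 12 univalents.
N_CHROMOSOME_PAIRS = 6
DIPLOID_BODIES = 2 * N_CHROMOSOME_PAIRS


@dataclass(frozen=True)
class CountDistribution:
    """A weighted distribution of per-nucleus counts.

    ``counts`` maps a count ``k`` (e.g. number of foci or chiasmata per
    nucleus) to the number of nuclei observed with that count.  Weights
    may be fractional after normalization.  ``k_max`` is the largest
    count the model allows (6 for the wild-type karyotype).
    """

    counts: Mapping[int, float]
    k_max: int = N_CHROMOSOME_PAIRS

    def __post_init__(self) -> None:
        cleaned: Dict[int, float] = {}
        for k, w in self.counts.items():
            k = int(k)
            w = float(w)
            if k < 0:
                raise ValueError(f"negative count class k={k}")
            if w < 0:
                raise ValueError(f"negative weight {w} at k={k}")
            if w != 0.0:
                cleaned[k] = cleaned.get(k, 0.0) + w
        object.__setattr__(self, "counts", cleaned)

    def total(self) -> float:
        """Total weight (number of nuclei, possibly fractional)."""
        return float(sum(self.counts.values()))

    def weight(self, k: int) -> float:
        return self.counts.get(k, 0.0)

    def as_array(self) -> np.ndarray:
        """Dense weights on the support ``0..k_max``."""
        arr = np.zeros(self.k_max + 1)
        for k, w in self.counts.items():
            if k > self.k_max:
                raise ValueError(
                    f"weight at k={k} exceeds k_max={self.k_max}; clamp first"
                )
            arr[k] = w
        return arr

    @classmethod
    def from_array(cls, arr: np.ndarray, k_max: int | None = None) -> "CountDistribution":
        if k_max is None:
            k_max = len(arr) - 1
        return cls({k: float(w) for k, w in enumerate(arr)}, k_max=k_max)

    @classmethod
    def from_observations(cls, ks, k_max: int = N_CHROMOSOME_PAIRS) -> "CountDistribution":
        """Tally raw per-nucleus counts into a distribution (no clamping)."""
        vals, freq = np.unique(np.asarray(list(ks), dtype=int), return_counts=True)
        return cls(dict(zip(vals.tolist(), freq.astype(float).tolist())), k_max=k_max)


@dataclass(frozen=True)
class MaturationFit:
    """Result of the SSD grid search for the per-focus success probability.

    Attributes
    ----------
    p_hat:
        The grid value of the maturation probability minimizing the SSD.
    ssd_curve:
        Mapping from each grid probability to its SSD, for plotting the
        objective and locating the arrowed minimum.
    adjusted:
        The focus distribution thinned at ``p_hat``, i.e. the predicted
        chiasma distribution at the optimum.
    grid_step:
        Spacing of the probability grid searched.
    """

    p_hat: float
    ssd_curve: Dict[float, float]
    adjusted: CountDistribution
    grid_step: float = 0.01


def chiasmata_from_dapi(dapi_count: int) -> int:
    """Infer the chiasma count of a diakinesis nucleus from its DAPI bodies.

    Each chiasma fuses two univalents into one bivalent, so a nucleus
    with ``d`` separable DAPI bodies carries ``12 - d`` chiasmata.
    Counts above 12 would imply chromosome fragmentation, which the
    model does not cover, and counts below 6 would imply aggregation
    beyond a full bivalent complement.
    """
    d = int(dapi_count)
    if not 1 <= d <= DIPLOID_BODIES:
        raise ValueError(
            f"DAPI body count {d} outside [1, {DIPLOID_BODIES}]; "
            "counts above 12 indicate fragmentation not covered by the model"
        )
    return DIPLOID_BODIES - d


def clamp_counts(dist: CountDistribution, k_max: int = N_CHROMOSOME_PAIRS) -> CountDistribution:
    """Move any weight above ``k_max`` onto ``k_max``, preserving the total.

    Occasional counts of 7 or 8 foci (double-labelled sites or touching
    signals) are corrected to 6 before fitting, since the model allows
    at most one designated site per chromosome pair.
    """
    out: Dict[int, float] = {}
    for k, w in dist.counts.items():
        kk = min(k, k_max)
        out[kk] = out.get(kk, 0.0) + w
    return CountDistribution(out, k_max=k_max)


def normalize_total(dist: CountDistribution, target_total: float) -> CountDistribution:
    """Rescale all weights so the distribution totals ``target_total``.

    Used to put the focus-count sample on the same footing as the
    DAPI-body sample when the two were scored in different numbers of
    nuclei.  Fractional nucleus counts are deliberate and carried exactly.
    """
    if target_total <= 0:
        raise ValueError(f"target_total must be positive, got {target_total}")
    tot = dist.total()
    if tot <= 0:
        raise ValueError("cannot normalize a distribution with zero total weight")
    scale = target_total / tot
    return CountDistribution(
        {k: w * scale for k, w in dist.counts.items()}, k_max=dist.k_max
    )


def adjust_distribution(dist: CountDistribution, p: float) -> CountDistribution:
    """Binomially thin a count distribution at per-unit success probability ``p``.

    The adjusted weight in class ``k`` is

        N'_k = sum_{m >= k} N_m * C(m, k) * p**k * (1 - p)**(m - k)

    i.e. every nucleus with ``m`` foci is redistributed over chiasma
    classes ``0..m`` according to the Binomial(m, p) pmf.  Because each
    binomial row sums to one, the total weight is conserved.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"maturation probability must lie in [0, 1], got {p}")
    k_max = dist.k_max
    out = np.zeros(k_max + 1)
    for m, w in dist.counts.items():
        if m > k_max:
            raise ValueError(f"distribution has weight at k={m} > k_max={k_max}; clamp first")
        out[: m + 1] += w * stats.binom.pmf(np.arange(m + 1), m, p)
    return CountDistribution.from_array(out, k_max=k_max)


def mean_count(dist: CountDistribution) -> float:
    """Weighted mean count per nucleus."""
    tot = dist.total()
    if tot <= 0:
        raise ValueError("mean of a zero-total distribution is undefined")
    return float(sum(k * w for k, w in dist.counts.items()) / tot)


def estimate_p_success(
    cosa: CountDistribution,
    chiasma: CountDistribution,
    grid_step: float = 0.01,
) -> MaturationFit:
    """Estimate the per-focus maturation probability by SSD grid search.

    ``cosa`` is the (clamped, normalized) focus-count distribution and
    ``chiasma`` the chiasma distribution inferred from DAPI bodies.  The
    objective ``SSD(p) = sum_k (chiasma_k - thin(cosa, p)_k)**2`` is
    evaluated over ``k = 0..k_max`` on the grid ``{0, grid_step, .., 1}``
    and the minimizing probability returned (ties broken toward the
    smaller probability).  The grid is exact at the resolution at which
    success rates are reported (whole percent).

    Callers normally pass ``cosa`` already normalized to
    ``chiasma.total()``; the SSD is computed on weights, so a constant
    scale offset between the two inputs only rescales the curve.
    """
    if cosa.total() <= 0 or chiasma.total() <= 0:
        raise ValueError("both distributions must carry positive weight")
    if not 0 < grid_step <= 1:
        raise ValueError(f"grid_step must lie in (0, 1], got {grid_step}")
    k_max = cosa.k_max
    observed = chiasma.as_array() if chiasma.k_max == k_max else CountDistribution(
        dict(chiasma.counts), k_max=k_max
    ).as_array()

    n_steps = int(round(1.0 / grid_step))
    grid = np.round(np.linspace(0.0, 1.0, n_steps + 1), 12)
    curve: Dict[float, float] = {}
    best_p, best_ssd, best_adj = 0.0, np.inf, None
    for p in grid:
        adj = adjust_distribution(cosa, float(p))
        ssd = float(np.sum((observed - adj.as_array()) ** 2))
        curve[float(p)] = ssd
        if ssd < best_ssd:  # strict: ties keep the smaller p
            best_p, best_ssd, best_adj = float(p), ssd, adj
    return MaturationFit(p_hat=best_p, ssd_curve=curve, adjusted=best_adj, grid_step=grid_step)
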