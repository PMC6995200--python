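"""Decompose a Ks distribution into major normal components.

Each large-scale duplication event leaves a roughly Gaussian peak in the
Ks distribution of surviving duplicate pairs; the observed distribution
is their mixture with a long right tail of saturated estimates.  The
tail is handled by hard truncation to a fit range (default (0, 2]),
after which an EM Gaussian mixture is fitted for each candidate
component count and the best count selected by BIC.

Values are sorted before fitting so results do not depend on input
order; every source of randomness is controlled by ``seed``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.mixture import GaussianMixture


@dataclass(frozen=True)
class Component:
    mu: float
    sigma: float
    weight: float


@dataclass
class KsMixture:
    """Fitted Gaussian components of a Ks distribution, sorted by mean."""

    components: List[Component]
    ks_range: Tuple[float, float]
    n_points: int
    bic: float

    @property
    def k(self) -> int:
        return len(self.components)

    def weighted_log_density(self, ks) -> np.ndarray:
        """(n, k) matrix of log(weight_j * Normal(ks_i; mu_j, sigma_j))."""
        x = np.atleast_1d(np.asarray(ks, dtype=float))
        out = np.empty((x.size, self.k))
        for j, c in enumerate(self.components):
            out[:, j] = (
                math.log(c.weight)
                - 0.5 * math.log(2 * math.pi) - math.log(c.sigma)
                - 0.5 * ((x - c.mu) / c.sigma) ** 2
            )
        return out

    def thresholds(self) -> List[float]:
        """Cut points between adjacent components where the weight-scaled
        densities are equal (one fewer than the component count)."""
        cuts = []
        for c1, c2 in zip(self.components, self.components[1:]):
            cuts.append(_equal_density_point(c1, c2))
        return cuts


def _equal_density_point(c1: Component, c2: Component) -> float:
    """Solve w1 N(x;m1,s1) = w2 N(x;m2,s2) for x between the two means."""
    m1, s1, w1 = c1.mu, c1.sigma, c1.weight
    m2, s2, w2 = c2.mu, c2.sigma, c2.weight
    if abs(s1 - s2) < 1e-12:
        # equal variances: linear equation
        num = (m2 ** 2 - m1 ** 2) / (2 * s1 ** 2) + math.log(w1 / w2)
        den = (m2 - m1) / s1 ** 2
        if abs(den) > 0:
            x = num / den
            if m1 <= x <= m2:
                return x
        return (m1 + m2) / 2.0
    a = 1.0 / (2 * s1 ** 2) - 1.0 / (2 * s2 ** 2)
    b = m2 / s2 ** 2 - m1 / s1 ** 2
    c = m1 ** 2 / (2 * s1 ** 2) - m2 ** 2 / (2 * s2 ** 2) + math.log((w1 * s2) / (w2 * s1))
    disc = b * b - 4 * a * c
    if disc >= 0:
        roots = [(-b + sign * math.sqrt(disc)) / (2 * a) for sign in (1, -1)]
        inside = [r for r in roots if m1 <= r <= m2]
        if inside:
            return min(inside, key=lambda r: abs(r - (m1 + m2) / 2))
    # no analytic root between the means: locate numerically
    grid = np.linspace(m1, m2, 512)
    mix = KsMixture([c1, c2], (0, 0), 0, 0.0)
    diff = np.abs(mix.weighted_log_density(grid)[:, 0] - mix.weighted_log_density(grid)[:, 1])
    return float(grid[np.argmin(diff)])


def _fit_k(x: np.ndarray, k: int, seed: int) -> GaussianMixture:
    """Fit one component count: a quantile-spread initialization plus nine
    seeded random-from-data initializations; best final likelihood wins."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    common = dict(
        n_components=k, covariance_type="full", tol=1e-6, max_iter=500, reg_covar=1e-8
    )
    q = (np.arange(k) + 0.5) / k
    means = np.quantile(x, q).reshape(-1, 1)
    var = max(float(np.var(x)) / max(k * k, 1), 1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm_q = GaussianMixture(
            **common,
            weights_init=np.full(k, 1.0 / k),
            means_init=means,
            precisions_init=np.full((k, 1, 1), 1.0 / var),
            random_state=seed,
        ).fit(x.reshape(-1, 1))
        best = gm_q
        if k > 1:
            gm_r = GaussianMixture(
                **common, n_init=9, init_params="random_from_data", random_state=seed
            ).fit(x.reshape(-1, 1))
            if gm_r.lower_bound_ > best.lower_bound_:
                best = gm_r
    return best


def fit_mixture(
    ks_values,
    k_range: Sequence[int] = (1, 2, 3, 4),
    ks_range: Tuple[float, float] = (0.0, 2.0),
    seed: int = 0,
) -> KsMixture:
    """EM Gaussian-mixture fit of a Ks sample, component count chosen by BIC.

    Values outside ``(ks_min, ks_max]`` are discarded before fitting
    (exactly-zero Ks from recent tandem duplicates is excluded by the
    exclusive lower bound).  At least 50 in-range values are required.
    """
    lo, hi = ks_range
    x = np.asarray(ks_values, dtype=float)
    x = x[np.isfinite(x)]
    x = x[(x > lo) & (x <= hi)]
    if x.size < 50:
        raise ValueError(
            f"only {x.size} Ks values inside ({lo}, {hi}]; at least 50 are needed -- "
            "provide more gene pairs or widen the range"
        )
    x = np.sort(x)
    best_model = None
    best_bic = math.inf
    for k in sorted(set(int(k) for k in k_range)):
        if k < 1 or k > x.size:
            continue
        gm = _fit_k(x, k, seed)
        bic = gm.bic(x.reshape(-1, 1))
        if bic < best_bic:
            best_bic = bic
            best_model = gm
    assert best_model is not None
    comps = [
        Component(float(m[0]), float(math.sqrt(c[0][0])), float(w))
        for m, c, w in zip(best_model.means_, best_model.covariances_, best_model.weights_)
    ]
    comps.sort(key=lambda c: c.mu)
    total_w = sum(c.weight for c in comps)
    comps = [Component(c.mu, c.sigma, c.weight / total_w) for c in comps]
    return KsMixture(components=comps, ks_range=(lo, hi), n_points=int(x.size), bic=float(best_bic))


def classify_by_event(
    ks, mixture: KsMixture, return_flag: bool = False
) -> Union[int, np.ndarray, Tuple]:
    """Component index with maximal weight-scaled density at each Ks value.

    Ties at an equal-density cut point go to the lower-index (younger)
    component.  Values outside the fit range are assigned the nearest
    boundary component and flagged when ``return_flag`` is set.
    """
    x = np.atleast_1d(np.asarray(ks, dtype=float))
    lo, hi = mixture.ks_range
    out_of_range = (x <= lo) | (x > hi)
    clamped = np.clip(x, np.nextafter(lo, hi), hi)
    logd = mixture.weighted_log_density(clamped)
    # argmax returns the first (lowest) index on exact ties
    idx = np.argmax(np.round(logd, 12), axis=1)
    if np.isscalar(ks) or np.asarray(ks).ndim == 0:
        result: Union[int, np.ndarray] = int(idx[0])
        flag = bool(out_of_range[0])
    else:
        result = idx
        flag = out_of_range
    return (result, flag) if return_flag else result
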