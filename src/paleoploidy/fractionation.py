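"""Post-polyploidy gene-loss statistics.

Gene loss after polyploidy proceeds in short runs of consecutive genes.
Given presence/absence vectors along the reference gene order (one per
target subgenome column of the homology table) this module extracts
deletion run lengths, fits the geometric run-length model by maximum
likelihood, computes sliding-window retention profiles, and tests pairs
of subgenomes for biased fractionation (subgenome dominance).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class RunLengthSample:
    """Maximal runs of absent genes; runs touching a vector end are censored
    (their true length is unknown)."""

    runs: List[int] = field(default_factory=list)
    censored: List[bool] = field(default_factory=list)

    def extend(self, other: "RunLengthSample") -> None:
        self.runs.extend(other.runs)
        self.censored.extend(other.censored)

    def uncensored(self) -> List[int]:
        return [r for r, c in zip(self.runs, self.censored) if not c]

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def deletion_runs(presence: Sequence) -> RunLengthSample:
    """Extract maximal runs of absent genes from a presence vector.

    ``presence`` is any sequence of truthy (retained) / falsy (lost)
    values along the reference gene order.
    """
    v = np.asarray([bool(x) for x in presence])
    sample = RunLengthSample()
    n = len(v)
    i = 0
    while i < n:
        if not v[i]:
            j = i
            while j < n and not v[j]:
                j += 1
            sample.runs.append(j - i)
            sample.censored.append(i == 0 or j == n)
            i = j
        else:
            i += 1
    return sample


@dataclass(frozen=True)
class GeometricFit:
    """Maximum-likelihood geometric fit of deletion run lengths.

    ``p_hat`` is the closed-form MLE (number of runs / total deleted
    genes): the probability that a removal event deletes exactly one
    gene.  ``frac_runs_le2`` = p(2-p) is the model's share of runs of
    one or two genes.  ``goodness_p`` comes from a chi-square test of
    binned observed vs expected run-length counts (or, with
    method="regression", from the log-frequency regression F-test).
    """

    p_hat: float
    goodness_p: float
    frac_runs_le2: float
    n_runs: int
    method: str = "chisq"
    p_regression: Optional[float] = None


def _chisq_goodness(runs: np.ndarray, p: float) -> float:
    n = len(runs)
    # bins 1..9 and >=10, tail-merged until every expected count >= 5
    edges = list(range(1, 10))
    observed = [int(np.sum(runs == l)) for l in edges] + [int(np.sum(runs >= 10))]
    expected = [n * p * (1 - p) ** (l - 1) for l in edges] + [n * (1 - p) ** 9]
    while len(expected) > 2 and expected[-1] < 5:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected.pop()
        observed.pop()
    # merge any remaining small interior bins into their right neighbour
    i = 0
    while i < len(expected) - 1:
        if expected[i] < 5:
            expected[i + 1] += expected[i]
            observed[i + 1] += observed[i]
            del expected[i], observed[i]
        else:
            i += 1
    dof = len(expected) - 1 - 1  # one estimated parameter
    if dof < 1:
        return 1.0
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    exp *= obs.sum() / exp.sum()
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(max(stats.chi2.sf(chi2, dof), np.nextafter(0.0, 1.0)))


def _regression_goodness(runs: np.ndarray) -> Tuple[float, float]:
    """Slope regression of log run-length frequencies: under geometric(p),
    log f(l) is linear in l with slope log(1-p).  Returns (p_from_slope,
    regression F-test p-value)."""
    lengths, counts = np.unique(runs, return_counts=True)
    if len(lengths) < 3:
        return float("nan"), 1.0
    res = stats.linregress(lengths, np.log(counts))
    p_reg = 1.0 - float(np.exp(res.slope)) if res.slope < 0 else float("nan")
    return p_reg, float(res.pvalue)


def fit_geometric(
    sample: RunLengthSample, exclude_censored: bool = True, method: str = "chisq"
) -> GeometricFit:
    """Fit geometric(p) to run lengths by maximum likelihood.

    Censored (edge-touching) runs are excluded by default.  Requires at
    least 30 usable runs.
    """
    runs = np.asarray(sample.uncensored() if exclude_censored else sample.runs, dtype=int)
    if len(runs) < 30:
        raise ValueError(f"only {len(runs)} usable deletion runs; at least 30 required")
    p_hat = float(len(runs) / runs.sum())
    p_regression = None
    if method == "regression":
        p_regression, goodness = _regression_goodness(runs)
    elif method == "chisq":
        goodness = 1.0 if p_hat >= 1.0 else _chisq_goodness(runs, p_hat)
    else:
        raise ValueError(f"unknown goodness-of-fit method {method!r}")
    return GeometricFit(
        p_hat=p_hat,
        goodness_p=goodness,
        frac_runs_le2=p_hat * (2.0 - p_hat),
        n_runs=int(len(runs)),
        method=method,
        p_regression=p_regression,
    )


def retention_windows(presence: Sequence, window: int = 100, step: int = 1) -> np.ndarray:
    """Sliding-window retention fractions along the reference gene order.

    Window ``i`` starts at reference rank ``i*step``; the profile has
    max(0, n - window + 1) entries for step 1 and is empty (with a
    warning) when the vector is shorter than the window.
    """
    v = np.asarray([bool(x) for x in presence], dtype=float)
    n = len(v)
    if n < window:
        import warnings

        warnings.warn(f"presence vector ({n}) shorter than window ({window}); empty profile")
        return np.empty(0)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    starts = np.arange(0, n - window + 1, step)
    return (csum[starts + window] - csum[starts]) / window


@dataclass(frozen=True)
class SubgenomeComparison:
    """Window-wise divergence summary between two subgenome retention profiles."""

    frac_divergent: float
    mean_diff: float
    dominant: Optional[str]
    n_windows: int
    sign_consistency: float
    labels: Tuple[str, str] = ("A", "B")


def compare_subgenomes(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    window: int = 100,
    delta: float = 0.05,
    alpha: float = 0.05,
    labels: Tuple[str, str] = ("A", "B"),
) -> SubgenomeComparison:
    """Test two retention profiles (same reference axis) for biased loss.

    Per window a two-proportion z-test (window size as trials) is
    combined with the absolute-difference gate |ra - rb| >= delta.  A
    subgenome is called dominant when at least half the windows are
    significant-and-divergent and at least 80% of those agree in sign.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        return SubgenomeComparison(0.0, 0.0, None, 0, 0.0, labels)
    diff = a - b
    pooled = (a + b) / 2.0
    se = np.sqrt(np.clip(pooled * (1 - pooled) * 2.0 / window, 0, None))
    z = np.zeros_like(diff)
    nz = se > 0
    z[nz] = diff[nz] / se[nz]
    pvals = np.where(nz, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    divergent = (pvals < alpha) & (np.abs(diff) >= delta)
    frac = float(np.mean(divergent))
    mean_diff = float(np.mean(diff))
    dominant = None
    consistency = 0.0
    if divergent.any():
        signs = np.sign(diff[divergent])
        major = 1.0 if signs.sum() >= 0 else -1.0
        consistency = float(np.mean(signs == major))
        if frac >= 0.5 and consistency >= 0.8:
            dominant = labels[0] if major > 0 else labels[1]
    return SubgenomeComparison(
        frac_divergent=frac,
        mean_diff=mean_diff,
        dominant=dominant,
        n_windows=int(a.size),
        sign_consistency=consistency,
        labels=labels,
    )
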