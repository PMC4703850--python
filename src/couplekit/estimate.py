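"""Estimate the decay constant and coupling strength from intensity data.

Two estimators, matching the two kinds of data the assay produces:

* **Profile fit** — per-cell intensities at known coupling distances x are
  normalized to the probe intensity I0 and fit with

      I_norm(x) = (1 - b) * exp(-lambda * x) + b,       b = I_bg / I0,

  by bounded nonlinear least squares on shell means (the mean intensity at
  each distinct x). The coupling strength is S = exp(-lambda).

* **Neighbor ratio** — for mosaic data, the background-adjusted ratio of the
  mean intensity of the six nearest marker-positive cells to the probe
  intensity, S = (mean(I1) - I_bg) / (I0 - I_bg).

Group comparisons use a two-sided permutation test on the difference of group
means: exact (full enumeration) whenever the number of distinct relabelings
fits in the permutation budget, Monte-Carlo with add-one correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import comb
from scipy.stats import spearmanr

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedStrengthError,
    UnidentifiableFitError,
)

__all__ = [
    "IntensityProfile",
    "FitResult",
    "MosaicMeasurement",
    "StrengthResult",
    "GroupComparison",
    "DoseResponseSummary",
    "fit_decay",
    "neighbor_ratio_strength",
    "compare_groups",
    "dose_response_table",
]


@dataclass(frozen=True)
class IntensityProfile:
    """Per-cell (coupling distance, intensity) observations for one probe.

    ``x`` counts coupling hops from the probe cell; at least one observation
    must be at x = 0 (it defines the probe intensity I0). ``I_bg`` is the
    measured background intensity, or ``None`` to estimate it jointly as the
    fitted asymptote.
    """

    x: np.ndarray
    I: np.ndarray
    probe_id: str = ""
    I_bg: float | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "I", I)
        if x.shape != I.shape or x.ndim != 1:
            raise InvalidParameterError("x and I must be 1D arrays of equal length")
        if np.any(x < 0):
            raise InvalidParameterError("coupling distances must be non-negative")
        if np.any(I < 0):
            raise InvalidParameterError("intensities must be non-negative")
        if not np.any(x == 0):
            raise InvalidParameterError(
                "profile needs at least one x = 0 observation (the probe cell)"
            )
        if self.I_bg is not None and self.I_bg < 0:
            raise InvalidParameterError("I_bg must be non-negative")

    @property
    def I0(self) -> float:
        """Probe intensity: mean intensity of the x = 0 observations."""
        return float(np.mean(self.I[self.x == 0]))

    def shell_means(self) -> tuple[np.ndarray, np.ndarray]:
        """(distinct x, mean intensity at each x), sorted by x."""
        xs = np.unique(self.x)
        means = np.array([np.mean(self.I[self.x == xi]) for xi in xs])
        return xs, means


@dataclass(frozen=True)
class FitResult:
    """Result of a decay-constant fit.

    ``bg_frac`` is the (fitted or fixed) background fraction I_bg / I0;
    ``rss`` is the residual sum of squares on the normalized scale; ``n_obs``
    is the number of shell means entering the fit.
    """

    lam: float
    S: float
    bg_frac: float
    rss: float
    se_lam: float
    n_obs: int


class StrengthResult(NamedTuple):
    """Coupling strength with a flag marking values clipped into [0, 1]."""

    S: float
    clipped: bool


@dataclass(frozen=True)
class MosaicMeasurement:
    """Probe intensity, six-nearest-neighbor intensities and background for
    one probe cell of a mosaic."""

    I0: float
    I1: tuple[float, ...]
    I_bg: float
    probe_id: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "I1", tuple(float(v) for v in self.I1))
        object.__setattr__(self, "flags", tuple(self.flags))
        if not self.I1:
            raise InvalidParameterError("I1 must be non-empty")
        if len(self.I1) > 6:
            raise InvalidParameterError("I1 holds at most six neighbor intensities")
        if self.I0 <= self.I_bg:
            raise UndefinedStrengthError(
                f"probe intensity {self.I0} does not exceed background {self.I_bg}"
            )


def _norm_model(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    lam, b = theta
    return (1.0 - b) * np.exp(-lam * x) + b


def fit_decay(profile: IntensityProfile, estimate_bg: bool = True) -> FitResult:
    """Fit the normalized exponential decay to a profile's shell means.

    Parameters
    ----------
    estimate_bg :
        If True (default) the background fraction b = I_bg / I0 is a free
        parameter in [0, 1); if False it is fixed from ``profile.I_bg``.

    The fit is bounded nonlinear least squares (lambda >= 0, 0 <= b < 1)
    started from lambda in {0.1, 1, 3}; the lowest-RSS solution wins.
    Normalization makes the result invariant to rescaling all intensities.
    """
    xs, means = profile.shell_means()
    if xs.size < 3:
        raise InsufficientDataError(
            f"need at least 3 distinct coupling distances, got {xs.size}"
        )
    I0 = profile.I0
    if I0 <= 0:
        raise UnidentifiableFitError("probe intensity is zero")
    if not estimate_bg and profile.I_bg is None:
        raise InvalidParameterError("estimate_bg=False requires profile.I_bg")
    if profile.I_bg is not None and I0 - profile.I_bg <= 1e-9 * max(I0, profile.I_bg):
        raise UnidentifiableFitError(
            "profile is flat at background level (I0 <= I_bg); "
            "the decay constant is unidentifiable"
        )

    y = means / I0
    b_hi = 1.0 - 1e-6  # keeps the degenerate (b -> 1, lambda arbitrary) ray out
    if estimate_bg:
        b0 = float(np.clip(y[-1], 0.0, 0.9))
        starts = [(0.0, b0), (0.1, b0), (1.0, b0), (3.0, b0)]
        bounds = ([0.0, 0.0], [np.inf, b_hi])

        def resid(theta):
            return _norm_model(theta, xs) - y
    else:
        b_fixed = profile.I_bg / I0
        if not 0.0 <= b_fixed < 1.0:
            raise InvalidParameterError("I_bg / I0 must lie in [0, 1)")
        starts = [(0.0,), (0.1,), (1.0,), (3.0,)]
        bounds = ([0.0], [np.inf])

        def resid(theta):
            return _norm_model((theta[0], b_fixed), xs) - y

    best = None
    for s in starts:
        res = least_squares(resid, np.asarray(s, dtype=float), bounds=bounds,
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None:
            best = res
            continue
        tol = 1e-12 * max(1.0, best.cost)
        if res.cost < best.cost - tol:
            best = res
        elif abs(res.cost - best.cost) <= tol and res.x[0] < best.x[0]:
            # RSS tie (e.g. flat profile): prefer the smaller decay constant
            best = res

    lam = float(best.x[0])
    b = float(best.x[1]) if estimate_bg else float(profile.I_bg / I0)
    rss = float(2.0 * best.cost)
    n = xs.size
    p = len(best.x)
    se_lam = math.nan
    if n > p:
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J) * rss / (n - p)
            se_lam = float(math.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            pass
    return FitResult(lam=lam, S=math.exp(-lam), bg_frac=b, rss=rss,
                     se_lam=se_lam, n_obs=int(n))


def neighbor_ratio_strength(measurement: MosaicMeasurement) -> StrengthResult:
    """Background-adjusted neighbor ratio S = (mean(I1) - I_bg) / (I0 - I_bg),
    clipped to [0, 1] with ``clipped=True`` when clipping occurred."""
    raw = (float(np.mean(measurement.I1)) - measurement.I_bg) / (
        measurement.I0 - measurement.I_bg
    )
    S = min(max(raw, 0.0), 1.0)
    return StrengthResult(S=S, clipped=(S != raw))


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided permutation test on the difference of group means."""

    delta_mean: float
    p_value: float
    se_a: float
    se_b: float
    n_a: int
    n_b: int
    exact: bool
    n_perm: int


def _sem(v: np.ndarray) -> float:
    if v.size < 2:
        return math.nan
    return float(np.std(v, ddof=1) / math.sqrt(v.size))


def compare_groups(S_a: Sequence[float], S_b: Sequence[float],
                   n_perm: int = 9999, seed: int | None = None) -> GroupComparison:
    """Compare two groups of coupling strengths by permutation test.

    The statistic is the difference of means (a minus b). When the number of
    distinct group relabelings C(n_a + n_b, n_a) is within ``n_perm`` the test
    enumerates all of them and the p-value is exact; otherwise ``n_perm``
    random relabelings are drawn and the p-value uses the add-one correction
    (p = (1 + #extreme) / (n_perm + 1)). Deterministic given ``seed``.
    """
    a = np.asarray(S_a, dtype=float)
    b = np.asarray(S_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs at least 3 values")
    if n_perm < 999:
        raise InvalidParameterError("n_perm must be at least 999")
    delta = float(np.mean(a) - np.mean(b))
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    # tolerance for float ties so 'as extreme' includes equal statistics
    tie_eps = 1e-12 * max(1.0, float(np.max(np.abs(pooled))))
    target = abs(delta) - tie_eps

    n_total = comb(n, na, exact=True)
    if n_total <= n_perm:
        count = 0
        idx = range(n)
        for pick in combinations(idx, na):
            m = np.zeros(n, dtype=bool)
            m[list(pick)] = True
            d = pooled[m].mean() - pooled[~m].mean()
            if abs(d) >= target:
                count += 1
        p = count / n_total
        exact, used = True, n_total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            d = perm[:na].mean() - perm[na:].mean()
            if abs(d) >= target:
                count += 1
        p = (1 + count) / (n_perm + 1)
        exact, used = False, n_perm
    return GroupComparison(delta_mean=delta, p_value=float(p), se_a=_sem(a),
                           se_b=_sem(b), n_a=int(na), n_b=int(b.size),
                           exact=exact, n_perm=used)


@dataclass(frozen=True)
class DoseResponseSummary:
    """Per-dose mean +/- SEM with a monotone-trend statistic (Spearman rank
    correlation of dose against mean S; ``None`` for a single dose)."""

    table: pd.DataFrame
    spearman_rho: float | None


def dose_response_table(doses: Sequence[float],
                        S_values: Sequence[Sequence[float]]) -> DoseResponseSummary:
    """Summarize per-dose coupling strengths.

    ``S_values[i]`` holds the per-probe S estimates at ``doses[i]``.
    """
    if len(doses) != len(S_values):
        raise InvalidParameterError("doses and S_values must have equal length")
    rows = []
    for d, vals in zip(doses, S_values):
        v = np.asarray(vals, dtype=float)
        rows.append({"dose": float(d), "mean_S": float(np.mean(v)),
                     "sem_S": _sem(v), "n": int(v.size)})
    table = pd.DataFrame(rows)
    rho = None
    if len(rows) > 1:
        rho = float(spearmanr(table["dose"], table["mean_S"]).statistic)
    return DoseResponseSummary(table=table, spearman_rho=rho)
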