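"""Five entropy estimators for real-valued time series.

Two families are implemented:

* **Ordinal (Shannon-type)**: permutation entropy (PEn) and modified
  permutation entropy (MPEn).  The series is cut into overlapping
  windows of ``n`` consecutive samples, each window is encoded by the
  rank order of its samples, and Shannon's entropy of the empirical
  pattern distribution is returned.  PEn breaks ties by order of
  appearance; MPEn keeps ties as patterns in their own right, so its
  pattern universe is larger (the ordered Bell numbers: 13 patterns for
  n = 3 rather than 3! = 6).

* **Embedding (conditional-probability)**: sample entropy (SEn),
  quadratic sample entropy (QSEn) and fuzzy entropy (FEn).  Template
  vectors of length ``m`` are compared under the Chebyshev (max-norm)
  distance with tolerance ``r`` expressed as a fraction of the standard
  deviation of the series; the estimator is the negative log of the
  conditional probability that templates matching at length ``m`` still
  match at length ``m + 1``.  QSEn adds ``log(2r)`` so that values are
  comparable across tolerances; FEn replaces the hard Heaviside match
  by the graded similarity ``exp(-d^n / r)`` on baseline-removed
  vectors.

All estimators use the natural logarithm by default (the ordinal pair
can switch to base 2), an embedding/pattern delay of 1 sample, and
exclude self-matches.  Undefined embedding-entropy ratios (no matches
at either template length) are reported as ``nan`` rather than raised
or silently mapped to infinity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PEnConfig",
    "MPEnConfig",
    "SEnConfig",
    "QSEnConfig",
    "FEnConfig",
    "EntropyConfig",
    "ordinal_patterns",
    "permutation_entropy",
    "modified_permutation_entropy",
    "sample_entropy",
    "quadratic_sample_entropy",
    "fuzzy_entropy",
    "compute_entropy",
    "merged_rank_pattern_count",
    "config_name",
    "config_family",
    "default_grid",
]


# ---------------------------------------------------------------------------
# configurations

@dataclass(frozen=True)
class PEnConfig:
    """Permutation entropy settings: pattern length ``n`` (>= 2)."""

    n: int = 3
    normalize: bool = True
    log_base: str = "e"  # "e" or "2"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("pattern order n must be >= 2")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")


@dataclass(frozen=True)
class MPEnConfig:
    """Modified (tie-inclusive) permutation entropy settings."""

    n: int = 3
    normalize: bool = True
    log_base: str = "e"

    __post_init__ = PEnConfig.__post_init__


@dataclass(frozen=True)
class SEnConfig:
    """Sample entropy settings: embedding dimension ``m`` and tolerance
    ``r`` as a fraction of the SD of the series it is applied to."""

    m: int = 2
    r: float = 0.2

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be positive")


@dataclass(frozen=True)
class QSEnConfig:
    """Quadratic sample entropy settings (SEn plus the log(2r) term)."""

    m: int = 2
    r: float = 0.2

    __post_init__ = SEnConfig.__post_init__


@dataclass(frozen=True)
class FEnConfig:
    """Fuzzy entropy settings.

    ``n`` is the similarity exponent shaping ``exp(-d^n / r)``; ``m``
    and ``r`` as for sample entropy.  ``remove_baseline`` subtracts each
    template vector's own mean before comparison (the standard fuzzy
    construction); it can be switched off for cross-checks.
    """

    n: int = 1
    m: int = 2
    r: float = 0.2
    remove_baseline: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("similarity exponent n must be >= 1")
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be positive")


EntropyConfig = Union[PEnConfig, MPEnConfig, SEnConfig, QSEnConfig, FEnConfig]


# ---------------------------------------------------------------------------
# ordinal patterns

def _strict_patterns(x: np.ndarray, n: int) -> np.ndarray:
    # stable argsort breaks ties by order of appearance (classic PEn rule)
    w = sliding_window_view(x, n)
    perm = np.argsort(w, axis=1, kind="stable")
    return perm @ (n ** np.arange(n))


def _merged_rank_patterns(x: np.ndarray, n: int) -> np.ndarray:
    # dense ranks: tied samples share one rank, ranks are 0..k-1
    w = sliding_window_view(x, n)
    order = np.argsort(w, axis=1, kind="stable")
    svals = np.take_along_axis(w, order, axis=1)
    dense_sorted = np.cumsum(
        np.concatenate(
            [np.zeros((w.shape[0], 1), dtype=int), (np.diff(svals, axis=1) > 0).astype(int)],
            axis=1,
        ),
        axis=1,
    )
    ranks = np.empty_like(dense_sorted)
    np.put_along_axis(ranks, order, dense_sorted, axis=1)
    return ranks @ (n ** np.arange(n))


def ordinal_patterns(x, n: int, tie_rule: str = "order-of-appearance") -> np.ndarray:
    """Encode every length-``n`` window of ``x`` as an integer pattern id.

    ``tie_rule='order-of-appearance'`` gives the strict-permutation
    encoding used by PEn (tied samples are ranked by position);
    ``'merged-rank'`` gives the tie-inclusive encoding used by MPEn
    (tied samples share a rank).  Pattern ids are only comparable within
    one (n, tie_rule) combination.
    """
    x = np.asarray(x, dtype=float)
    if x.size < n:
        raise ValueError(f"need at least n={n} samples, got {x.size}")
    if tie_rule == "order-of-appearance":
        return _strict_patterns(x, n)
    if tie_rule == "merged-rank":
        return _merged_rank_patterns(x, n)
    raise ValueError(f"unknown tie rule: {tie_rule!r}")


@lru_cache(maxsize=None)
def merged_rank_pattern_count(n: int) -> int:
    """Number of distinct tie-inclusive rank patterns of ``n`` samples.

    Counted by exhaustive enumeration of dense-rank vectors (every
    surjection of n positions onto ranks {0..k-1}); equals the ordered
    Bell numbers 3, 13, 75, 541, ... for n = 2, 3, 4, 5, ...
    """
    count = 0
    for p in itertools.product(range(n), repeat=n):
        k = max(p) + 1
        if len(set(p)) == k:
            count += 1
    return count


def _shannon(counts: np.ndarray, log) -> float:
    p = counts / counts.sum()
    return float(-(p * log(p)).sum())


def _log_fn(base: str):
    return np.log if base == "e" else np.log2


def permutation_entropy(x, cfg: PEnConfig = PEnConfig()) -> float:
    """Shannon entropy of the strict ordinal-pattern distribution.

    Normalized values divide by ``log(n!)`` and lie in [0, 1].
    """
    pats = ordinal_patterns(x, cfg.n, "order-of-appearance")
    _, counts = np.unique(pats, return_counts=True)
    log = _log_fn(cfg.log_base)
    h = _shannon(counts, log)
    if cfg.normalize:
        h /= float(log(float(math.factorial(cfg.n))))
    return h


def modified_permutation_entropy(x, cfg: MPEnConfig = MPEnConfig()) -> float:
    """Shannon entropy of the tie-inclusive ordinal-pattern distribution.

    Normalization divides by the log of the full enumerated pattern
    universe, so continuous-valued noise — which never realises tie
    patterns — saturates below 1 (at ln6/ln13 ~= 0.70 for n = 3).
    """
    pats = ordinal_patterns(x, cfg.n, "merged-rank")
    _, counts = np.unique(pats, return_counts=True)
    log = _log_fn(cfg.log_base)
    h = _shannon(counts, log)
    if cfg.normalize:
        h /= float(log(float(merged_rank_pattern_count(cfg.n))))
    return h


# ---------------------------------------------------------------------------
# embedding entropies

_CHUNK = 512  # rows per block in pairwise-distance accumulation


def _match_counts(x: np.ndarray, m: int, tol: float) -> tuple[int, int]:
    """Pair counts (B at length m, A at length m+1) over the N-m templates
    that admit an (m+1)-sample extension; self-matches excluded."""
    n_t = x.size - m
    xm = sliding_window_view(x, m)[:n_t]
    ext = x[m:]  # (m+1)-th element of each template
    b = 0
    a = 0
    for i0 in range(0, n_t, _CHUNK):
        i1 = min(i0 + _CHUNK, n_t)
        d = np.abs(xm[i0:i1, None, :] - xm[None, :, :]).max(axis=2)
        bm = d <= tol
        am = bm & (np.abs(ext[i0:i1, None] - ext[None, :]) <= tol)
        b += int(bm.sum()) - (i1 - i0)  # subtract diagonal self-matches
        a += int(am.sum()) - (i1 - i0)
    return a // 2, b // 2

def sample_entropy(x, cfg: SEnConfig = SEnConfig()) -> float:
    """Sample entropy ``-log(A/B)`` with Chebyshev matching.

    ``B`` counts template pairs of length ``m`` within ``r * SD(x)``,
    ``A`` the pairs still matching at length ``m + 1``.  Returns ``nan``
    when either count is zero (the ratio is undefined); callers that
    iterate over windows are expected to tag, not drop, such values.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= cfg.m + 1:
        raise ValueError(f"need more than m+1={cfg.m + 1} samples, got {x.size}")
    sd = float(x.std())
    if sd == 0.0:
        return 0.0  # constant series: all templates match at every length
    a, b = _match_counts(x, cfg.m, cfg.r * sd)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def quadratic_sample_entropy(x, cfg: QSEnConfig = QSEnConfig()) -> float:
    """Sample entropy normalised by the matching-region volume:
    ``QSEn = SEn + log(2r)``.  Propagates ``nan`` from SEn."""
    sen = sample_entropy(x, SEnConfig(m=cfg.m, r=cfg.r))
    return sen + math.log(2.0 * cfg.r)


def _fuzzy_phi(vec: np.ndarray, n_exp: int, tol: float) -> float:
    n_v = vec.shape[0]
    total = 0.0
    for i0 in range(0, n_v, _CHUNK):
        i1 = min(i0 + _CHUNK, n_v)
        d = np.abs(vec[i0:i1, None, :] - vec[None, :, :]).max(axis=2)
        sim = np.exp(-(d ** n_exp) / tol)
        total += float(sim.sum()) - (i1 - i0)  # drop self-similarity (exactly 1)
    return total / (n_v * (n_v - 1))


def fuzzy_entropy(x, cfg: FEnConfig = FEnConfig()) -> float:
    """Fuzzy entropy ``-log(phi_{m+1} / phi_m)``.

    ``phi_m`` is the average pairwise similarity ``exp(-d^n / r)`` over
    baseline-removed template vectors (each vector minus its own mean),
    d the Chebyshev distance, tolerance ``r * SD(x)``.  Always defined:
    similarities are strictly positive.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= cfg.m + 1:
        raise ValueError(f"need more than m+1={cfg.m + 1} samples, got {x.size}")
    sd = float(x.std())
    if sd == 0.0:
        return 0.0
    tol = cfg.r * sd
    n_t = x.size - cfg.m
    phis = []
    for length in (cfg.m, cfg.m + 1):
        vec = sliding_window_view(x, length)[:n_t].astype(float)
        if cfg.remove_baseline:
            vec = vec - vec.mean(axis=1, keepdims=True)
        phis.append(_fuzzy_phi(vec, cfg.n, tol))
    return -math.log(phis[1] / phis[0])


# ---------------------------------------------------------------------------
# dispatch and parameter grids

_DISPATCH = {
    PEnConfig: permutation_entropy,
    MPEnConfig: modified_permutation_entropy,
    SEnConfig: sample_entropy,
    QSEnConfig: quadratic_sample_entropy,
    FEnConfig: fuzzy_entropy,
}

_FAMILY = {
    PEnConfig: "PEn",
    MPEnConfig: "MPEn",
    SEnConfig: "SEn",
    QSEnConfig: "QSEn",
    FEnConfig: "FEn",
}


def compute_entropy(x, cfg: EntropyConfig) -> float:
    """Evaluate any estimator configuration on a sequence."""
    return _DISPATCH[type(cfg)](x, cfg)


def config_family(cfg: EntropyConfig) -> str:
    """Algorithm family tag ('PEn', 'MPEn', 'SEn', 'QSEn', 'FEn')."""
    return _FAMILY[type(cfg)]


def config_name(cfg: EntropyConfig) -> str:
    """Canonical column name, e.g. ``'SEn(m=2,r=0.2)'``."""
    fam = config_family(cfg)
    if isinstance(cfg, (PEnConfig, MPEnConfig)):
        return f"{fam}(n={cfg.n})"
    if isinstance(cfg, (SEnConfig, QSEnConfig)):
        return f"{fam}(m={cfg.m},r={cfg.r:g})"
    return f"{fam}(n={cfg.n},m={cfg.m},r={cfg.r:g})"


#: QSEn tolerance presets: "methods" is the grid stated with the
#: algorithm definition, "results" the wider grid used when reporting.
QSEN_R_PRESETS = {"methods": (0.2, 0.4, 0.6, 0.8), "results": (0.4, 0.6, 0.8, 1.0)}


def default_grid(qsen_preset: str = "methods") -> list[EntropyConfig]:
    """The full 47-configuration study grid.

    4 PEn orders + 3 MPEn orders + 8 SEn + 8 QSEn + 24 FEn settings.
    """
    grid: list[EntropyConfig] = []
    grid += [PEnConfig(n=n) for n in (3, 4, 5, 6)]
    grid += [MPEnConfig(n=n) for n in (3, 4, 5)]
    grid += [SEnConfig(m=m, r=r) for m in (1, 2) for r in (0.1, 0.15, 0.2, 0.25)]
    grid += [QSEnConfig(m=m, r=r) for m in (1, 2) for r in QSEN_R_PRESETS[qsen_preset]]
    grid += [
        FEnConfig(n=n, m=m, r=r)
        for n in (1, 2, 3)
        for m in (1, 2)
        for r in (0.1, 0.15, 0.2, 0.25)
    ]
    return grid
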