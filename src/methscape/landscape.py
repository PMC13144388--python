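"""Per-window Ising potential-energy landscapes and per-region methylation
level distributions.

A window's landscape is the maximum-likelihood fit of the three-parameter
chain model (alpha, beta, gamma): field ``a_n = alpha + beta * rho_n`` with
rho_n the local CpG density (CpGs within +/-500 bp, per kb), and coupling
``c_n = gamma * 100 / max(d_n, 10)`` with d_n the bp distance between
neighboring CpGs.  From a fitted window, each 150-bp analysis region gets the
exact distribution ``P_L`` of its methylation level L in {0, 1/N, ..., 1},
its mean methylation level (MML) and its normalized methylation entropy
(NME = Shannon entropy / log2(N+1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _ising
from .genome_io import REGIONS_PER_WINDOW, GenomePartition, ReadMatrix, WindowInfo

logger = logging.getLogger(__name__)

PARAM_BOUNDS = (np.array([-5.0, -20.0, -5.0]), np.array([5.0, 20.0, 5.0]))
DEFAULT_STARTS = np.array(
    [
        [0.0, 0.0, 0.0],
        [2.0, 0.0, 0.5],
        [-2.0, 0.0, 0.5],
        [0.0, 0.0, -0.5],
    ]
)
MIN_READS = 5


@dataclass(frozen=True)
class IsingParameters:
    alpha: float
    beta: float
    gamma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    def fields(self, window: WindowInfo) -> tuple[np.ndarray, np.ndarray]:
        """Per-site fields a_n and per-pair couplings c_n for a window."""
        a = self.alpha + self.beta * window.rho
        c = self.gamma * window.w
        return a, c


@dataclass
class FitResult:
    params: IsingParameters | None
    log_likelihood: float
    converged: bool
    at_boundary: bool
    n_reads: int
    estimated: bool

    @classmethod
    def not_estimated(cls, n_reads: int) -> "FitResult":
        return cls(None, np.nan, False, False, n_reads, False)


@dataclass
class LevelDistribution:
    """Distribution of the methylation level over {0, 1/N, ..., 1}."""

    n_cpgs: int
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.size != self.n_cpgs + 1:
            raise ValueError("need N+1 probabilities for N CpGs")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probabilities = np.clip(p, 0.0, None)

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.n_cpgs + 1) / self.n_cpgs

    @property
    def mml(self) -> float:
        return mml(self)

    @property
    def nme(self) -> float:
        return nme(self)


def mml(dist: LevelDistribution) -> float:
    """Mean methylation level: E[L] = sum_l l * P_L(l)."""
    return float(np.dot(dist.levels, dist.probabilities))


def nme(dist: LevelDistribution) -> float:
    """Normalized methylation entropy:
    -(1/log2(N+1)) * sum_l P_L(l) log2 P_L(l), with 0 log 0 = 0.

    1 when all N+1 levels are equally likely (fully stochastic), 0 when a
    single level carries all mass (perfectly ordered)."""
    p = dist.probabilities
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log2(nz)))
    return h / np.log2(dist.n_cpgs + 1)


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------


def ising_log_likelihood(
    params: IsingParameters, read_matrix: ReadMatrix, window: WindowInfo
) -> float:
    """Log-likelihood of the window's reads: each read contributes the log
    marginal probability of its observed contiguous CpG run under the window
    chain, with the unobserved prefix and suffix marginalized out."""
    arr = params.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite Ising parameters")
    if window.n_cpgs < 1:
        raise ValueError("window has no CpGs")
    if read_matrix.n_reads == 0:
        return 0.0
    a, c = params.fields(window)
    return float(
        _ising.window_log_likelihood(
            a, c, read_matrix.starts, read_matrix.offsets, read_matrix.flat
        )
    )


def fit_window(
    read_matrix: ReadMatrix,
    window: WindowInfo,
    min_reads: int = MIN_READS,
    starts: np.ndarray = DEFAULT_STARTS,
    bounds: tuple[np.ndarray, np.ndarray] = PARAM_BOUNDS,
    fixed: dict[str, float] | None = None,
    fatol: float = 1e-6,
    xatol: float = 1e-4,
    max_iter: int = 400,
) -> FitResult:
    """Maximum-likelihood landscape for one window.

    Runs a bounded derivative-free simplex search from several deterministic
    starting points and keeps the best objective (ties broken by lowest start
    index).  Windows with fewer than ``min_reads`` informative reads are
    flagged not-estimated and excluded downstream; this is not an error.
    ``fixed`` may pin any of alpha/beta/gamma to a constant (the remaining
    parameters are profiled over).
    """
    n_reads = read_matrix.n_reads
    if window.n_cpgs < 1 or n_reads < min_reads:
        return FitResult.not_estimated(n_reads)
    free_mask = np.array([True, True, True])
    x_fixed = np.zeros(3)
    if fixed:
        names = ["alpha", "beta", "gamma"]
        for k, v in fixed.items():
            i = names.index(k)
            free_mask[i] = False
            x_fixed[i] = float(v)
    lb, ub = bounds
    theta, nll, conv = _ising.fit_window_multistart(
        np.asarray(starts, dtype=np.float64),
        lb,
        ub,
        free_mask,
        x_fixed,
        window.rho,
        window.w,
        read_matrix.starts,
        read_matrix.offsets,
        read_matrix.flat,
        fatol,
        xatol,
        max_iter,
    )
    at_boundary = bool(
        np.any(free_mask & ((theta <= lb + 1e-3) | (theta >= ub - 1e-3)))
    )
    return FitResult(
        params=IsingParameters(*theta),
        log_likelihood=-float(nll),
        converged=bool(conv),
        at_boundary=at_boundary,
        n_reads=n_reads,
        estimated=True,
    )


# ---------------------------------------------------------------------------
# Level distributions
# ---------------------------------------------------------------------------


def level_distribution(
    params: IsingParameters, window: WindowInfo, region_index: int
) -> LevelDistribution | None:
    """Exact P_L for one analysis region, marginalizing the window CpGs
    outside the region by dynamic programming over (spin, methylated count).
    Returns None for regions without CpGs (excluded downstream)."""
    lo, hi = window.region_cpg_slice(region_index)
    if hi <= lo:
        return None
    a, c = params.fields(window)
    p = _ising.level_count_distribution(a, c, lo, hi)
    return LevelDistribution(hi - lo, p / p.sum())


def window_level_distributions(
    params: IsingParameters, window: WindowInfo
) -> list[LevelDistribution | None]:
    """P_L for all analysis regions of a window (None where N=0)."""
    return [level_distribution(params, window, j) for j in range(REGIONS_PER_WINDOW)]


def fit_all_windows(
    matrices: dict[int, ReadMatrix],
    partition: GenomePartition,
    min_reads: int = MIN_READS,
    **kwargs,
) -> dict[int, FitResult]:
    """Fit every window that has read data; windows with no matrix or too few
    reads are flagged not-estimated."""
    out: dict[int, FitResult] = {}
    for win in partition.windows:
        rm = matrices.get(win.index)
        if rm is None or win.n_cpgs == 0:
            out[win.index] = FitResult.not_estimated(0 if rm is None else rm.n_reads)
            continue
        out[win.index] = fit_window(rm, win, min_reads=min_reads, **kwargs)
    return out


def region_level_table(
    fits: dict[int, FitResult], partition: GenomePartition
) -> "RegionLevels":
    """Flatten fitted windows into per-region arrays of P_L / MML / NME."""
    n_regions = partition.n_regions
    mml_arr = np.full(n_regions, np.nan)
    nme_arr = np.full(n_regions, np.nan)
    n_arr = np.zeros(n_regions, dtype=np.int32)
    dists: dict[int, np.ndarray] = {}
    for win in partition.windows:
        fit = fits.get(win.index)
        if fit is None or not fit.estimated:
            continue
        for j in range(REGIONS_PER_WINDOW):
            d = level_distribution(fit.params, win, j)
            if d is None:
                continue
            rid = partition.region_id(win.index, j)
            dists[rid] = d.probabilities
            n_arr[rid] = d.n_cpgs
            mml_arr[rid] = d.mml
            nme_arr[rid] = d.nme
    return RegionLevels(mml_arr, nme_arr, n_arr, dists)


@dataclass
class RegionLevels:
    """Per-sample (or per-group) region-level summaries on the global grid."""

    mml: np.ndarray
    nme: np.ndarray
    n_cpgs: np.ndarray
    distributions: dict[int, np.ndarray] = field(repr=False, default_factory=dict)

    def covered(self) -> np.ndarray:
        return ~np.isnan(self.mml)


# ---------------------------------------------------------------------------
# Brute-force enumeration reference (independent slow path, N <= ~16)
# ---------------------------------------------------------------------------


def _all_configurations(n: int) -> np.ndarray:
    """2^n x n matrix of all binary configurations, row i = binary of i."""
    idx = np.arange(2**n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(np.int8)


def enumerate_configurations(params: IsingParameters, window: WindowInfo) -> np.ndarray:
    """All 2^N configuration probabilities by direct summation of the
    Boltzmann weights.  An independent (non-transfer-matrix) reference path;
    usable only for small windows."""
    n = window.n_cpgs
    if n > 20:
        raise ValueError("enumeration limited to N <= 20")
    a, c = params.fields(window)
    s = 2.0 * _all_configurations(n) - 1.0
    e = s @ a
    if n > 1:
        e += (s[:, :-1] * s[:, 1:]) @ c
    e -= e.max()  # overflow guard; cancels in the normalization
    probs = np.exp(e)
    return probs / probs.sum()


def enumerate_level_distribution(
    params: IsingParameters, window: WindowInfo, region_index: int
) -> LevelDistribution | None:
    lo, hi = window.region_cpg_slice(region_index)
    if hi <= lo:
        return None
    n = window.n_cpgs
    probs = enumerate_configurations(params, window)
    counts = _all_configurations(n)[:, lo:hi].sum(axis=1)
    out = np.bincount(counts, weights=probs, minlength=hi - lo + 1)
    return LevelDistribution(hi - lo, out / out.sum())


def enumerate_read_log_likelihood(
    params: IsingParameters, read_matrix: ReadMatrix, window: WindowInfo
) -> float:
    """Reference likelihood: sums full-configuration probabilities compatible
    with each read's observed run."""
    n = window.n_cpgs
    probs = enumerate_configurations(params, window)
    configs = _all_configurations(n)
    total = 0.0
    for r in range(read_matrix.n_reads):
        seg = read_matrix.flat[read_matrix.offsets[r] : read_matrix.offsets[r + 1]]
        u = read_matrix.starts[r]
        match = np.all(configs[:, u : u + seg.size] == seg, axis=1)
        total += np.log(probs[match].sum())
    return float(total)
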