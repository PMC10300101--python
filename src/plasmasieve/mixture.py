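"""Four-component beta-mixture model of variant allele frequencies.

Tumor-only panel calls mix four VAF regimes: sequencing errors (VAF near
0), true somatic variants (low VAF set by tumor fraction), germline
heterozygous (near 0.5) and germline homozygous (near 1).  An EM-fitted
mixture of four beta distributions separates these regimes; the VAF ranges
where the two germline components dominate, combined with dbSNP membership,
flag likely germline variants for removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import betaln, logsumexp
from scipy.stats import beta as beta_dist

from .variant_io import MembershipSet, VariantCall

ROLES = ("error", "somatic", "germline_het", "germline_hom")

#: Role-biased initial component means; concentration 20, equal weights.
DEFAULT_INIT_MEANS = (0.005, 0.10, 0.50, 0.95)
DEFAULT_INIT_CONCENTRATION = 20.0

_EPS = 1e-4


@dataclass
class BetaMixtureModel:
    alphas: np.ndarray   # shape (k,)
    betas: np.ndarray    # shape (k,)
    weights: np.ndarray  # shape (k,), sums to 1
    roles: tuple[str, ...]  # parallel to components, assigned by sorted means
    n_iter: int = 0
    log_likelihood: float = float("-inf")
    ll_trace: list[float] = field(default_factory=list)

    @property
    def means(self) -> np.ndarray:
        return self.alphas / (self.alphas + self.betas)

    def component(self, role: str) -> int:
        return self.roles.index(role)

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Per-component weighted log densities, shape (n, k)."""
        x = np.asarray(x, dtype=float)[:, None]
        return np.log(self.weights)[None, :] + beta_dist.logpdf(
            x, self.alphas[None, :], self.betas[None, :]
        )

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Component responsibilities for each observation, shape (n, k)."""
        logd = self.log_density(np.atleast_1d(np.asarray(x, dtype=float)))
        return np.exp(logd - logsumexp(logd, axis=1, keepdims=True))


@dataclass(frozen=True)
class GermlineIntervals:
    """VAF ranges assigned to the germline components.

    The heterozygous range is half-open at its upper end so the two ranges
    partition contiguously at their shared boundary.
    """

    het_low: float
    het_high: float
    hom_low: float
    hom_high: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.het_low < self.het_high <= self.hom_low < self.hom_high <= 1.0:
            raise ValueError("germline intervals must be ordered within (0, 1]")

    def contains(self, vaf: float) -> bool:
        return (self.het_low <= vaf < self.het_high) or (self.hom_low <= vaf <= self.hom_high)


#: Published operating intervals, usable without refitting on small panels.
DEFAULT_GERMLINE_INTERVALS = GermlineIntervals(het_low=0.36, het_high=0.67, hom_low=0.67, hom_high=1.0)


def _init_params(
    means: tuple[float, ...], concentration: float
) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(means, dtype=float)
    return m * concentration, (1.0 - m) * concentration


def _component_objective(a: float, b: float, n_k: float, s_logx: float, s_log1mx: float) -> float:
    """Expected complete-data log-likelihood contribution of one component."""
    return (a - 1.0) * s_logx + (b - 1.0) * s_log1mx - n_k * betaln(a, b)


def _mstep_component(
    a0: float, b0: float, n_k: float, s_logx: float, s_log1mx: float
) -> tuple[float, float]:
    """Weighted beta MLE; falls back to the current parameters when the
    optimizer does not improve, preserving EM monotonicity."""
    if n_k <= 1e-12:
        return a0, b0

    def neg(logp: np.ndarray) -> float:
        a, b = np.exp(logp)
        return -_component_objective(a, b, n_k, s_logx, s_log1mx)

    res = optimize.minimize(neg, np.log([a0, b0]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 500})
    a, b = np.exp(res.x)
    if _component_objective(a, b, n_k, s_logx, s_log1mx) >= _component_objective(
        a0, b0, n_k, s_logx, s_log1mx
    ):
        return float(a), float(b)
    return a0, b0


def fit_beta_mixture(
    vafs: np.ndarray,
    k: int = 4,
    init_means: tuple[float, ...] = DEFAULT_INIT_MEANS,
    init_concentration: float = DEFAULT_INIT_CONCENTRATION,
    tol: float = 1e-7,
    max_iter: int = 500,
    seed: int | None = None,
) -> BetaMixtureModel:
    """EM fit of a k-component beta mixture to VAF observations.

    Observations are clamped to [1e-4, 1-1e-4] (beta support is open).
    Components are initialized at role-biased means and, after convergence
    (relative log-likelihood change < ``tol``), labeled error / somatic /
    germline-het / germline-hom in order of increasing fitted mean.  The fit
    is deterministic given data and initialization; ``seed`` is accepted for
    interface symmetry with stochastic fitters.
    """
    x = np.clip(np.asarray(vafs, dtype=float), _EPS, 1.0 - _EPS)
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} observations, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate data: all VAFs identical")
    if len(init_means) != k:
        raise ValueError("one initial mean per component required")

    alphas, betas = _init_params(init_means, init_concentration)
    weights = np.full(k, 1.0 / k)
    logx, log1mx = np.log(x), np.log1p(-x)

    ll_prev = -np.inf
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logd = (
            np.log(weights)[None, :]
            + (alphas - 1.0)[None, :] * logx[:, None]
            + (betas - 1.0)[None, :] * log1mx[:, None]
            - betaln(alphas, betas)[None, :]
        )
        norm = logsumexp(logd, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(logd - norm[:, None])
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            break
        ll_prev = ll
        n_k = resp.sum(axis=0)
        weights = n_k / x.size
        weights = np.maximum(weights, 1e-12)
        weights /= weights.sum()
        for j in range(k):
            alphas[j], betas[j] = _mstep_component(
                alphas[j], betas[j], n_k[j],
                float(resp[:, j] @ logx), float(resp[:, j] @ log1mx),
            )

    order = np.argsort(alphas / (alphas + betas))
    roles = tuple(ROLES[i] if k == 4 else f"component_{i}" for i in range(k))
    return BetaMixtureModel(
        alphas=alphas[order],
        betas=betas[order],
        weights=weights[order],
        roles=roles,
        n_iter=n_iter,
        log_likelihood=trace[-1],
        ll_trace=trace,
    )


def _argmax_role(model: BetaMixtureModel, x: np.ndarray) -> np.ndarray:
    return np.argmax(model.log_density(x), axis=1)


def derive_intervals(
    model: BetaMixtureModel, step: float = 1e-3, refine_tol: float = 1e-6
) -> GermlineIntervals:
    """VAF ranges where each germline component is the most likely origin.

    A dense scan over (0, 1) finds where the het / hom components attain the
    highest posterior; boundaries are then refined by bisection between
    neighbouring grid points, so each boundary sits at the posterior
    crossover of adjacent components (within ``refine_tol``).
    """
    het, hom = model.component("germline_het"), model.component("germline_hom")
    grid = np.arange(step, 1.0, step)
    winner = _argmax_role(model, grid)

    def contiguous_range(comp: int) -> tuple[float, float]:
        idx = np.flatnonzero(winner == comp)
        if idx.size == 0:
            raise ValueError(
                f"component {model.roles[comp]!r} is never the most likely origin; "
                f"fitted means {np.round(model.means, 4)}, weights {np.round(model.weights, 4)}"
            )
        # take the run containing the component mean (or the longest run)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        mean = model.means[comp]
        for run in runs:
            if grid[run[0]] - step <= mean <= grid[run[-1]] + step:
                idx = run
                break
        else:
            idx = max(runs, key=len)
        return grid[idx[0]], grid[idx[-1]]

    def refine(lo: float, hi: float, comp: int, want_left_in: bool) -> float:
        """Bisect for the crossover where `comp` starts/stops winning."""
        for _ in range(60):
            if hi - lo < refine_tol:
                break
            mid = 0.5 * (lo + hi)
            if (_argmax_role(model, np.array([mid]))[0] == comp) == want_left_in:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    het_lo_g, het_hi_g = contiguous_range(het)
    hom_lo_g, hom_hi_g = contiguous_range(hom)
    het_low = refine(max(het_lo_g - step, step / 2), het_lo_g, het, True)
    het_high = refine(het_hi_g, min(het_hi_g + step, 1.0 - step / 2), het, False)
    hom_low = refine(max(hom_lo_g - step, het_high), hom_lo_g, hom, True)
    hom_high = 1.0 if hom_hi_g >= grid[-1] else refine(
        hom_hi_g, min(hom_hi_g + step, 1.0 - step / 2), hom, False
    )
    hom_low = max(hom_low, het_high)  # shared boundary: ranges partition
    return GermlineIntervals(het_low=het_low, het_high=het_high,
                             hom_low=hom_low, hom_high=hom_high)


def flag_germline(
    call: VariantCall,
    intervals: GermlineIntervals,
    dbsnp: MembershipSet,
) -> bool:
    """True (remove) iff the VAF lies in a germline range AND the variant is
    a known polymorphism (dbSNP member)."""
    return intervals.contains(call.vaf) and call.key in dbsnp
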