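"""Cross-population composite-likelihood sweep scan (XP-CLR style).

Model
-----
Let p1 be the allele frequency in a reference population and x the frequency
in a diverged "object" population. Under neutral drift, x | p1 is modelled as
Normal(p1, omega * p1 * (1 - p1)) truncated to (0, 1) with the tail mass
placed as point masses at 0 and 1 (loss / fixation). omega is a single
genome-wide drift scale estimated by a moment estimator.

Under a hitchhiking sweep at genetic distance d (Morgans) from a focal site,
a linked lineage is captured by the sweeping haplotype with probability
kappa = exp(-d / sigma). The neutral frequency y is transformed to
x = kappa + (1 - kappa) * y with probability y, else x = (1 - kappa) * y.

The observed alt count m2 out of n2 sampled chromosomes is binomial given x;
site likelihoods marginalize x by Gauss-Legendre quadrature restricted to the
effective support of the drift density, with the discrete weight set
renormalized so each site likelihood is an exact probability distribution
over m2 at any quadrature size.

The scan slides a window of fixed genetic width over a bp grid, down-weights
clusters of correlated SNPs (weight 1/m_k where m_k counts window SNPs with
r^2 >= cutoff to SNP k), and reports the composite likelihood-ratio score
S = 2 * [max_sigma sum_k w_k * ll_sweep - sum_k w_k * ll_neutral]; the sigma
grid contains a neutral entry so S >= 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from .genmap import GeneticMap
from .variants import AlleleCounts

__all__ = [
    "DriftModel",
    "ScanParams",
    "estimate_omega",
    "neutral_site_loglik",
    "sweep_site_loglik",
    "snp_weights",
    "xpclr_scan",
]

log = logging.getLogger(__name__)

LOG_FLOOR = -745.0  # log of the smallest positive double
_POINT_MASS_SD = 1e-5  # below this drift SD the density is treated as a spike


@lru_cache(maxsize=8)
def _leggauss(n_quad: int):
    return np.polynomial.legendre.leggauss(n_quad)


@dataclass
class DriftModel:
    """Genome-wide drift variance scale of the object population."""

    omega: float

    def __post_init__(self):
        if not np.isfinite(self.omega) or self.omega < 0:
            raise ValueError(f"omega must be finite and >= 0, got {self.omega}")


def default_sigma_grid() -> np.ndarray:
    """12 log-spaced sweep scales spanning ~kb to ~Mb footprints at 1 cM/Mb."""
    return np.logspace(-5, -1, 12)


@dataclass
class ScanParams:
    """Scan settings; defaults follow the common usage of the original tool
    (-w1 0.005 100 2000 / -p1 0.7)."""

    window_morgans: float = 0.005
    max_snps: int = 100
    grid_bp: int = 2000
    r2_cutoff: float = 0.7
    sigma_grid: np.ndarray = field(default_factory=default_sigma_grid)
    n_quad: int = 64
    seed: int = 0
    # per-site sweep log-likelihoods are tabulated at this many kappa knots
    # and linearly interpolated during the scan; 0 disables the table and
    # evaluates every (site, sigma) pair exactly
    interp_knots: int = 129

    def __post_init__(self):
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=float)
        if (
            self.window_morgans <= 0
            or self.max_snps <= 0
            or self.grid_bp <= 0
            or self.r2_cutoff <= 0
            or self.n_quad <= 0
            or np.any(self.sigma_grid <= 0)
            or self.interp_knots < 0
            or self.interp_knots == 1
        ):
            raise ValueError("invalid scan parameters")


# ---------------------------------------------------------------------------
# drift-scale estimation
# ---------------------------------------------------------------------------


def estimate_omega(counts_ref: AlleleCounts, counts_obj: AlleleCounts) -> DriftModel:
    """Moment estimator of the drift scale omega.

    Per site: [(p1-p2)^2 - p1*q1/(n1-1) - p2*q2/(n2-1)] / [p1*q1*n1/(n1-1)],
    averaged over sites polymorphic in the reference population. The sampling
    corrections make numerator and denominator unbiased for (p1-p2)^2 and
    p1*q1 respectively; negative site terms are retained so the average stays
    unbiased, and the final estimate is floored at 0.
    """
    m1, n1 = counts_ref.m.astype(float), counts_ref.n.astype(float)
    m2, n2 = counts_obj.m.astype(float), counts_obj.n.astype(float)
    usable = (n1 >= 2) & (n2 >= 2) & (m1 > 0) & (m1 < n1)
    if not np.any(usable):
        raise ValueError("no usable sites (all fixed in reference or uncalled)")
    if usable.sum() < 1000:
        warnings.warn(
            f"only {int(usable.sum())} usable sites; omega estimate may be noisy",
            stacklevel=2,
        )
    p1, p2 = m1 / n1, m2 / n2
    q1, q2 = 1 - p1, 1 - p2
    num = (p1 - p2) ** 2 - p1 * q1 / (n1 - 1) - p2 * q2 / (n2 - 1)
    den = p1 * q1 * n1 / (n1 - 1)
    omega = float(np.mean(num[usable] / den[usable]))
    return DriftModel(omega=max(omega, 0.0))


# ---------------------------------------------------------------------------
# site likelihoods
# ---------------------------------------------------------------------------


def _drift_atoms(p1: float, omega: float, n_quad: int):
    """Discretize the drift distribution of x | p1 into probability atoms.

    Returns (y, w): atom locations in [0, 1] and probabilities summing to 1.
    Interior atoms are Gauss-Legendre nodes on the +/- 8 SD support of the
    Gaussian density; boundary point masses are the Gaussian tail integrals.
    The whole set is renormalized so downstream marginals are exact pmfs.
    """
    sd = np.sqrt(omega * p1 * (1.0 - p1))
    if sd < _POINT_MASS_SD:
        return np.array([p1]), np.array([1.0])
    lo = max(0.0, p1 - 8.0 * sd)
    hi = min(1.0, p1 + 8.0 * sd)
    nodes, wq = _leggauss(n_quad)
    y = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    scale = 0.5 * (hi - lo)
    dens = np.exp(-0.5 * ((y - p1) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))
    w = wq * scale * dens
    mass0 = ndtr((0.0 - p1) / sd)  # drift to loss
    mass1 = ndtr((p1 - 1.0) / sd)  # drift to fixation
    y = np.concatenate([[0.0], y, [1.0]])
    w = np.concatenate([[mass0], w, [mass1]])
    total = w.sum()
    if total <= 0:
        raise FloatingPointError("degenerate drift discretization")
    return y, w / total


def _log_binom_pmf(m: int, n: int, x: np.ndarray) -> np.ndarray:
    """log C(n,m) + m log x + (n-m) log(1-x), with 0*log(0) = 0."""
    x = np.asarray(x, dtype=float)
    logc = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(m == 0, 0.0, m * np.log(x))
        t2 = np.where(n - m == 0, 0.0, (n - m) * np.log1p(-x))
    out = logc + t1 + t2
    return np.where(np.isnan(out), -np.inf, out)


def _binom_pmf(m, n, x):
    return np.exp(_log_binom_pmf(m, n, x))


def _clamp_p1(p_hat: float, n1: int) -> float:
    lo = 1.0 / (2.0 * n1)
    return min(max(p_hat, lo), 1.0 - lo)


def neutral_site_loglik(
    m2: int, n2: int, p1: float, model: DriftModel, n_quad: int = 64
) -> float:
    """Log marginal probability of m2 alt alleles out of n2 under drift."""
    if n2 < 1 or not (0 <= m2 <= n2):
        raise ValueError("need 0 <= m2 <= n2, n2 >= 1")
    if not (0.0 < p1 < 1.0):
        raise ValueError("p1 must be in (0, 1); clamp fixed sites upstream")
    y, w = _drift_atoms(p1, model.omega, n_quad)
    pmf = float(np.sum(w * _binom_pmf(m2, n2, y)))
    return float(np.log(pmf)) if pmf > 0 else LOG_FLOOR


def sweep_site_loglik(
    m2: int,
    n2: int,
    p1: float,
    model: DriftModel,
    kappa: float,
    n_quad: int = 64,
) -> float:
    """Log marginal probability of m2 under the hitchhiking transform.

    The marginal is an expectation over the neutral atoms y:
    E_y[ y * Binom(m2; n2, kappa + (1-kappa) y) + (1-y) * Binom(m2; n2, (1-kappa) y) ].
    kappa = 0 reduces exactly to the neutral likelihood; kappa = 1 places all
    mass on loss/fixation, so intermediate counts get the log floor.
    """
    if not (0.0 <= kappa <= 1.0):
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    if not (0.0 < p1 < 1.0):
        raise ValueError("p1 must be in (0, 1); clamp fixed sites upstream")
    y, w = _drift_atoms(p1, model.omega, n_quad)
    x_cap = kappa + (1.0 - kappa) * y
    x_esc = (1.0 - kappa) * y
    pmf = float(
        np.sum(w * (y * _binom_pmf(m2, n2, x_cap) + (1.0 - y) * _binom_pmf(m2, n2, x_esc)))
    )
    return float(np.log(pmf)) if pmf > 0 else LOG_FLOOR


# ---------------------------------------------------------------------------
# LD down-weighting
# ---------------------------------------------------------------------------


def snp_weights(matrix: np.ndarray, r2_cutoff: float = 0.7) -> np.ndarray:
    """Weights 1/m_k, m_k = number of window SNPs (self included) with
    r^2 >= cutoff to SNP k.

    matrix: (n_snps, n_chromosomes) haplotype 0/1 matrix (or dosage matrix);
    r^2 is the squared Pearson correlation across chromosomes. Monomorphic
    SNPs correlate with nothing but themselves.
    """
    matrix = np.asarray(matrix, dtype=float)
    k = matrix.shape[0]
    if k == 0:
        return np.empty(0)
    sd = matrix.std(axis=1)
    poly = sd > 0
    r2 = np.zeros((k, k))
    if poly.sum() >= 2:
        with np.errstate(invalid="ignore"):
            cc = np.corrcoef(matrix[poly])
        r2[np.ix_(poly, poly)] = np.nan_to_num(cc) ** 2
    np.fill_diagonal(r2, 1.0)
    m = (r2 >= r2_cutoff).sum(axis=1)
    return 1.0 / m


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------


def _vector_sweep_loglik(m2, n2, atoms_y, atoms_w, kappa):
    """Vectorized sweep log-likelihood for one window.

    m2, n2: (K,) site counts; atoms_y/atoms_w: (K, Q); kappa: (S, K).
    Returns (S, K) log-likelihood matrix.
    """
    y = atoms_y[None, :, :]  # (1, K, Q)
    w = atoms_w[None, :, :]
    kap = kappa[:, :, None]  # (S, K, 1)
    x_cap = kap + (1.0 - kap) * y
    x_esc = (1.0 - kap) * y
    m = m2[None, :, None].astype(float)
    n = n2[None, :, None].astype(float)
    logc = (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))

    def pmf(x):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(m == 0, 0.0, m * np.log(x))
            t2 = np.where(n - m == 0, 0.0, (n - m) * np.log1p(-x))
        lp = logc + t1 + t2
        return np.exp(np.where(np.isnan(lp), -np.inf, lp))

    marg = np.sum(w * (y * pmf(x_cap) + (1.0 - y) * pmf(x_esc)), axis=2)
    with np.errstate(divide="ignore"):
        ll = np.log(marg)
    return np.maximum(ll, LOG_FLOOR)


def xpclr_scan(
    counts_ref: AlleleCounts,
    counts_obj: AlleleCounts,
    hap_obj: np.ndarray,
    positions: np.ndarray,
    genetic_map: GeneticMap,
    params: ScanParams,
    model: DriftModel,
    chrom: str = "chr",
) -> pd.DataFrame:
    """Composite-likelihood sweep scan along one chromosome.

    Returns a DataFrame with columns chrom, pos (grid point, bp), score,
    n_snps, best_sigma. Grid points with no SNPs in the window are NaN.
    Windows larger than params.max_snps are uniformly downsampled with a
    deterministic per-grid-point seed derived from params.seed.
    """
    positions = np.asarray(positions)
    n_sites = len(positions)
    if len(counts_ref) != n_sites or len(counts_obj) != n_sites:
        raise ValueError("counts and positions disagree in length")
    morgans = genetic_map.morgans(positions)
    if np.any(~np.isfinite(morgans)):
        raise ValueError("genetic map does not cover all positions")

    n1 = counts_ref.n
    usable = (counts_ref.n >= 2) & (counts_obj.n >= 2)
    p1 = np.array(
        [
            _clamp_p1(counts_ref.m[i] / counts_ref.n[i], int(n1[i])) if usable[i] else np.nan
            for i in range(n_sites)
        ]
    )

    idx_usable = np.flatnonzero(usable)
    # precompute drift atoms and neutral log-likelihood once per site
    max_q = params.n_quad + 2
    atoms_y = np.zeros((n_sites, max_q))
    atoms_w = np.zeros((n_sites, max_q))
    neutral_ll = np.full(n_sites, np.nan)
    for i in idx_usable:
        y, w = _drift_atoms(p1[i], model.omega, params.n_quad)
        atoms_y[i, : len(y)] = y
        atoms_w[i, : len(w)] = w
        pmf = float(np.sum(w * _binom_pmf(int(counts_obj.m[i]), int(counts_obj.n[i]), y)))
        neutral_ll[i] = np.log(pmf) if pmf > 0 else LOG_FLOOR

    # optional per-site sweep-likelihood table over kappa knots; knots are
    # quadratically spaced toward kappa = 1 where the likelihood varies fastest
    use_table = params.interp_knots >= 2
    if use_table:
        n_knots = params.interp_knots
        u_knots = np.linspace(0.0, 1.0, n_knots)
        kappa_knots = 1.0 - (1.0 - u_knots) ** 2
        ll_table = np.full((n_sites, n_knots), LOG_FLOOR)
        for j, kap in enumerate(kappa_knots):
            krow = np.full((1, len(idx_usable)), kap)
            ll_table[idx_usable, j] = _vector_sweep_loglik(
                counts_obj.m[idx_usable],
                counts_obj.n[idx_usable],
                atoms_y[idx_usable],
                atoms_w[idx_usable],
                krow,
            )[0]
        # the kappa = 0 knot is the neutral model; pin it exactly
        ll_table[idx_usable, 0] = neutral_ll[idx_usable]

    lo_bp = int(positions.min())
    hi_bp = int(positions.max())
    grid = np.arange(lo_bp, hi_bp + 1, params.grid_bp, dtype=np.int64)
    grid_m = genetic_map.morgans(grid)
    half = params.window_morgans / 2.0

    # High-LD partners (r^2 >= cutoff) among usable sites, precomputed once:
    # windows are contiguous runs of usable sites, so per-window weights
    # 1/m_k follow from counting each site's partners inside the run.
    hap = np.asarray(hap_obj, dtype=float)
    sd = hap.std(axis=1)
    z = np.zeros_like(hap)
    nz = sd > 0
    z[nz] = (hap[nz] - hap[nz].mean(axis=1, keepdims=True)) / (
        sd[nz, None] * np.sqrt(hap.shape[1])
    )
    partner_lists = [np.empty(0, dtype=np.int64)] * n_sites
    pos_usable_m = morgans[idx_usable]
    for a, i in enumerate(idx_usable):
        if not nz[i]:
            continue
        b_hi = np.searchsorted(pos_usable_m, pos_usable_m[a] + params.window_morgans,
                               side="right")
        cand = idx_usable[a + 1 : b_hi]
        cand = cand[nz[cand]]
        if len(cand) == 0:
            continue
        r2 = (z[cand] @ z[i]) ** 2
        hits = cand[r2 >= params.r2_cutoff]
        if len(hits):
            partner_lists[i] = np.concatenate([partner_lists[i], hits])
            for j in hits:
                partner_lists[j] = np.concatenate([partner_lists[j], [i]])
    partner_lists = [np.sort(pl) for pl in partner_lists]

    sigmas = params.sigma_grid
    scores = np.full(len(grid), np.nan)
    n_used = np.zeros(len(grid), dtype=int)
    best_sigma = np.full(len(grid), np.nan)
    # one random priority per SNP, drawn once per scan: a window keeps its
    # max_snps lowest-priority SNPs. The subset is uniform within each
    # window yet nearly identical between neighbouring grid points, so the
    # score surface is not jittered by independent per-window resampling.
    rng = np.random.default_rng(params.seed & 0x7FFFFFFF)
    priority = rng.permutation(n_sites)

    m_usable = morgans[idx_usable]
    for g in range(len(grid)):
        lo = np.searchsorted(m_usable, grid_m[g] - half, side="left")
        hi = np.searchsorted(m_usable, grid_m[g] + half, side="right")
        win = idx_usable[lo:hi]
        if len(win) == 0:
            continue
        if len(win) > params.max_snps:
            keep = np.argpartition(priority[win], params.max_snps)[: params.max_snps]
            win = np.sort(win[keep])
            w_ld = snp_weights(hap_obj[win], params.r2_cutoff)
        else:
            m_k = np.ones(len(win))
            lo_i, hi_i = win[0], win[-1]
            for k, i in enumerate(win):
                pl = partner_lists[i]
                if len(pl):
                    m_k[k] += np.searchsorted(pl, hi_i, side="right") - np.searchsorted(
                        pl, lo_i, side="left"
                    )
            w_ld = 1.0 / m_k
        d = np.abs(morgans[win] - grid_m[g])
        kappa = np.exp(-d[None, :] / sigmas[:, None])  # (S, K)
        if use_table:
            u = (1.0 - np.sqrt(1.0 - kappa)) * (n_knots - 1)
            j0 = np.minimum(u.astype(int), n_knots - 2)
            frac = u - j0
            wrow = win[None, :]
            ll_sweep = (
                ll_table[wrow, j0] * (1.0 - frac) + ll_table[wrow, j0 + 1] * frac
            )
        else:
            ll_sweep = _vector_sweep_loglik(
                counts_obj.m[win],
                counts_obj.n[win],
                atoms_y[win],
                atoms_w[win],
                kappa,
            )
        sweep_sums = ll_sweep @ w_ld  # (S,)
        neutral_sum = float(neutral_ll[win] @ w_ld)
        # the neutral entry (kappa == 0) is part of the hypothesis grid
        all_sums = np.concatenate([sweep_sums, [neutral_sum]])
        best = int(np.argmax(all_sums))
        scores[g] = 2.0 * (all_sums[best] - neutral_sum)
        n_used[g] = len(win)
        best_sigma[g] = sigmas[best] if best < len(sigmas) else np.inf
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": grid,
            "score": scores,
            "n_snps": n_used,
            "best_sigma": best_sigma,
        }
    )
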