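"""Compositional correlation inference from count tables (SparCC-style).

Relative abundances are compositional: because proportions sum to one, naive
Pearson correlations between taxa are biased negative.  The log-ratio
variance t_ij = Var(log x_i / x_j) is sub-compositionally coherent and
decomposes as

    t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j,

where w_i^2 are the variances of the latent (unconstrained) "basis"
log-abundances and rho_ij their correlations.  Under the sparsity assumption
(most rho_ij ~ 0) summing t_ij over j gives a linear system for the basis
variances; the strongest correlated pairs are then excluded one at a time and
the system re-solved, so that a few strong associations do not distort the
variance estimates.  Counts are converted to strictly positive fractions by
Dirichlet resampling (posterior with a uniform prior), the procedure is
repeated ``n_inner`` times, and the element-wise median is reported.
Pseudo p-values come from permuting each taxon's counts across samples,
which breaks all associations while preserving marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OtuTable

__all__ = [
    "LogRatioVariance",
    "CorrelationEstimate",
    "logratio_variance_matrix",
    "estimate_basis_correlations",
    "sparcc",
    "sparcc_pvalues",
]

_OMEGA2_FLOOR = 1e-12


@dataclass
class LogRatioVariance:
    taxon_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = len(self.taxon_ids)
        if self.values.shape != (d, d):
            raise ValueError("log-ratio variance matrix must be square over taxa")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("log-ratio variance matrix must be symmetric")


@dataclass
class CorrelationEstimate:
    taxon_ids: list[str]
    rho: np.ndarray
    pvals: np.ndarray | None = None
    n_inner: int = 0
    n_boot: int = 0
    seed: int = 0


def _as_matrix(counts) -> tuple[list[str], np.ndarray]:
    if isinstance(counts, OtuTable):
        if counts.kind != "counts":
            raise ValueError("sparcc operates on the counts table")
        return list(counts.taxon_ids), counts.values
    arr = np.asarray(counts, dtype=float)
    return [f"T{j}" for j in range(arr.shape[1])], arr


def logratio_variance_matrix(fractions) -> LogRatioVariance:
    """t_ij = sample variance (n-1 denominator) of log(x_i) - log(x_j).

    Computed from the covariance matrix of the log fractions:
    t_ij = C_ii + C_jj - 2 C_ij.
    """
    if isinstance(fractions, OtuTable):
        taxa, x = list(fractions.taxon_ids), fractions.values
    else:
        x = np.asarray(fractions, dtype=float)
        taxa = [f"T{j}" for j in range(x.shape[1])]
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a samples x taxa matrix with n >= 3 samples")
    if np.any(x <= 0):
        raise ValueError("fractions must be strictly positive (resample first)")
    logx = np.log(x)
    c = np.cov(logx, rowvar=False, ddof=1)
    diag = np.diag(c)
    t = diag[:, None] + diag[None, :] - 2.0 * c
    t = np.clip((t + t.T) / 2.0, 0.0, None)
    np.fill_diagonal(t, 0.0)
    return LogRatioVariance(taxa, t)


def estimate_basis_correlations(T: LogRatioVariance,
                                exclusion_threshold: float = 0.1,
                                max_exclusions: int | None = None):
    """Solve for basis variances and correlations with iterative exclusion.

    Under sparsity, summing t_ij over the non-excluded partners j of taxon i
    gives A w2 = b with A[i,i] = (number of partners), A[i,j] = 1 for each
    partner — for no exclusions this is ones + (D-2) I, the normal equations
    of the least-squares fit of t_ij ~ w_i^2 + w_j^2 over all pairs.  After
    each solve the single most-correlated pair with \\|rho\\| above the
    threshold is removed from the system and the solve repeated, until no
    pair exceeds the threshold or ``max_exclusions`` is reached.

    Returns (basis variances w2, correlation matrix rho clipped to [-1, 1]).
    """
    t = T.values
    d = t.shape[0]
    if d < 4:
        raise ValueError("need at least 4 taxa to identify basis variances")
    if max_exclusions is None:
        max_exclusions = d - 3
    included = ~np.eye(d, dtype=bool)  # pair (i, j) still in the system

    def solve() -> tuple[np.ndarray, np.ndarray]:
        a = included.astype(float)
        np.fill_diagonal(a, included.sum(axis=1))
        b = (t * included).sum(axis=1)
        try:
            w2 = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "basis-variance system singular; use fewer exclusions") from exc
        w2 = np.clip(w2, _OMEGA2_FLOOR, None)
        w = np.sqrt(w2)
        rho = (w2[:, None] + w2[None, :] - t) / (2.0 * np.outer(w, w))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return w2, rho

    w2, rho = solve()
    for _ in range(max_exclusions):
        masked = np.where(included, np.abs(rho), 0.0)
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        if included.sum(axis=1).min() < 1:
            break  # a taxon would drop out of the system entirely
        w2, rho = solve()
    return w2, rho


def _dirichlet_fractions(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    g = rng.standard_gamma(counts + 1.0)
    return g / g.sum(axis=1, keepdims=True)


def sparcc(counts, n_inner: int = 20, exclusion_threshold: float = 0.1,
           seed: int = 0, max_exclusions: int | None = None) -> CorrelationEstimate:
    """Median basis-correlation estimate over Dirichlet-resampled fractions.

    Each of the ``n_inner`` repetitions draws per-sample fractions from the
    Dirichlet posterior with parameters (counts + 1), computes the log-ratio
    variance matrix and solves the basis system; the final rho is the
    element-wise median.  Deterministic given ``seed``.
    """
    taxa, x = _as_matrix(counts)
    n, d = x.shape
    if d < 4:
        raise ValueError("need at least 4 taxa")
    if n < 5:
        raise ValueError("need at least 5 samples")
    rng = np.random.default_rng(seed)
    rhos = np.empty((n_inner, d, d))
    for k in range(n_inner):
        fractions = _dirichlet_fractions(x, rng)
        t = logratio_variance_matrix(fractions)
        t.taxon_ids = taxa
        _, rhos[k] = estimate_basis_correlations(t, exclusion_threshold,
                                                 max_exclusions)
    rho = np.median(rhos, axis=0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationEstimate(taxa, rho, None, n_inner=n_inner, seed=seed)


def sparcc_pvalues(counts, rho_observed: CorrelationEstimate,
                   n_boot: int = 100, seed: int = 0,
                   n_inner: int | None = None) -> np.ndarray:
    """Two-sided permutation pseudo p-values for every taxon pair.

    Each replicate permutes every taxon's counts across samples independently
    (an exchangeable no-association null preserving marginals), reruns the
    correlation estimate, and counts replicates with \\|rho*\\| >= \\|rho\\|:
    p = (1 + exceedances) / (1 + n_boot).
    """
    if n_boot < 19:
        raise ValueError("n_boot must be >= 19 to resolve alpha = 0.05")
    taxa, x = _as_matrix(counts)
    if taxa != rho_observed.taxon_ids:
        raise ValueError("taxa of counts and rho_observed differ")
    if n_inner is None:
        n_inner = rho_observed.n_inner or 20
    n, d = x.shape
    abs_obs = np.abs(rho_observed.rho)
    exceed = np.zeros((d, d))
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_boot):
        rng = np.random.default_rng(child)
        perm = np.empty_like(x)
        for j in range(d):
            perm[:, j] = x[rng.permutation(n), j]
        inner_seed = int(rng.integers(0, 2**31 - 1))
        est = sparcc(perm, n_inner=n_inner,
                     exclusion_threshold=0.1, seed=inner_seed)
        exceed += np.abs(est.rho) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_boot)
    p = np.minimum(p, 1.0)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 1.0)
    return p
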