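"""Coverage diagnostics, bin filtering and matrix balancing.

Hi-C counts carry multiplicative per-bin biases (mappability, GC,
restriction-site density).  Balancing factors them out by finding positive
per-bin factors b such that corrected_ij = raw_ij / (b_i * b_j) has equal
row sums over unmasked bins.  Two solvers are provided: symmetric iterative
proportional fitting (ICE) and the Knight-Ruiz Newton-type algorithm.
Bins with extreme coverage are masked beforehand using thresholds expressed
in MAD units of log2 coverage about the median, matching the diagnostic
plot convention of standard Hi-C correction tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .matrix import ContactMatrix


@dataclass
class CoverageDiagnostics:
    coverage: np.ndarray          # per-bin total contacts
    score: np.ndarray             # MAD-units of log2 coverage (NaN where cov==0)
    zero_coverage: np.ndarray     # bool flag per bin
    median_log2: float
    mad_log2: float


@dataclass
class BalanceResult:
    matrix: ContactMatrix         # corrected (counts divided by bias outer)
    bias: np.ndarray              # per-bin factor; NaN on masked bins
    iterations: int
    final_cv: float               # coefficient of variation of unmasked row sums
    converged: bool


def _row_coverage(m: ContactMatrix) -> np.ndarray:
    upper = m.counts
    full = upper + sp.triu(upper, 1).T
    return np.asarray(full.sum(axis=1)).ravel()


def coverage_diagnostics(m: ContactMatrix) -> CoverageDiagnostics:
    """Score each bin's coverage in MAD units of log2 coverage.

    score_i = (log2 cov_i - median log2 cov) / MAD(log2 cov), computed over
    bins with nonzero coverage; zero-coverage bins are flagged separately.
    """
    cov = _row_coverage(m)
    if cov.sum() == 0:
        raise ValueError("matrix has no contacts")
    zero = cov == 0
    log2cov = np.full(cov.shape, np.nan)
    log2cov[~zero] = np.log2(cov[~zero])
    med = float(np.median(log2cov[~zero]))
    mad = float(np.median(np.abs(log2cov[~zero] - med)))
    score = np.full(cov.shape, np.nan)
    if mad > 0:
        score[~zero] = (log2cov[~zero] - med) / mad
    else:
        score[~zero] = 0.0
    return CoverageDiagnostics(cov, score, zero, med, mad)


def filter_bins(
    m: ContactMatrix, lower: float = -1.4, upper: float = 5.0
) -> ContactMatrix:
    """Mask bins with coverage score outside (lower, upper) or zero coverage.

    The thresholds are in MAD units of log2 coverage (see
    :func:`coverage_diagnostics`); defaults follow the restriction-fragment
    resolution convention (-1.4, 5).
    """
    if not lower < upper:
        raise ValueError("lower threshold must be below upper")
    diag = coverage_diagnostics(m)
    bad = diag.zero_coverage.copy()
    with np.errstate(invalid="ignore"):
        bad |= np.nan_to_num(diag.score, nan=0.0) < lower
        bad |= np.nan_to_num(diag.score, nan=0.0) > upper
    if bad.all():
        raise ValueError("all bins masked by thresholds")
    out = ContactMatrix(m.bins, m.counts.copy(), corrected=m.corrected,
                        bias=None if m.bias is None else m.bias.copy())
    out.mask = m.mask | bad
    return out


def _masked_dense(m: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    dense = m.dense()
    keep = ~m.mask
    return dense, keep


def _finalize(m: ContactMatrix, bias_full: np.ndarray, iterations: int,
              cv: float, converged: bool) -> BalanceResult:
    keep = ~m.mask
    # normalize to unit geometric mean over unmasked bins
    gm = np.exp(np.mean(np.log(bias_full[keep])))
    bias_full = bias_full / gm
    coo = m.counts.tocoo()
    ok = keep[coo.row] & keep[coo.col]
    vals = np.zeros_like(coo.data, dtype=float)
    vals[ok] = coo.data[ok] / (bias_full[coo.row[ok]] * bias_full[coo.col[ok]])
    corrected = sp.csr_matrix(
        sp.coo_matrix((vals[ok], (coo.row[ok], coo.col[ok])),
                      shape=m.counts.shape))
    bias_out = np.where(keep, bias_full, np.nan)
    cm = ContactMatrix(m.bins, corrected, corrected=True, bias=bias_out)
    cm.mask = m.mask.copy()
    return BalanceResult(cm, bias_out, iterations, cv, converged)


def _row_sums(dense: np.ndarray, keep: np.ndarray, bias: np.ndarray
              ) -> np.ndarray:
    sub = dense[np.ix_(keep, keep)] / np.outer(bias[keep], bias[keep])
    return sub.sum(axis=1)


def ice_correct(
    m: ContactMatrix, tol: float = 1e-5, max_iter: int = 1000
) -> BalanceResult:
    """Iterative correction: symmetric proportional fitting of row sums.

    Repeatedly multiplies the bias of each unmasked bin by the square root
    of its row sum relative to the mean row sum until the coefficient of
    variation of unmasked row sums drops below ``tol``.  Non-convergence at
    ``max_iter`` returns a result flagged unconverged with a warning.
    """
    dense, keep = _masked_dense(m)
    if not keep.any():
        raise ValueError("all bins masked")
    cov = dense[np.ix_(keep, keep)].sum(axis=1)
    if np.any(cov == 0):
        raise ValueError("unmasked bin with zero coverage; filter first")
    bias = np.ones(m.n_bins)
    cv = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        rs = _row_sums(dense, keep, bias)
        mean = rs.mean()
        cv = rs.std() / mean
        if cv < tol:
            break
        bias[keep] *= np.sqrt(rs / mean)
    else:
        warnings.warn(f"ICE did not converge in {max_iter} iterations "
                      f"(CV={cv:.2e})")
    rs = _row_sums(dense, keep, bias)
    cv = rs.std() / rs.mean()
    return _finalize(m, bias, it, cv, cv < tol)


def kr_balance(m: ContactMatrix, tol: float = 1e-8,
               max_outer: int = 100) -> BalanceResult:
    """Knight-Ruiz balancing: find x > 0 with diag(x) A diag(x) doubly
    stochastic on the unmasked block, via the inner-outer Newton iteration.

    Disconnected (reducible) unmasked blocks are balanced per connected
    component with a warning.  The returned bias is 1/x rescaled to the
    package's convention (corrected = raw / (bias_i bias_j), unit geometric
    mean), so KR and ICE agree up to a global scalar.
    """
    dense, keep = _masked_dense(m)
    if not keep.any():
        raise ValueError("all bins masked")
    sub = dense[np.ix_(keep, keep)]
    if np.any(sub.sum(axis=1) == 0):
        raise ValueError("unmasked bin with zero coverage; filter first")
    n_comp, labels = sp.csgraph.connected_components(
        sp.csr_matrix(sub > 0), directed=False)
    if n_comp > 1:
        warnings.warn(f"matrix reducible into {n_comp} components; "
                      "balancing each separately")
    x = np.empty(sub.shape[0])
    iters = 0
    converged = True
    for comp in range(n_comp):
        idx = labels == comp
        xc, itc, okc = _kr_core(sub[np.ix_(idx, idx)], tol, max_outer)
        x[idx] = xc
        iters = max(iters, itc)
        converged &= okc
    bias = np.ones(m.n_bins)
    bias[keep] = 1.0 / x
    rs = _row_sums(dense, keep, bias)
    cv = rs.std() / rs.mean()
    return _finalize(m, bias, iters, cv, converged)


def _kr_core(A: np.ndarray, tol: float, max_outer: int
             ) -> tuple[np.ndarray, int, bool]:
    """Inner-outer Newton iteration of Knight & Ruiz for a symmetric
    nonnegative irreducible matrix; returns x with diag(x) A diag(x)
    row-stochastic."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (A @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    i = 0
    MVP = 0
    while rout > tol * tol and i < max_outer:
        i += 1
        k = 0
        y = e.copy()
        innertol = max(eta * eta * rout, tol * tol)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            MVP += 1
            if MVP > 50 * n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        eta = min(max(eta, stop_tol / res_norm if res_norm > 0 else etamax),
                  etamax)
    return x, i, rout <= tol * tol
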