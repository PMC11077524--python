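"""Diabatic free-energy curves along the energy-gap coordinate.

The free energy of state J along the gap coordinate eps is

    A_J(eps) = -kB T ln p_J(eps) + A_J,

estimated here from multi-state samples by MBAR (binless multistate
reweighting) or, for harmonically biased umbrella windows, by WHAM.  The
crossing statistics give the classical golden-rule rate

    k_class = (2 pi / hbar) |H|^2 p_A(eps = 0);

when the sampled region does not reach eps = 0 the resonance density is
extrapolated with a quadratic free-energy (Gaussian density) ansatz fitted
to the empirical cumulative distribution function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, ndtr

from .constants import HBAR_EV_FS, FS_PER_S, beta_ev
from .rates import RateResult
from .synthetic import GapSampleSet


@dataclass
class FreeEnergyCurve:
    """A_J(eps) on a grid, with per-bin effective sample counts."""

    epsilon: np.ndarray
    a_values: np.ndarray
    state_label: str
    offset_reference: str
    n_effective: np.ndarray | None = None


class EstimatorDegenerateError(RuntimeError):
    """No overlap between the sampled states; reweighting is ill-posed."""


def mbar_solve(
    u_kn: np.ndarray,
    N_k: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 50000,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent MBAR free energies with Newton polish.

    ``u_kn`` has shape (K, N_total): reduced energy of every pooled sample
    under every state; ``N_k`` counts samples contributed by each state.
    Returns ``(f_k, Theta)`` with ``f_0 = 0`` and the asymptotic covariance
    matrix of the ``f_k``.
    """
    u_kn = np.asarray(u_kn, dtype=float)
    N_k = np.asarray(N_k, dtype=float)
    K, N = u_kn.shape
    f = np.zeros(K)
    logN = np.log(N_k)

    def sc_step(f):
        log_denom = logsumexp(logN[:, None] + f[:, None] - u_kn, axis=0)
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        return f_new - f_new[0]

    delta = np.inf
    for it in range(max_iter):
        # a few contraction steps, then a Newton step on the MBAR gradient
        for _ in range(5):
            f = sc_step(f)
        log_denom = logsumexp(logN[:, None] + f[:, None] - u_kn, axis=0)
        W = np.exp(f[:, None] - u_kn - log_denom[None, :])  # (K, N)
        g = N_k * (1.0 - W.sum(axis=1))  # negative MBAR gradient
        WN = W * N_k[:, None]
        H = np.diag(N_k * W.sum(axis=1)) - WN @ WN.T
        try:
            step = np.linalg.lstsq(H[1:, 1:], g[1:], rcond=None)[0]
            f_new = f.copy()
            f_new[1:] += np.clip(step, -2.0, 2.0)
        except np.linalg.LinAlgError:
            f_new = sc_step(f)
        # reject a Newton step that increases the self-consistency residual
        if np.max(np.abs(sc_step(f_new) - f_new)) > np.max(np.abs(sc_step(f) - f)):
            f_new = sc_step(f)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol * max(1.0, np.max(np.abs(f))):
            break
    else:
        raise RuntimeError(
            f"MBAR did not converge: residual {delta:.3g} after {max_iter} iterations"
        )
    # asymptotic covariance: Theta = V S (I - S V^T N V S)^+ S V^T
    log_denom = logsumexp(logN[:, None] + f[:, None] - u_kn, axis=0)
    Wnk = np.exp(f[None, :] - u_kn.T - log_denom[:, None])  # (N, K)
    _, S, Vt = np.linalg.svd(Wnk, full_matrices=False)
    V = Vt.T
    inner = np.eye(K) - (S[:, None] * Vt) @ (N_k[:, None] * V) * S[None, :]
    Theta = V @ (S[:, None] * np.linalg.pinv(inner, rcond=1e-12) * S[None, :]) @ Vt
    if not np.all(np.isfinite(f)):
        raise EstimatorDegenerateError("MBAR produced non-finite free energies")
    return f, Theta


def _pooled(samples: GapSampleSet):
    x = np.concatenate(samples.samples)
    u = np.concatenate(samples.reduced_energies, axis=1)
    N_k = np.array([len(s) for s in samples.samples], dtype=float)
    return x, u, N_k


def _check_overlap(samples: GapSampleSet):
    """Adjacent states must share sampled gap range."""
    ranges = [(s.min(), s.max()) for s in samples.samples]
    order = np.argsort([0.5 * (lo + hi) for lo, hi in ranges])
    for a, b in zip(order[:-1], order[1:]):
        lo = max(ranges[a][0], ranges[b][0])
        hi = min(ranges[a][1], ranges[b][1])
        if lo >= hi:
            raise EstimatorDegenerateError(
                "no overlap between sampled gap ranges of neighbouring states"
            )


def mbar_free_energy_curves(
    samples: GapSampleSet,
    temperature: float,
    grid: np.ndarray,
    min_effective: float = 50.0,
):
    """Free-energy curves per state and the free energy change.

    Returns ``(curves, delta_A, d_delta_A)``: the curves follow
    ``A_J(eps) = -kB T ln p_J(eps)`` offset by the MBAR state free energy
    (state 0's minimum is the common reference), and ``delta_A`` is
    ``kB T (f_last - f_0)`` with its one-sigma asymptotic uncertainty.
    Bins with fewer than ``min_effective`` effective samples are NaN.
    """
    if samples.n_states < 2:
        raise ValueError("need at least two states")
    _check_overlap(samples)
    kT = 1.0 / beta_ev(temperature)
    x, u_kn, N_k = _pooled(samples)
    f, Theta = mbar_solve(u_kn, N_k)
    grid = np.asarray(grid, dtype=float)
    edges = np.concatenate(
        [[grid[0] - 0.5 * (grid[1] - grid[0])],
         0.5 * (grid[1:] + grid[:-1]),
         [grid[-1] + 0.5 * (grid[-1] - grid[-2])]]
    )
    widths = np.diff(edges)
    logN = np.log(N_k)
    log_denom = logsumexp(logN[:, None] + f[:, None] - u_kn, axis=0)
    idx = np.digitize(x, edges) - 1
    inside = (idx >= 0) & (idx < len(grid))
    curves = []
    labels = samples.labels or [str(j) for j in range(samples.n_states)]
    for j in range(samples.n_states):
        logw = f[j] - u_kn[j] - log_denom  # normalised weights for state j
        w = np.exp(logw)
        dens = np.bincount(idx[inside], weights=w[inside], minlength=len(grid))
        wsq = np.bincount(idx[inside], weights=w[inside] ** 2, minlength=len(grid))
        with np.errstate(divide="ignore", invalid="ignore"):
            n_eff = np.where(wsq > 0, dens**2 / wsq, 0.0)
            a = -kT * np.log(dens / widths) + kT * f[j]
        a[n_eff < min_effective] = np.nan
        curves.append(
            FreeEnergyCurve(
                epsilon=grid, a_values=a, state_label=labels[j],
                offset_reference=labels[0], n_effective=n_eff,
            )
        )
    dA = kT * (f[-1] - f[0])
    var = Theta[0, 0] + Theta[-1, -1] - 2.0 * Theta[0, -1]
    return curves, float(dA), float(kT * np.sqrt(max(var, 0.0)))


@dataclass
class QuadraticFit:
    """Gaussian (quadratic free-energy) fit of one state's gap density."""

    barrier: float  # A(0) - A(mode), eV
    mean: float
    variance: float
    cvm_distance: float = np.nan


def quadratic_extrapolation(
    samples: np.ndarray, temperature: float, degree: int = 2
) -> QuadraticFit:
    """Barrier to the crossing point by quadratic free-energy extrapolation.

    A Gaussian density (quadratic ansatz for A(eps)) is fitted by minimising
    the Cramer-von Mises distance to the empirical CDF, then the barrier is
    read off as ``A(0) - A(mode) = kB T * mean^2 / (2 variance)``.  Degrees
    other than 2 fit ``-ln p`` as an even-behaved polynomial with numeric
    normalisation (same CDF criterion).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 1000:
        raise ValueError("need at least 1e3 samples for a stable CDF fit")
    if np.var(x) <= 0:
        raise ValueError("degenerate (zero-variance) samples")
    kT = 1.0 / beta_ev(temperature)
    target = (np.arange(1, n + 1) - 0.5) / n
    m0, s0 = x.mean(), x.std()

    if degree == 2:
        def cvm(p):
            mu, log_s = p
            cdf = ndtr((x - mu) / np.exp(log_s))
            return np.mean((cdf - target) ** 2)

        res = minimize(cvm, [m0, np.log(s0)], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 4000})
        mu, sig = res.x[0], np.exp(res.x[1])
        barrier = kT * mu**2 / (2.0 * sig**2)
        return QuadraticFit(barrier=float(barrier), mean=float(mu),
                            variance=float(sig**2), cvm_distance=float(res.fun))

    if degree < 2 or degree % 2 != 0:
        raise ValueError("polynomial degree must be an even integer >= 2")
    span = max(abs(x[0]), abs(x[-1]), abs(m0) + 8 * s0)
    grid = np.linspace(-span, span, 4001)

    def model_cdf(coeffs):
        a = np.concatenate([[0.0], coeffs])  # A(eps)/kT = sum a_i eps^i, a_0 free
        logp = -np.polyval(a[::-1], grid)
        logp -= logp.max()
        p = np.exp(logp)
        Z = np.trapezoid(p, grid)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(grid))]) / Z
        return np.interp(x, grid, cdf), grid, p / Z

    init = np.zeros(degree)
    init[0] = -m0 / s0**2
    init[1] = 1.0 / (2.0 * s0**2)

    def cvm_poly(c):
        cdf, _, _ = model_cdf(c)
        return np.mean((cdf - target) ** 2)

    res = minimize(cvm_poly, init, method="Nelder-Mead",
                   options={"maxiter": 8000, "fatol": 1e-16})
    cdf, g, p = model_cdf(res.x)
    p0 = np.interp(0.0, g, p)
    pmax = p.max()
    mean_fit = np.trapezoid(g * p, g)
    var_fit = np.trapezoid((g - mean_fit) ** 2 * p, g)
    return QuadraticFit(barrier=float(kT * np.log(pmax / p0)), mean=float(mean_fit),
                        variance=float(var_fit), cvm_distance=float(res.fun))


def wham_curves(
    windows: GapSampleSet,
    temperature: float,
    grid: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100000,
) -> FreeEnergyCurve:
    """Unbiased free-energy curve from umbrella windows by binned WHAM.

    Standard self-consistent histogram reweighting with harmonic biases
    ``w_i(eps) = curvature/2 (eps - c_i)^2``; a single window with zero bias
    reduces to ``-kB T ln(histogram)``.
    """
    if windows.bias_spec is None:
        raise ValueError("windows carry no bias specification")
    _check_overlap(windows)
    beta = beta_ev(temperature)
    kT = 1.0 / beta
    grid = np.asarray(grid, dtype=float)
    edges = np.concatenate(
        [[grid[0] - 0.5 * (grid[1] - grid[0])],
         0.5 * (grid[1:] + grid[:-1]),
         [grid[-1] + 0.5 * (grid[-1] - grid[-2])]]
    )
    widths = np.diff(edges)
    hist = np.stack([np.histogram(s, bins=edges)[0] for s in windows.samples])
    N_i = hist.sum(axis=1).astype(float)
    if np.any(N_i == 0):
        raise EstimatorDegenerateError("a window contributes no samples on the grid")
    bias = np.stack(
        [0.5 * kappa * (grid - c) ** 2 for c, kappa in windows.bias_spec]
    )  # (n_windows, n_bins), eV
    log_boltz = -beta * bias
    numer = hist.sum(axis=0).astype(float)
    logf = np.zeros(len(windows.samples))
    logP = np.where(numer > 0, np.log(numer), -np.inf)
    for it in range(max_iter):
        denom = logsumexp(
            np.log(N_i)[:, None] + logf[:, None] + log_boltz, axis=0
        )
        with np.errstate(divide="ignore"):
            logP_new = np.where(numer > 0, np.log(numer) - denom, -np.inf)
        logf_new = -logsumexp(log_boltz + logP_new[None, :], axis=1)
        logf_new -= logf_new[0]
        delta = np.max(np.abs(logf_new - logf))
        logf, logP = logf_new, logP_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"WHAM did not converge: residual {delta:.3g}")
    a = -kT * (logP - np.log(widths))
    a -= np.nanmin(a)
    a[numer == 0] = np.nan
    return FreeEnergyCurve(
        epsilon=grid, a_values=a, state_label="A", offset_reference="A",
        n_effective=numer.astype(float),
    )


def classical_fgr_rate(
    barrier: float,
    coupling_cm1: float,
    temperature: float,
    lam: float | None = None,
    resonance_density: float | None = None,
) -> RateResult:
    """Classical golden-rule rate from the crossing-point statistics.

    ``k = (2 pi/hbar)|H|^2 p_A(0)`` with the resonance density either given
    directly (1/eV) or formed from the barrier and the Gaussian prefactor
    ``(4 pi lam kB T)^{-1/2}``; with a quadratic free energy this is exactly
    the Marcus expression.
    """
    if barrier < 0:
        raise ValueError("barrier must be non-negative")
    from .constants import cm1_to_ev

    beta = beta_ev(temperature)
    H = cm1_to_ev(coupling_cm1)
    if resonance_density is None:
        if lam is None:
            raise ValueError("need lam (for the Gaussian prefactor) or resonance_density")
        resonance_density = np.exp(-beta * barrier) / np.sqrt(4.0 * np.pi * lam / beta)
    k_fs = (2.0 * np.pi / HBAR_EV_FS) * H**2 * resonance_density
    return RateResult(
        value=float(k_fs * FS_PER_S),
        method="classical_fgr",
        diagnostics={"barrier_eV": barrier, "resonance_density_per_eV": resonance_density},
    )


def linear_response_parameters(mean_gap_A: float, mean_gap_B: float):
    """Linear-response (lam, delta_A) from the two states' mean gaps.

    lam = |<dV>_B - <dV>_A| / 2 and DeltaA = (<dV>_A + <dV>_B)/2; equal
    means are flagged as degenerate (lam = 0).
    """
    lam = abs(mean_gap_B - mean_gap_A) / 2.0
    delta_A = (mean_gap_A + mean_gap_B) / 2.0
    return {"lam": lam, "delta_A": delta_A, "degenerate": lam == 0.0}
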