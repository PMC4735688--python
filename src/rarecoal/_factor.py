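"""Per-branch (derived, non-derived) lineage-count factor dynamics.

Within one population branch of scaled size ``lam``, the pair
``(a, n)`` of derived and non-derived ancestral lineage counts is a
continuous-time Markov chain (rates per scaled time unit):

* ``(a, n) -> (a-1, n)`` at ``a (a-1) / (2 lam)``   derived pair coalescence
* ``(a, n) -> (a, n-1)`` at ``n (n-1) / (2 lam)``   non-derived pair coalescence
* killed at ``a n / lam``                            derived / non-derived
                                                     coalescence (the site
                                                     pattern becomes
                                                     impossible)

Because branches evolve independently between joins, tracking this factor
per branch and convolving factors at joins is *exact*; no expectation
approximation or time discretization is required.  A factor is a matrix
``F[a, n]`` of (defective) probabilities.  Epochs are solved by
uniformization; the time integrals ``M0 = int F dt`` (needed for the
expected singleton time and the kill mass split) come from triangular
solves of ``G M0 = F_end - F_0`` in topological order, with first-moment
corrections for the rate-zero states.
"""

import math

import numpy as np
from numba import njit

__all__ = ["evolve_factor", "convolve_factors", "root_tail_acc", "trim_factor"]


@njit(cache=False)
def _rates(na, nn, lam):
    R = np.empty((na, nn))
    for a in range(na):
        for n in range(nn):
            R[a, n] = (a * (a - 1) / 2.0 + n * (n - 1) / 2.0 + a * n) / lam
    return R


@njit(cache=False)
def _apply_G(v, R, lam):
    """y = G v for the factor generator (kills included in the diagonal)."""
    na, nn = v.shape
    y = -R * v
    for a in range(1, na):
        ca = a * (a - 1) / 2.0 / lam
        for n in range(nn):
            y[a - 1, n] += ca * v[a, n]
    for n in range(1, nn):
        cn = n * (n - 1) / 2.0 / lam
        for a in range(na):
            y[a, n - 1] += cn * v[a, n]
    return y


@njit(cache=False)
def _uniformize(F, R, lam, dt, tol):
    """F(dt) = expm(G dt) F by uniformization, chunked for stability."""
    q = R.max()
    if q * dt <= 1e-14:
        return F.copy()
    n_chunks = int(math.ceil(q * dt / 40.0))
    sub = dt / n_chunks
    out = F.copy()
    for _ in range(n_chunks):
        qd = q * sub
        v = out.copy()
        acc = np.zeros_like(out)
        w = math.exp(-qd)
        acc += w * v
        k = 0
        wsum = w
        while wsum < 1.0 - tol and k < 100000:
            k += 1
            v = v + _apply_G(v, R, lam) / q
            w *= qd / k
            acc += w * v
            wsum += w
        out = acc
    return out


@njit(cache=False)
def _moments(F0, Fend, R, lam, dt):
    """M0[a,n] = int_0^dt P(a,n,t) dt, with first-moment handling of the
    rate-zero states (0,0), (0,1), (1,0)."""
    na, nn = F0.shape
    M0 = np.zeros((na, nn))
    M1 = np.zeros((na, nn))
    # positive-rate states, topological order (decreasing a, then n)
    for a in range(na - 1, -1, -1):
        for n in range(nn - 1, -1, -1):
            if R[a, n] <= 0.0:
                continue
            inflow0 = 0.0
            inflow1 = 0.0
            if a + 1 < na:
                ca = (a + 1) * a / 2.0 / lam
                inflow0 += ca * M0[a + 1, n]
                inflow1 += ca * M1[a + 1, n]
            if n + 1 < nn:
                cn = (n + 1) * n / 2.0 / lam
                inflow0 += cn * M0[a, n + 1]
                inflow1 += cn * M1[a, n + 1]
            M0[a, n] = (F0[a, n] - Fend[a, n] + inflow0) / R[a, n]
            M1[a, n] = (M0[a, n] - dt * Fend[a, n] + inflow1) / R[a, n]
    # rate-zero states: M0 = F0*dt + sum_in r' (dt*M0' - M1')
    for a in range(min(na, 2)):
        for n in range(min(nn, 2)):
            if R[a, n] > 0.0:
                continue
            extra = F0[a, n] * dt
            if a + 1 < na:
                ca = (a + 1) * a / 2.0 / lam
                extra += ca * (dt * M0[a + 1, n] - M1[a + 1, n])
            if n + 1 < nn:
                cn = (n + 1) * n / 2.0 / lam
                extra += cn * (dt * M0[a, n + 1] - M1[a, n + 1])
            M0[a, n] = extra
    return M0


@njit(cache=False)
def _evolve(F, lam, dt, tol):
    na, nn = F.shape
    R = _rates(na, nn, lam)
    Fend = _uniformize(F, R, lam, dt, tol)
    M0 = _moments(F, Fend, R, lam, dt)
    # integrated singleton occupancy and kill masses
    i1 = 0.0
    kill_sing = 0.0
    kill_multi = 0.0
    for n in range(nn):
        if na > 1:
            i1 += M0[1, n]
            kill_sing += (1.0 * n / lam) * M0[1, n]
        for a in range(2, na):
            kill_multi += (a * n / lam) * M0[a, n]
    return Fend, i1, kill_sing, kill_multi


def evolve_factor(F: np.ndarray, lam: float, dt: float, tol: float = 1e-12):
    """Advance a factor by dt.

    Returns (F_end, i1, kill_singleton, kill_multi) where i1 is the
    integral of P(a == 1) over the epoch and the kill terms are the
    probability mass absorbed by derived/non-derived coalescence from
    singleton and multi-derived states respectively.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return F.copy(), 0.0, 0.0, 0.0
    Fend, i1, ks, km = _evolve(np.ascontiguousarray(F, dtype=np.float64),
                               float(lam), float(dt), float(tol))
    return Fend, float(i1), float(ks), float(km)


@njit(cache=False)
def _convolve(Fi, Fj):
    na1, nn1 = Fi.shape
    na2, nn2 = Fj.shape
    out = np.zeros((na1 + na2 - 1, nn1 + nn2 - 1))
    for a1 in range(na1):
        for n1 in range(nn1):
            v = Fi[a1, n1]
            if v != 0.0:
                for a2 in range(na2):
                    for n2 in range(nn2):
                        out[a1 + a2, n1 + n2] += v * Fj[a2, n2]
    return out


@njit(cache=False)
def pure_death_marginal(p, lam, dt, tol):
    """Evolve a plain lineage-count distribution (no derived lineages).

    Returns (p_end, m) with m[k] = integral of P(count == k) over the
    epoch; this is the a = 0 row of the factor dynamics.
    """
    F = p.reshape((1, p.shape[0]))
    R = _rates(1, p.shape[0], lam)
    Fend = _uniformize(F, R, lam, dt, tol)
    M0 = _moments(F, Fend, R, lam, dt)
    return Fend[0], M0[0]


def convolve_factors(Fi: np.ndarray, Fj: np.ndarray, max_a: int | None = None):
    """Factor of a merged branch: independent sums of (a, n)."""
    out = _convolve(
        np.ascontiguousarray(Fi, dtype=np.float64),
        np.ascontiguousarray(Fj, dtype=np.float64),
    )
    if max_a is not None and out.shape[0] > max_a + 1:
        out = out[: max_a + 1]
    return out


def trim_factor(F: np.ndarray, tol: float = 1e-14):
    """Drop trailing n columns whose total mass is negligible."""
    col_mass = F.sum(axis=0)
    keep = len(col_mass)
    while keep > 1 and col_mass[keep - 1 :].sum() < tol:
        keep -= 1
    return np.ascontiguousarray(F[:, :keep])


@njit(cache=False)
def root_tail_table(na: int, nn: int, lam: float) -> np.ndarray:
    """E[(remaining singleton time) | start in (a, n)] in an isolated
    branch of size lam: first-step recursion of the (a, n) chain.
    E(1, 1) = lam; E(1, n) adds the sojourn 2 lam / (n (n+1)) and survives
    non-derived coalescence with odds (n-1)/(n+1)."""
    E = np.zeros((na, nn))
    if na < 2:
        return E
    for n in range(1, nn):
        if n == 1:
            E[1, 1] = lam
        else:
            E[1, n] = 2.0 * lam / (n * (n + 1)) + (n - 1.0) / (n + 1.0) * E[1, n - 1]
    for a in range(2, na):
        for n in range(1, nn):
            rate_aa = a * (a - 1) / 2.0
            rate_nn = n * (n - 1) / 2.0
            tot = rate_aa + rate_nn + a * n
            val = rate_aa / tot * E[a - 1, n]
            if n >= 2:
                val += rate_nn / tot * E[a, n - 1]
            E[a, n] = val
    return E


def root_tail_acc(q: np.ndarray, lam: float, table: np.ndarray | None = None):
    """Expected remaining singleton time from factor q in the final
    (root) branch.  A precomputed `table` (root_tail_table at least as
    large as q) may be shared across patterns."""
    na, nn = q.shape
    if na < 2:
        return 0.0
    if q[1:, 0].sum() > 1e-12:
        raise ValueError(
            "pattern subtends all sampled lineages; the subtending branch "
            "has unbounded expected length"
        )
    if table is None:
        table = root_tail_table(na, nn, lam)
    return float((q * table[:na, :nn]).sum())
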