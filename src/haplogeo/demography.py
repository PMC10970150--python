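"""Neutrality tests and mismatch-distribution demography.

Tajima's D contrasts the mean pairwise difference k-hat with Watterson's
S/a1; an excess of rare variants (recent expansion) drives D negative.
Fu's Fs is built on the Ewens sampling distribution of the number of
distinct haplotypes K given theta = k-hat:

    P(K = k) = |S1(n, k)| theta^k / (theta (theta+1) ... (theta+n-1))

with unsigned Stirling numbers of the first kind; Fs = ln(S'/(1-S')) with
S' = P(K >= K_obs), strongly negative when many haplotypes segregate at a
modest k-hat.  Both statistics are undefined on monomorphic data and are
rendered as 0 with p = 1 in table output.

The mismatch distribution (spectrum of pairwise difference counts) is fit
with the sudden-expansion model: a population at mutation-scaled size
theta0 = 2*N1*mu grew instantaneously to theta1 = 2*N2*mu at tau = 2*u*T
mutational time units ago.  The expected spectrum is the exact pair
solution of that two-epoch coalescent,

    F_i = Fhat_i(theta1) * P(coalesce before tau)
          + residual Poisson(tau) transient mixed with Fhat(theta0),

where Fhat_i(theta) = theta^i/(1+theta)^(i+1) is the stationary geometric
spectrum.  Goodness of fit uses the sum of squared deviations (SSD) and
Harpending's raggedness index, both tested by parametric bootstrap from
the fitted model.

Significance of D and Fs is obtained by simulating constant-size neutral
coalescent samples conditioned on the observed theta estimate and taking
the lower tail (the expansion direction) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, special

from .errors import InsufficientDataError
from .io import Alignment
from .diversity import mean_pairwise_differences, pairwise_differences


# ---------------------------------------------------------------------------
# Tajima's D

def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d_from_summary(n: int, s: int, k_hat: float) -> float:
    """Tajima's D from sample size, segregating sites and k-hat; NaN if S=0."""
    if n < 2:
        raise InsufficientDataError("Tajima's D needs n >= 2")
    if s == 0:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return (k_hat - s / a1) / math.sqrt(var)


def segregating_sites(a: Alignment) -> int:
    """Number of polymorphic sites among fully resolved (cleaned) columns."""
    from .io import clean_alignment

    mat = clean_alignment(a, "complete").matrix
    return int((~(mat == mat[0]).all(axis=0)).sum())


def tajimas_d(a: Alignment) -> float:
    return tajimas_d_from_summary(
        a.n_samples, segregating_sites(a), mean_pairwise_differences(a)
    )


# ---------------------------------------------------------------------------
# Fu's Fs via the Ewens sampling distribution

@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> tuple:
    """log |S1(n, k)| for k = 0..n, exact integer recurrence under the log."""
    row = [1]
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (row[k - 1] if k - 1 < len(row) else 0) + (m - 1) * (
                row[k] if k < len(row) else 0
            )
        row = new
    return tuple(math.log(v) if v > 0 else -math.inf for v in row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k), k = 0..n, for a sample of n genes at scaled rate theta."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = np.array(_log_stirling_row(n))
    k = np.arange(n + 1)
    denom = float(np.sum(np.log(theta + np.arange(n))))
    return logs + k * math.log(theta) - denom


def fu_fs_from_summary(n: int, k_hat: float, n_haplotypes: int) -> float:
    """Fu's Fs from n, mean pairwise differences, and observed K; NaN if k_hat=0."""
    if n < 2:
        raise InsufficientDataError("Fu's Fs needs n >= 2")
    if k_hat <= 0:
        return float("nan")
    logp = ewens_log_pmf(n, k_hat)
    log_sp = special.logsumexp(logp[n_haplotypes:])
    # Fs = logit of S'; guard the boundaries where S' saturates.
    sp = math.exp(min(log_sp, 0.0))
    if sp >= 1.0 - 1e-15:
        return float("inf")
    if sp <= 0.0:
        return float("-inf")
    return float(log_sp - math.log1p(-sp))


def count_haplotypes(a: Alignment) -> int:
    from .io import clean_alignment

    return len(set(clean_alignment(a, "complete").sequences))


def fu_fs(a: Alignment) -> float:
    return fu_fs_from_summary(
        a.n_samples, mean_pairwise_differences(a), count_haplotypes(a)
    )


@dataclass(frozen=True)
class NeutralityResult:
    population: str
    n: int
    s: int
    k_hat: float
    tajima_d: float
    p_d: float
    fu_fs: float
    p_fs: float


# ---------------------------------------------------------------------------
# Lightweight coalescent simulator (mutational time units)

def _simulate_sample(n: int, theta: float, rng, tau: float | None = None,
                     theta_anc: float | None = None) -> list:
    """Simulate per-leaf mutation sets under a (two-epoch) coalescent.

    Time is measured in mutational units (1/(2u) generations), in which a
    pair coalesces at rate 1/theta(t) and each lineage mutates at rate 1/2.
    ``theta`` applies from the present; if ``tau`` is given the rate
    switches to ``theta_anc`` beyond it (sudden-expansion history viewed
    backwards).  Returns a list of n sets of mutation ids.
    """
    lineages = [[i] for i in range(n)]
    muts: list = [set() for _ in range(n)]
    next_mut = 0
    t = 0.0
    theta_now = max(theta, 1e-9)
    while len(lineages) > 1:
        j = len(lineages)
        rate = j * (j - 1) / 2.0 / theta_now
        dt = rng.exponential(1.0 / rate)
        if tau is not None and t < tau <= t + dt:
            seg = tau - t
            for lin in lineages:
                for _ in range(rng.poisson(seg / 2.0)):
                    for leaf in lin:
                        muts[leaf].add(next_mut)
                    next_mut += 1
            t = tau
            theta_now = max(theta_anc if theta_anc is not None else theta, 1e-9)
            tau = None
            continue
        for lin in lineages:
            for _ in range(rng.poisson(dt / 2.0)):
                for leaf in lin:
                    muts[leaf].add(next_mut)
                next_mut += 1
        t += dt
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = sorted((i1, i2))
        lineages[a] = lineages[a] + lineages[b]
        del lineages[b]
    return muts


def _summaries_from_mutsets(muts: list):
    """(S, k_hat, K) from per-leaf mutation sets."""
    n = len(muts)
    counts: dict = {}
    for m in muts:
        for mut in m:
            counts[mut] = counts.get(mut, 0) + 1
    s = sum(1 for c in counts.values() if 0 < c < n)
    k_hat = sum(2.0 * c * (n - c) for c in counts.values()) / (n * (n - 1))
    k = len({frozenset(m) for m in muts})
    return s, k_hat, k


def mismatch_from_mutsets(muts: list) -> np.ndarray:
    n = len(muts)
    diffs = [
        len(muts[i].symmetric_difference(muts[j]))
        for i in range(n)
        for j in range(i + 1, n)
    ]
    spec = np.bincount(diffs).astype(float)
    return spec / spec.sum()


def neutrality_p_value(
    stat: str,
    observed: float,
    n: int,
    theta: float,
    n_reps: int = 1000,
    seed: int | None = None,
    alternative: str = "lower",
) -> float:
    """Simulated p-value for Tajima's D or Fu's Fs.

    Constant-size neutral panmictic samples are simulated conditioned on
    the plug-in theta estimate (S/a1 for D, k-hat for Fs); p is the
    fraction of simulated statistics <= observed (lower tail: the
    expansion direction).  ``alternative`` may be "lower", "upper" or
    "two-sided".  Degenerate observed statistics give p = 1.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if not math.isfinite(observed) or theta <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    sims = np.empty(n_reps)
    for r in range(n_reps):
        muts = _simulate_sample(n, theta, rng)
        s, k_hat, k = _summaries_from_mutsets(muts)
        if stat == "D":
            v = tajimas_d_from_summary(n, s, k_hat)
            sims[r] = 0.0 if not math.isfinite(v) else v
        elif stat == "Fs":
            v = fu_fs_from_summary(n, k_hat, k)
            sims[r] = 0.0 if not math.isfinite(v) else v
        else:
            raise ValueError(f"unknown statistic {stat!r}")
    lower = float(np.mean(sims <= observed + 1e-12))
    upper = float(np.mean(sims >= observed - 1e-12))
    if alternative == "lower":
        return lower
    if alternative == "upper":
        return upper
    return min(1.0, 2.0 * min(lower, upper))


def neutrality_tests(
    a: Alignment,
    population: str = "",
    n_reps: int = 1000,
    seed: int | None = None,
) -> NeutralityResult:
    """D and Fs with simulated p-values for one population sample."""
    n = a.n_samples
    s = segregating_sites(a)
    k_hat = mean_pairwise_differences(a)
    d = tajimas_d_from_summary(n, s, k_hat)
    fs = fu_fs_from_summary(n, k_hat, count_haplotypes(a))
    a1 = _tajima_constants(n)[0]
    ss = np.random.SeedSequence(seed).spawn(2) if seed is not None else [None, None]
    p_d = neutrality_p_value("D", d, n, s / a1 if s else 0.0, n_reps, _seed_of(ss[0]))
    p_fs = neutrality_p_value("Fs", fs, n, k_hat, n_reps, _seed_of(ss[1]))
    return NeutralityResult(population, n, s, k_hat, d, p_d, fs, p_fs)


def _seed_of(ss):
    return None if ss is None else int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Mismatch distribution and the sudden-expansion model

def mismatch_observed(a: Alignment) -> np.ndarray:
    """Relative frequency of each pairwise difference count (0..max)."""
    if a.n_samples < 2:
        raise InsufficientDataError("mismatch spectrum needs >= 2 sequences")
    d = pairwise_differences(a)
    iu = np.triu_indices(a.n_samples, k=1)
    spec = np.bincount(d[iu].astype(int)).astype(float)
    return spec / spec.sum()


def _stationary_spectrum(theta: float, d_max: int) -> np.ndarray:
    """Fhat_i(theta) = theta^i/(1+theta)^(i+1), i = 0..d_max."""
    i = np.arange(d_max + 1)
    if theta <= 0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))


def expansion_expected_spectrum(
    theta0: float, theta1: float, tau: float, d_max: int
) -> np.ndarray:
    """Expected mismatch probabilities under sudden expansion, renormalised.

    Exact two-epoch pair solution: coalescence at rate 1/theta1 until tau
    (mutational units), 1/theta0 beyond; differences are Poisson(t) given
    coalescence at t.  At tau = 0 this reduces to the stationary geometric
    spectrum at theta0; for theta0 -> 0 and large tau it approaches a
    Poisson peak at tau.
    """
    if min(theta0, theta1, tau) < 0:
        raise ValueError("parameters must be non-negative")
    theta1 = max(theta1, 1e-12)
    i = np.arange(d_max + 1)
    beta1 = (theta1 + 1.0) / theta1
    f1 = _stationary_spectrum(theta1, d_max)
    f0 = _stationary_spectrum(theta0, d_max)
    # P(pair coalesces after tau) given Poisson(i) differences by then:
    surv = special.pdtrc(i, beta1 * tau) if tau > 0 else np.zeros(d_max + 1)
    recent = f1 * (1.0 - surv) if tau > 0 else np.zeros(d_max + 1)
    if tau > 0:
        pois = np.exp(-tau + i * math.log(tau) - special.gammaln(i + 1))
    else:
        pois = np.eye(1, d_max + 1, 0)[0]
    transient = math.exp(-tau / theta1) * np.convolve(pois, f0)[: d_max + 1]
    f = recent + transient
    total = f.sum()
    if total <= 0:
        f = np.zeros(d_max + 1)
        f[0] = 1.0
        return f
    return f / total


def raggedness(spectrum) -> float:
    """Harpending's raggedness index with zero classes padded at both ends.

    rag = sum of squared successive differences of the spectrum including
    the steps up from (and back down to) zero, so a point mass gives 2 and
    the uniform spectrum over 0..d gives 2/(d+1)^2.
    """
    x = np.concatenate([[0.0], np.asarray(spectrum, dtype=float), [0.0]])
    return float(np.sum(np.diff(x) ** 2))


def ssd(observed, expected) -> float:
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    return float(np.sum((o - e) ** 2))


@dataclass(frozen=True)
class MismatchFit:
    observed_spectrum: np.ndarray = field(repr=False)
    expected_spectrum: np.ndarray = field(repr=False)
    theta0: float
    theta1: float
    tau: float
    ssd: float
    raggedness: float
    p_ssd: float = float("nan")
    p_rag: float = float("nan")
    converged: bool = True


_GRID_THETA0 = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0)
_GRID_THETA1 = (0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 5000.0, 10000.0)
_GRID_TAU = (0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 25.0, 50.0, 100.0)

BOUNDS = {"theta0": (0.0, 100.0), "theta1": (0.0, 1e4), "tau": (0.0, 100.0)}


def fit_expansion(observed, quick: bool = False) -> MismatchFit:
    """Least-squares fit of (theta0, theta1, tau) to an observed spectrum.

    A coarse grid search seeds a Nelder-Mead refinement of
    SSD = sum_i (obs_i - exp_i)^2 with box bounds theta0 in [0, 100],
    theta1 in [theta0, 1e4], tau in [0, 100].  ``quick`` prunes the grid
    (used inside the parametric bootstrap).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size == 0 or not np.isclose(obs.sum(), 1.0, atol=1e-6):
        raise ValueError("observed spectrum must be a 1-D array summing to 1")
    d_max = obs.size - 1

    def objective(params):
        t0 = np.clip(params[0], *BOUNDS["theta0"])
        t1 = np.clip(params[1], *BOUNDS["theta1"])
        tau = np.clip(params[2], *BOUNDS["tau"])
        t1 = max(t1, t0)  # post-expansion size not below pre-expansion
        return ssd(obs, expansion_expected_spectrum(t0, t1, tau, d_max))

    g0 = _GRID_THETA0[::2] if quick else _GRID_THETA0
    g1 = _GRID_THETA1[::2] if quick else _GRID_THETA1
    gt = _GRID_TAU[::2] if quick else _GRID_TAU
    grid = []
    for t0 in g0:
        for t1 in g1:
            if t1 < t0:
                continue
            for tau in gt:
                grid.append((objective((t0, t1, tau)), (t0, t1, tau)))
    grid.sort(key=lambda x: x[0])
    best_val, best = grid[0]
    # the SSD surface is multimodal; polish the top grid basins separately
    success = False
    for start_val, start in grid[: 2 if quick else 4]:
        res = optimize.minimize(
            objective,
            np.asarray(start, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-13, "maxiter": 4000, "maxfev": 6000},
        )
        if res.fun < best_val:
            best_val, best = float(res.fun), tuple(res.x)
            success = bool(res.success)
    t0 = float(np.clip(best[0], *BOUNDS["theta0"]))
    t1 = float(max(np.clip(best[1], *BOUNDS["theta1"]), t0))
    tau = float(np.clip(best[2], *BOUNDS["tau"]))
    expected = expansion_expected_spectrum(t0, t1, tau, d_max)
    return MismatchFit(
        observed_spectrum=obs,
        expected_spectrum=expected,
        theta0=t0,
        theta1=t1,
        tau=tau,
        ssd=float(best_val),
        raggedness=raggedness(obs),
        converged=success or best_val < 1e-10,
    )


def bootstrap_mismatch_tests(
    fit: MismatchFit, n: int, n_reps: int = 100, seed: int | None = None
) -> MismatchFit:
    """Parametric-bootstrap p-values for SSD and raggedness.

    Samples of size n are simulated under the fitted sudden-expansion
    coalescent, refit, and the observed SSD / raggedness are ranked against
    the bootstrap distributions (p = fraction >= observed).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if not np.isfinite(fit.ssd):
        return replace(fit, p_ssd=1.0, p_rag=1.0)
    rng = np.random.default_rng(seed)
    boot_ssd = np.empty(n_reps)
    boot_rag = np.empty(n_reps)
    for r in range(n_reps):
        muts = _simulate_sample(
            n, theta=fit.theta1, rng=rng, tau=fit.tau, theta_anc=fit.theta0
        )
        spec = mismatch_from_mutsets(muts)
        bfit = fit_expansion(spec, quick=True)
        boot_ssd[r] = bfit.ssd
        boot_rag[r] = raggedness(spec)
    return replace(
        fit,
        p_ssd=float(np.mean(boot_ssd >= fit.ssd - 1e-15)),
        p_rag=float(np.mean(boot_rag >= fit.raggedness - 1e-15)),
    )
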