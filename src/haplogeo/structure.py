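"""Population differentiation: Gst, Nst (with the haplotype-permutation test
for phylogeographic structure), Hudson's Fst, and one-level AMOVA with
Phi-st.

Gst and Nst use the Pons & Petit sample-size-unbiased within/total
diversities (harmonic-mean correction across populations).  Nst weights
haplotype pairs by their sequence distance, so Nst > Gst indicates that
similar haplotypes co-occur within populations, i.e. phylogeographic
structure; when all haplotype distances are equal Nst reduces exactly to
Gst.

AMOVA follows the Excoffier-Smouse-Quattro sums of squares built from
pairwise distances interpreted as squared Euclidean distances ("number of
different alleles" treatment: the raw difference count *is* the squared
distance), with the unequal-sample-size coefficient n0 and a permutation
test shuffling individuals among populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .io import Alignment, HaplotypeTable, population_partition
from .diversity import pairwise_differences


@dataclass(frozen=True)
class DistanceMatrix:
    """A labelled symmetric matrix with zero diagonal."""

    labels: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix diagonal not zero")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def reorder(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


def pairwise_difference_matrix(a: Alignment) -> DistanceMatrix:
    """Per-sample-pair differing-site counts (complete-deletion sites)."""
    return DistanceMatrix(a.sample_ids, pairwise_differences(a).astype(float))


def haplotype_distance_matrix(h: HaplotypeTable) -> DistanceMatrix:
    """Pairwise difference counts between haplotype sequences."""
    seqs = [np.frombuffer(s.encode(), dtype="S1") for s in h.haplotype_seqs]
    k = len(seqs)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = (seqs[i] != seqs[j]).sum()
    return DistanceMatrix(h.haplotype_ids, d)


def _unbiased_components(counts: pd.DataFrame, weight: np.ndarray):
    """Shared Pons & Petit machinery for Gst/Nst.

    ``weight`` is a haplotype x haplotype matrix w_ij (zero diagonal);
    the within-population statistic is sum_ij w_ij x_i x_j with the
    n/(n-1)-style unbiased correction via the harmonic mean sample size.
    Returns (vS, vT).
    """
    n = counts.sum(axis=1).to_numpy(dtype=float)
    keep = n >= 2
    if keep.sum() < 2:
        raise InsufficientDataError("Gst/Nst need >= 2 populations with n >= 2")
    if not keep.all():
        warnings.warn(
            f"excluding populations with n < 2: {list(counts.index[~keep])}"
        )
    x = counts.loc[keep].to_numpy(dtype=float)
    n = n[keep]
    k = x.shape[0]
    freqs = x / n[:, None]
    n_tilde = k / np.sum(1.0 / n)
    within = np.einsum("ki,ij,kj->k", freqs, weight, freqs)
    vS = n_tilde / (n_tilde - 1.0) * within.mean()
    xbar = freqs.mean(axis=0)
    vT = float(xbar @ weight @ xbar) + vS / (n_tilde * k)
    return float(vS), float(vT)


def gst(h: HaplotypeTable) -> float:
    """Unordered-allele differentiation (hT - hS)/hT, unbiased estimators."""
    k = len(h.haplotype_ids)
    w = 1.0 - np.eye(k)  # identity weighting: sum_{i != j} x_i x_j = 1 - sum x^2
    hS, hT = _unbiased_components(h.counts, w)
    if hT <= 0:
        warnings.warn("total diversity is zero; Gst undefined")
        return float("nan")
    return (hT - hS) / hT


def nst(h: HaplotypeTable, hap_dist: DistanceMatrix) -> float:
    """Distance-weighted differentiation (vT - vS)/vT (ordered alleles)."""
    d = hap_dist.reorder(h.haplotype_ids).values
    vS, vT = _unbiased_components(h.counts, d)
    if vT <= 0:
        warnings.warn("total distance diversity is zero; Nst undefined")
        return float("nan")
    return (vT - vS) / vT


def nst_gst_permutation_test(
    h: HaplotypeTable,
    hap_dist: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """One-sided test of Nst > Gst by permuting haplotype identities.

    The null keeps haplotype frequencies fixed and reassigns rows/columns of
    the haplotype distance matrix to labels at random, destroying any
    association between haplotype similarity and geography.  Returns
    ``(nst, gst, p)`` with p = (1 + #{Nst_perm - Gst >= Nst_obs - Gst}) /
    (n_perm + 1).
    """
    if len(h.haplotype_ids) < 2:
        raise InsufficientDataError("need >= 2 haplotypes for Nst vs Gst")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    g = gst(h)
    d = hap_dist.reorder(h.haplotype_ids).values
    obs = nst(h, hap_dist) - g
    k = d.shape[0]
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        dp = d[np.ix_(perm, perm)]
        vS, vT = _unbiased_components(h.counts, dp)
        n_perm_stat = (vT - vS) / vT if vT > 0 else np.nan
        if n_perm_stat - g >= obs - 1e-12:
            extreme += 1
    p = (extreme + 1) / (n_perm + 1)
    return nst(h, hap_dist), g, p


def _within_between_sums(d: np.ndarray, groups: np.ndarray):
    """Sum and count of pairwise entries within and between groups."""
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    same = groups[iu] == groups[ju]
    vals = d[iu, ju]
    return vals[same].sum(), same.sum(), vals[~same].sum(), (~same).sum()


def hudson_fst(a: Alignment, samples: pd.DataFrame) -> float:
    """Hudson-Slatkin-Maddison Fst = 1 - Hw/Hb on sequence data.

    Hw (Hb) is the mean number of differing sites over all within-population
    (between-population) sample pairs, pooled across populations.
    """
    d = pairwise_differences(a)
    pop_of = samples.set_index("sample_id")["population"]
    groups = pop_of.loc[list(a.sample_ids)].to_numpy()
    if len(set(groups)) < 2:
        raise InsufficientDataError("Hudson Fst needs >= 2 populations")
    sw, cw, sb, cb = _within_between_sums(d, groups)
    if cw == 0 or cb == 0 or sb == 0:
        return float("nan")
    return 1.0 - (sw / cw) / (sb / cb)


def pairwise_hudson_fst(a: Alignment, samples: pd.DataFrame) -> DistanceMatrix:
    """Hudson Fst for every population pair (NaN where undefined).

    Estimates are reported as computed (possibly negative); clamping is the
    caller's choice (the IBD transform clamps at zero).
    """
    parts = population_partition(samples)
    pops = [p for p, ids in parts.items() if len(ids) >= 1]
    d = pairwise_differences(a)
    index = {s: i for i, s in enumerate(a.sample_ids)}
    out = np.zeros((len(pops), len(pops)))
    for i, p1 in enumerate(pops):
        for j in range(i + 1, len(pops)):
            p2 = pops[j]
            ids = [index[s] for s in parts[p1] + parts[p2]]
            grp = np.array([0] * len(parts[p1]) + [1] * len(parts[p2]))
            sub = d[np.ix_(ids, ids)]
            sw, cw, sb, cb = _within_between_sums(sub, grp)
            if cw == 0 or cb == 0 or sb == 0:
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = 1.0 - (sw / cw) / (sb / cb)
    return DistanceMatrix(tuple(pops), out)


@dataclass(frozen=True)
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_a: float
    sigma2_b: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int


def _amova_components(sq: np.ndarray, groups: np.ndarray):
    """Variance components from squared distances and group labels."""
    n = sq.shape[0]
    labels, counts = np.unique(groups, return_counts=True)
    k = len(labels)
    ss_total = sq[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g, c in zip(labels, counts):
        idx = np.flatnonzero(groups == g)
        if c < 2:
            continue
        sub = sq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(c, k=1)].sum() / c
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (n - np.sum(counts**2) / n) / df_among
    sigma_b = ms_within
    sigma_a = (ss_among / df_among - ms_within) / n0
    return ss_among, ss_within, sigma_a, sigma_b, df_among, df_within


def amova(
    d: DistanceMatrix,
    samples: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA over populations.

    ``d`` holds pairwise difference counts, treated as squared Euclidean
    distances.  Phi-st = sigma_a^2/(sigma_a^2 + sigma_b^2); its p-value is
    the (1 + #extreme)/(n_perm + 1) fraction of label permutations with
    Phi-st at least the observed value.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pop_of = samples.set_index("sample_id")["population"]
    groups = pop_of.loc[list(d.labels)].to_numpy()
    sizes = pd.Series(groups).value_counts()
    if (sizes == 0).any():
        warnings.warn("populations of size 0 excluded from AMOVA")
    if len(sizes) < 2:
        raise InsufficientDataError("AMOVA needs >= 2 populations")
    sq = d.values
    ssa, ssw, sa, sb, dfa, dfw = _amova_components(sq, groups)
    total = sa + sb
    if total <= 0:
        warnings.warn("all distances zero; Phi-st undefined, reporting 0 variance")
        return AmovaResult(dfa, dfw, ssa, ssw, sa, sb, 0.0, 0.0, float("nan"), 1.0, n_perm)
    phi = sa / total
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm_groups = rng.permutation(groups)
        _, _, pa, pb, _, _ = _amova_components(sq, perm_groups)
        ptot = pa + pb
        pphi = pa / ptot if ptot > 0 else 0.0
        if pphi >= phi - 1e-12:
            extreme += 1
    p = (extreme + 1) / (n_perm + 1)
    return AmovaResult(
        dfa, dfw, ssa, ssw, sa, sb,
        100.0 * sa / total, 100.0 * sb / total, phi, p, n_perm,
    )


def amova_frame(result: AmovaResult, label: str = "") -> pd.DataFrame:
    """AMOVA table in the conventional report shape."""
    return pd.DataFrame(
        {
            "marker": [label, label, label],
            "source": ["Among populations", "Within populations", "Total"],
            "df": [result.df_among, result.df_within, result.df_among + result.df_within],
            "sum_of_squares": [
                result.ss_among,
                result.ss_within,
                result.ss_among + result.ss_within,
            ],
            "variance_component": [result.sigma2_a, result.sigma2_b, result.sigma2_a + result.sigma2_b],
            "pct_variance": [result.pct_among, result.pct_within, 100.0],
            "phi_st": [result.phi_st, np.nan, np.nan],
            "p_value": [result.p_value, np.nan, np.nan],
        }
    )
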