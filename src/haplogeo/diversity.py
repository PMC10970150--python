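"""Haplotype diversity h, per-site nucleotide diversity pi, and survey-style
per-population summary tables.

h is the observed (plug-in) haplotype diversity h = 1 - sum_i p_i^2, the
probability that two randomly drawn sequences carry different haplotypes.
No n/(n-1) sample-size correction is applied: for a population of 3
individuals carrying two haplotypes in composition (2,1) this estimator
gives 0.4444 (the corrected one would give 0.6667), which is the convention
used throughout the reported tables this package reproduces.

pi is the mean proportion of differing sites over all unordered sequence
pairs, computed on completely cleaned sites so that h and pi describe the
same data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InsufficientDataError
from .io import Alignment, HaplotypeTable, clean_alignment, population_partition


def haplotype_diversity(freqs) -> float:
    """h = 1 - sum p_i^2 for a vector of haplotype frequencies."""
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise DegenerateDataError("empty frequency vector")
    if (p < 0).any():
        raise ValueError("negative haplotype frequency")
    tot = p.sum()
    if not np.isclose(tot, 1.0, atol=1e-8):
        raise ValueError(f"frequencies sum to {tot}, expected 1")
    return float(1.0 - np.sum(p**2))


def pairwise_differences(a: Alignment) -> np.ndarray:
    """n x n matrix of per-pair differing-site counts (cleaned sites)."""
    mat = clean_alignment(a, "complete").matrix
    codes = mat.view(np.uint8)
    n = codes.shape[0]
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i, i + 1 :] = (codes[i + 1 :] != codes[i]).sum(axis=1)
    return d + d.T


def nucleotide_diversity(a: Alignment) -> float:
    """Per-site pi: mean pairwise Hamming distance divided by cleaned length."""
    if a.n_samples < 2:
        raise InsufficientDataError("nucleotide diversity needs >= 2 sequences")
    clean = clean_alignment(a, "complete")
    d = pairwise_differences(clean)
    n = clean.n_samples
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean() / clean.length)


def mean_pairwise_differences(a: Alignment) -> float:
    """k-hat: mean number of differing sites over all unordered pairs."""
    if a.n_samples < 2:
        raise InsufficientDataError("needs >= 2 sequences")
    d = pairwise_differences(a)
    iu = np.triu_indices(a.n_samples, k=1)
    return float(d[iu].mean())


@dataclass(frozen=True)
class DiversitySummary:
    population: str
    n: int
    h: float
    pi_site: float
    n_haplotypes_ge2: int  # x: haplotypes with overall abundance >= 2
    n_singletons: int      # y: haplotypes with overall abundance 1
    haplotype_labels: tuple


def population_summary(
    h: HaplotypeTable, a: Alignment, samples: pd.DataFrame, total_pi: str = "pooled"
) -> list:
    """One :class:`DiversitySummary` per population plus a pooled Total row.

    The abundance classes x / y follow the survey-table footnote: for each
    population, x counts its haplotypes whose abundance in the *overall*
    sample is at least two, y those that are overall singletons.  ``total_pi``
    selects whether the Total row's pi is computed on the pooled sample
    (default) or as the across-population mean.
    """
    clean = clean_alignment(a, "complete")
    overall = h.overall_abundance
    parts = population_partition(samples)
    rows = []
    for pop in h.populations:
        ids = [s for s in parts.get(pop, []) if s in clean.sample_ids]
        n = len(ids)
        if n == 0:
            warnings.warn(f"population {pop} has no samples; excluded")
            continue
        counts = h.counts.loc[pop]
        present = counts[counts > 0]
        hv = haplotype_diversity(present / n)
        sub = clean.subset(ids)
        pi = nucleotide_diversity(sub) if n >= 2 else 0.0
        x = int((overall.loc[present.index] >= 2).sum())
        y = int((overall.loc[present.index] == 1).sum())
        rows.append(DiversitySummary(pop, n, hv, pi, x, y, tuple(present.index)))
    n_tot = int(overall.sum())
    h_tot = haplotype_diversity(overall / n_tot)
    if total_pi == "pooled":
        pi_tot = nucleotide_diversity(clean)
    elif total_pi == "mean":
        pi_tot = float(np.mean([r.pi_site for r in rows]))
    else:
        raise ValueError(f"unknown total_pi mode {total_pi!r}")
    rows.append(
        DiversitySummary(
            "Total",
            n_tot,
            h_tot,
            pi_tot,
            int((overall >= 2).sum()),
            int((overall == 1).sum()),
            tuple(h.haplotype_ids),
        )
    )
    return rows


def summary_frame(rows) -> pd.DataFrame:
    """Survey-table-shaped DataFrame (population, n, h, pi, 'x + y', labels)."""
    return pd.DataFrame(
        {
            "population": [r.population for r in rows],
            "n": [r.n for r in rows],
            "h": [r.h for r in rows],
            "pi": [r.pi_site for r in rows],
            "haplotype_classes": [
                f"{r.n_haplotypes_ge2} + {r.n_singletons}" for r in rows
            ],
            "haplotypes": [" ".join(r.haplotype_labels) for r in rows],
        }
    )


def across_population_mean(values, sample_sd: bool = True):
    """Mean and SD of a per-population statistic ('mean +/- SD' rows).

    ``sample_sd`` selects the n-1 denominator (default) versus n.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise DegenerateDataError("no values to average")
    sd = 0.0 if v.size == 1 else float(np.std(v, ddof=1 if sample_sd else 0))
    return float(v.mean()), sd
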