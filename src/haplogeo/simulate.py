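"""Coalescent generator of study-like two-locus organelle datasets.

Emulates a range-wide survey of a maternally inherited, non-recombining
genome: 29 demes with sample sizes between 3 and 30 (447 individuals in
total), exchanging seeds under Wright's island model, sequenced at two
uniparental loci of different mutation rates (a fast intergenic spacer and
a slower one).  Defaults reproduce the magnitudes of such a survey: deme
sizes mirror the field sampling design, within-deme per-site diversity is
of order 0.03 at the fast locus, and western demes are more diverse than
eastern ones (implemented as a declining effective-size gradient).

Migration convention
--------------------
``migration_rate`` is Wright's ms: the fraction of each deme replaced per
generation by seeds drawn from the species-wide pool (own deme included).
Backwards in time a lineage therefore moves to each *other* deme at rate
ms/d, i.e. ms*(d-1)/d in total.  Under this convention the expected
sequence-based Fst is 1/(1 + 2*Ne*ms) for any number of demes d, matching
the island-model equilibrium formula exactly rather than only in the
d -> infinity limit.

Genealogies come from msprime (haploid, single non-recombining tree per
locus); mutations are placed by this module under an
infinite-sites-on-finite-length scheme: Poisson numbers of mutations per
branch, each at a uniformly chosen site, substituting a random distinct
base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .io import Alignment, write_alignment, write_sample_table

#: Per-deme sample sizes of the emulated 29-population survey (total 447).
STUDY_DEME_SIZES = (
    9, 10, 11, 12, 23, 11, 9, 18, 29, 15, 24, 30, 27, 11, 14,
    26, 22, 25, 15, 6, 9, 5, 9, 11, 21, 9, 18, 3, 15,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the island-model generator.

    ``ne_per_deme`` may be a scalar or a length-``n_demes`` sequence; the
    default declines linearly west to east (7500 -> 2500, mean 5000),
    producing the west-rich diversity gradient of the emulated survey.
    ``mu_per_locus`` are per-site per-generation rates; the first (fast)
    locus defaults to 1e-7 so that within-deme per-site diversity
    2*d*Ne*mu is about 0.03, the second to 1.5e-8.  ``expansion`` maps deme
    index -> (tau_mut, growth) for an instantaneous size increase by
    ``growth`` at tau_mut mutational units (2*u*T, u = per-locus rate of
    the first locus) before the present.
    """

    n_demes: int = 29
    deme_sizes: tuple = STUDY_DEME_SIZES
    ne_per_deme: object = None  # None -> default west-east gradient
    migration_rate: float = 1.3e-4
    locus_names: tuple = ("psbA-trnH-like", "trnL-trnL-like")
    locus_lengths: tuple = (564, 500)
    mu_per_locus: tuple = (1.0e-7, 1.5e-8)
    expansion: dict | None = None
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required")
        if len(self.deme_sizes) != self.n_demes:
            raise ValueError("deme_sizes length must equal n_demes")
        if min(self.deme_sizes) < 1:
            raise ValueError("deme sizes must be >= 1")
        if self.migration_rate < 0 or min(self.mu_per_locus) < 0:
            raise ValueError("rates must be non-negative")
        if len(self.locus_lengths) != len(self.mu_per_locus):
            raise ValueError("locus_lengths and mu_per_locus disagree")

    @property
    def ne_array(self) -> np.ndarray:
        if self.ne_per_deme is None:
            if self.n_demes == 1:
                return np.array([5000.0])
            return np.linspace(7500.0, 2500.0, self.n_demes)
        ne = np.asarray(self.ne_per_deme, dtype=float).ravel()
        if ne.size == 1:
            ne = np.full(self.n_demes, ne[0])
        if ne.size != self.n_demes:
            raise ValueError("ne_per_deme must be scalar or length n_demes")
        if (ne <= 0).any():
            raise ValueError("effective sizes must be positive")
        return ne


def _demography(cfg: SimulationConfig, u_fast: float) -> msprime.Demography:
    ne = cfg.ne_array
    dem = msprime.Demography()
    for i in range(cfg.n_demes):
        dem.add_population(name=f"deme{i}", initial_size=ne[i])
    ms = cfg.migration_rate
    if cfg.n_demes > 1:
        if ms == 0:
            warnings.warn(
                "zero migration with multiple demes: using a vanishing rate "
                "to keep coalescence finite"
            )
            ms = 1.0 / (1000.0 * ne.mean() * cfg.n_demes)
        rate = ms / cfg.n_demes  # Wright convention: pool includes own deme
        for i in range(cfg.n_demes):
            for j in range(cfg.n_demes):
                if i != j:
                    dem.set_migration_rate(f"deme{i}", f"deme{j}", rate)
    if cfg.expansion:
        for idx, (tau_mut, growth) in cfg.expansion.items():
            t_gen = tau_mut / (2.0 * u_fast)
            dem.add_population_parameters_change(
                time=t_gen, population=f"deme{idx}", initial_size=ne[idx] / growth
            )
    dem.sort_events()
    return dem


def simulate_island_coalescent(cfg: SimulationConfig) -> list:
    """One tskit TreeSequence per locus (genealogies only, no mutations)."""
    u_fast = cfg.mu_per_locus[0] * cfg.locus_lengths[0]
    dem = _demography(cfg, u_fast)
    samples = {f"deme{i}": n for i, n in enumerate(cfg.deme_sizes)}
    rng = np.random.default_rng(cfg.seed)
    out = []
    for L in cfg.locus_lengths:
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            sequence_length=L,
            recombination_rate=0.0,
            ploidy=1,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        out.append(ts)
    return out


def apply_mutations(
    ts, mu: float, L: int, seed: int | None = None, locus_name: str = "locus",
    sample_ids=None,
) -> Alignment:
    """Drop mutations on a single-tree genealogy and emit an alignment.

    Per branch, Poisson(branch_length * mu * L) mutations land at uniformly
    chosen sites of an A-filled ancestral sequence, each substituting a
    random distinct base (so back-mutation and multiple hits are possible
    at low rates, as on a real finite sequence).
    """
    rng = np.random.default_rng(seed)
    tree = ts.first()
    n = ts.num_samples
    seqs: dict = {}
    for root in tree.roots:
        seqs[root] = np.zeros(L, dtype=np.uint8)  # all-A ancestor
    for node in tree.nodes(order="preorder"):
        parent = tree.parent(node)
        if parent == -1:
            continue
        seq = seqs[parent].copy()
        t = tree.time(parent) - tree.time(node)
        for _ in range(rng.poisson(t * mu * L)):
            site = rng.integers(L)
            seq[site] = (seq[site] + 1 + rng.integers(3)) % 4
        seqs[node] = seq
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    mat = np.stack([_BASES[seqs[s]] for s in ts.samples()])
    return Alignment(locus_name, tuple(sample_ids), mat)


def _metadata(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """Synthetic site table: demes on a west-east transect.

    Longitudes run 99E -> 120E; elevation declines eastwards (1600 -> 400 m
    plus noise), mirroring the emulated survey's terrain.
    """
    d = cfg.n_demes
    lon = np.linspace(99.0, 120.0, d) + rng.normal(0, 0.3, d)
    lat = rng.uniform(22.0, 30.0, d)
    elev = np.clip(np.linspace(1600.0, 400.0, d) + rng.normal(0, 150.0, d), 0, None)
    rows = []
    for i in range(d):
        code = f"D{i + 1:02d}"
        for k in range(cfg.deme_sizes[i]):
            rows.append(
                (f"{code}_{k + 1:03d}", code, lon[i], lat[i], elev[i])
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "population", "longitude", "latitude", "elevation"]
    )


def generate_study_like_dataset(cfg: SimulationConfig, out_dir=None):
    """Per-locus alignments plus a metadata table; optionally written to disk.

    Returns ``(alignments, samples)``; with ``out_dir`` set, writes one
    FASTA per locus and ``samples.tsv`` suitable as direct pipeline input.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    samples = _metadata(cfg, rng)
    ids = tuple(samples["sample_id"])
    genealogies = simulate_island_coalescent(cfg)
    alignments = []
    for ts, name, L, mu in zip(
        genealogies, cfg.locus_names, cfg.locus_lengths, cfg.mu_per_locus
    ):
        aln = apply_mutations(
            ts, mu, L,
            seed=int(rng.integers(1, 2**31 - 1)),
            locus_name=name, sample_ids=ids,
        )
        alignments.append(aln)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for aln in alignments:
            write_alignment(aln, out / f"{aln.locus_name.replace('/', '_')}.fasta")
        write_sample_table(samples, out / "samples.tsv")
    return alignments, samples


def simulate_expansion_sample(
    theta0: float, theta1: float, tau: float, n: int, L: int, seed: int
) -> Alignment:
    """Single-deme sample under an instantaneous size change.

    Parameters are in mutational units: theta0/theta1 = 2*N*u before/after
    the expansion (u = per-locus rate), tau = 2*u*T.  tau = 0 reduces to a
    constant-size population at theta0.
    """
    if min(theta0, theta1, tau) < 0:
        raise ValueError("parameters must be non-negative")
    n1 = 1.0e4  # current size anchor; u follows from theta1
    if tau == 0:
        theta1 = theta0 if theta0 > 0 else 1e-6
    u = max(theta1, 1e-9) / (2.0 * n1)
    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=n1)
    if tau > 0:
        n0 = max(theta0 / (2.0 * u), 1e-2)
        dem.add_population_parameters_change(
            time=tau / (2.0 * u), initial_size=n0, population="pop"
        )
    rng = np.random.default_rng(seed)
    ts = msprime.sim_ancestry(
        samples={"pop": n},
        demography=dem,
        sequence_length=L,
        recombination_rate=0.0,
        ploidy=1,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    return apply_mutations(
        ts, u / L, L, seed=int(rng.integers(1, 2**31 - 1)), locus_name="expansion"
    )
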