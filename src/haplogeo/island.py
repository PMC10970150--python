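"""Wright's island-model equilibrium Fst and the mutation-to-seed-migration
ratio estimator for uniparentally inherited loci.

For a haploid maternally inherited locus in the island model at
drift-migration-mutation equilibrium,

    Fst = 1 / (1 + 2 Ne (ms + mu)),

where ms is the seed migration rate (the only gene-flow channel for
angiosperm cpDNA and mtDNA) and mu the locus mutation rate.  Comparing a
chloroplast locus with a mitochondrial locus from the same populations and
assuming the mtDNA mutation rate is negligible gives

    mu_cp / ms = (1/Fst_cp - 1) / (1/Fst_mt - 1) - 1,

an estimate of how strongly mutation (rather than restricted seed flow)
has eroded the observed cpDNA differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass


def equilibrium_fst(ne: float, ms: float, mu: float) -> float:
    """Fst = 1/(1 + 2*ne*(ms + mu)) for a haploid uniparental locus."""
    if ne <= 0:
        raise ValueError("ne must be positive")
    if ms < 0 or mu < 0:
        raise ValueError("rates must be non-negative")
    return 1.0 / (1.0 + 2.0 * ne * (ms + mu))


@dataclass(frozen=True)
class IslandModelEstimate:
    fst_cp: float
    fst_mt: float
    mu_over_ms: float
    assumptions: str = "mtDNA mutation rate treated as negligible (mu_mt ~ 0)"


def mu_over_ms(fst_cp: float, fst_mt: float) -> IslandModelEstimate:
    """cpDNA mutation-to-seed-migration ratio from two differentiation values.

    Both inputs must lie strictly in (0, 1).  The ratio is bounded below by
    -1 and is 0 when the two loci are equally differentiated.
    """
    for name, v in (("fst_cp", fst_cp), ("fst_mt", fst_mt)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must be in (0, 1), got {v}")
    ratio = (1.0 / fst_cp - 1.0) / (1.0 / fst_mt - 1.0) - 1.0
    return IslandModelEstimate(fst_cp, fst_mt, ratio)
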