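"""Bundled reference tables from the range-wide *Toona ciliata* cpDNA survey.

The package ships the published summary tables of the 29-population,
447-individual survey of the *T. ciliata* complex in southern China: the
sampling localities (with coordinates and elevations) and the
per-population haplotype diversity h and per-site nucleotide diversity pi
for the two chloroplast fragments (the fast psbA-trnH spacer and the
slower trnL-trnL fragment).  The raw alignments are not publicly
accessioned, so desk-scale reanalyses (column means, elevation
correlations, the island-model mutation/seed-flow ratio) start from these
printed values; full sequence-level analyses use the synthetic generator
in :mod:`haplogeo.simulate`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Among-population differentiation of the concatenated cpDNA fragments.
TOONA_FST_CP = 0.4284
#: mtDNA differentiation of the same populations (earlier companion survey).
TOONA_FST_MT = 0.8884

LOCI = ("psba_trnh", "trnl_trnl")


def _read(name: str) -> pd.DataFrame:
    with resources.files("haplogeo.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def toona_sites() -> pd.DataFrame:
    """Survey localities: population code, location, n, lon/lat, elevation."""
    return _read("toona_sites.tsv")


def toona_diversity(locus: str | None = None) -> pd.DataFrame:
    """Published per-population h and pi.

    With ``locus`` in ``{"psba_trnh", "trnl_trnl"}``, returns the columns
    for that fragment as ``population``, ``h``, ``pi``; otherwise the full
    table.
    """
    df = _read("toona_diversity.tsv")
    if locus is None:
        return df
    if locus not in LOCI:
        raise ValueError(f"locus must be one of {LOCI}")
    out = df[["population", f"h_{locus}", f"pi_{locus}"]].copy()
    out.columns = ["population", "h", "pi"]
    return out
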