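"""Alignment and metadata I/O, cleaning, concatenation and haplotype collapsing.

The central containers are :class:`Alignment` (an aligned set of haploid
sequences for one locus, stored as a byte matrix), a validated sample table
(a pandas DataFrame with one row per sequenced individual), and
:class:`HaplotypeTable` (distinct sequence variants with a population x
haplotype count matrix).

Sequences are normalised on ingest: uppercased, RNA ``U`` mapped to ``T``,
and IUPAC ambiguity codes other than ``A/C/G/T/-/N`` mapped to ``N``.  For
haplotype and diversity work, sites containing a gap or ``N`` in *any*
sequence are removed first ("complete deletion"), so that two individuals
share a haplotype iff they are identical at every retained site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentLengthError,
    DegenerateDataError,
    FormatError,
    SchemaError,
    ValidationError,
)

VALID_BASES = frozenset(b"ACGT")
MASK_CHARS = frozenset(b"-N")

SAMPLE_TABLE_COLUMNS = ("sample_id", "population", "longitude", "latitude", "elevation")


def _normalise_seq(seq: str) -> bytes:
    """Uppercase, U->T, any non-ACGT/- symbol -> N."""
    s = seq.upper().replace("U", "T")
    out = bytearray(len(s))
    for i, ch in enumerate(s.encode("ascii", errors="replace")):
        if ch in VALID_BASES or ch == ord("-"):
            out[i] = ch
        else:
            out[i] = ord("N")
    return bytes(out)


@dataclass(frozen=True)
class Alignment:
    """An aligned set of equal-length haploid sequences for one locus.

    Attributes
    ----------
    locus_name : str
        Free-text locus label (e.g. ``"psbA-trnH"``).
    sample_ids : tuple of str
        Unique sample identifiers, in file order.
    matrix : numpy.ndarray
        ``(n_samples, n_sites)`` array of dtype ``S1`` over ``{A,C,G,T,-,N}``.
    """

    locus_name: str
    sample_ids: tuple
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValidationError("alignment matrix must be 2-D")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValidationError("sample_ids and matrix rows disagree")
        if self.matrix.shape[1] == 0:
            raise DegenerateDataError("alignment has zero sites")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in alignment")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def sequences(self) -> list:
        """Sequences as plain strings, in ``sample_ids`` order."""
        return [row.tobytes().decode() for row in self.matrix]

    @classmethod
    def from_sequences(cls, locus_name: str, sample_ids: Iterable[str], seqs: Iterable[str]) -> "Alignment":
        ids = list(sample_ids)
        rows = [_normalise_seq(s) for s in seqs]
        if not rows:
            raise FormatError("no sequences given")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentLengthError(
                f"ragged alignment: record lengths {sorted(lengths)}"
            )
        mat = np.frombuffer(b"".join(rows), dtype="S1").reshape(len(rows), lengths.pop())
        return cls(locus_name, tuple(ids), mat.copy())

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Row-subset the alignment, preserving the order of *ids*."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"samples not in alignment: {missing}")
        rows = [index[s] for s in ids]
        return Alignment(self.locus_name, tuple(ids), self.matrix[rows])


def read_alignment(path, locus_name: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Record order is preserved; sequences are normalised (uppercase, U->T,
    non-IUPAC -> N).  Raises :class:`FormatError` on an empty file and
    :class:`AlignmentLengthError` on ragged records.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment.from_sequences(
        locus_name, [r.id for r in records], [str(r.seq) for r in records]
    )


def write_alignment(a: Alignment, path) -> None:
    """Write an alignment as sequential (unwrapped) FASTA."""
    with open(path, "w") as fh:
        for sid, seq in zip(a.sample_ids, a.sequences):
            fh.write(f">{sid}\n{seq}\n")


def read_sample_table(path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Required columns: ``sample_id``, ``population``, ``longitude``,
    ``latitude``, ``elevation`` (metres).  Population codes are kept
    verbatim.  Raises :class:`SchemaError` on missing columns and
    :class:`ValidationError` on duplicate sample ids or empty populations.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    return validate_sample_table(df)


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample table missing columns: {missing}")
    df = df.loc[:, list(SAMPLE_TABLE_COLUMNS)].copy()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    pops = df["population"].astype(str)
    if (pops.str.strip() == "").any() or df["population"].isna().any():
        raise ValidationError("empty population code in sample table")
    if (df["elevation"] < 0).any():
        raise ValidationError("negative elevation in sample table")
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(SAMPLE_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def masked_site_columns(a: Alignment) -> np.ndarray:
    """Boolean mask of sites containing '-' or 'N' in any sequence."""
    mat = a.matrix
    return (mat == b"-").any(axis=0) | (mat == b"N").any(axis=0)


def clean_alignment(a: Alignment, policy: str = "complete") -> Alignment:
    """Apply a site-mask policy.

    ``"complete"`` (complete deletion) drops every site at which any
    sequence carries ``-`` or ``N``; ``"pairwise"`` keeps all sites (the
    downstream statistic is expected to handle masks per pair).  Raises
    :class:`DegenerateDataError` if complete deletion removes every site.
    """
    if policy == "pairwise":
        return a
    if policy != "complete":
        raise ValueError(f"unknown cleaning policy {policy!r}")
    bad = masked_site_columns(a)
    if bad.all():
        raise DegenerateDataError("complete deletion removed all sites")
    if not bad.any():
        return a
    return Alignment(a.locus_name, a.sample_ids, a.matrix[:, ~bad])


def concatenate(a: Alignment, b: Alignment) -> Alignment:
    """Join two loci sample-wise; *b* is reordered to *a*'s sample order."""
    sa, sb = set(a.sample_ids), set(b.sample_ids)
    if sa != sb:
        raise ValidationError(
            f"sample sets differ: only in first {sorted(sa - sb)}, "
            f"only in second {sorted(sb - sa)}"
        )
    b_ordered = b.subset(a.sample_ids)
    mat = np.concatenate([a.matrix, b_ordered.matrix], axis=1)
    return Alignment(f"{a.locus_name}+{b.locus_name}", a.sample_ids, mat)


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes with per-population counts.

    ``counts`` is a populations x haplotypes integer DataFrame; haplotype
    labels are ``H1..Hk`` by descending overall abundance, ties broken by
    first occurrence in sample order.
    """

    haplotype_ids: tuple
    haplotype_seqs: tuple
    counts: pd.DataFrame = field(repr=False)
    sample_haplotype: pd.Series = field(repr=False)  # sample_id -> haplotype label

    def __post_init__(self):
        if list(self.counts.columns) != list(self.haplotype_ids):
            raise ValidationError("counts columns must equal haplotype_ids")
        if len(set(self.haplotype_seqs)) != len(self.haplotype_seqs):
            raise ValidationError("haplotype sequences not distinct")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative haplotype counts")

    @property
    def populations(self) -> list:
        return list(self.counts.index)

    @property
    def frequencies(self) -> pd.DataFrame:
        """Per-population haplotype frequencies (rows sum to 1)."""
        n = self.counts.sum(axis=1)
        return self.counts.div(n.where(n > 0, 1), axis=0)

    @property
    def overall_abundance(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def seq_of(self, label: str) -> str:
        return self.haplotype_seqs[self.haplotype_ids.index(label)]


def collapse_haplotypes(a: Alignment, samples: pd.DataFrame) -> HaplotypeTable:
    """Collapse identical cleaned sequences into haplotypes.

    Complete deletion is applied first so that haplotype identity is exact
    string equality on fully resolved sites.  Labels ``H1..Hk`` are ordered
    by descending overall abundance, ties by first occurrence.
    """
    samples = validate_sample_table(samples)
    extra = set(a.sample_ids) - set(samples["sample_id"])
    if extra:
        raise ValidationError(f"alignment samples missing from table: {sorted(extra)}")
    clean = clean_alignment(a, "complete")
    seqs = clean.sequences
    first_seen: dict = {}
    members: dict = {}
    for i, s in enumerate(seqs):
        if s not in first_seen:
            first_seen[s] = i
            members[s] = []
        members[s].append(clean.sample_ids[i])
    order = sorted(first_seen, key=lambda s: (-len(members[s]), first_seen[s]))
    labels = [f"H{i + 1}" for i in range(len(order))]
    by_seq = dict(zip(order, labels))
    sample_hap = pd.Series(
        {sid: by_seq[s] for s, ms in members.items() for sid in ms},
        name="haplotype",
    ).loc[list(clean.sample_ids)]
    pop_of = samples.set_index("sample_id")["population"]
    pops = list(dict.fromkeys(pop_of.loc[list(clean.sample_ids)]))
    counts = pd.DataFrame(0, index=pops, columns=labels, dtype=int)
    for sid in clean.sample_ids:
        counts.loc[pop_of[sid], sample_hap[sid]] += 1
    return HaplotypeTable(tuple(labels), tuple(order), counts, sample_hap)


def write_haplotypes(h: HaplotypeTable, fasta_path, counts_path) -> None:
    """Write haplotype sequences (FASTA) and the count matrix (TSV)."""
    if not h.haplotype_ids:
        raise DegenerateDataError("empty haplotype table")
    with open(fasta_path, "w") as fh:
        for label, seq in zip(h.haplotype_ids, h.haplotype_seqs):
            fh.write(f">{label}\n{seq}\n")
    h.counts.rename_axis("population").to_csv(counts_path, sep="\t")


def read_haplotypes(fasta_path, counts_path) -> HaplotypeTable:
    """Inverse of :func:`write_haplotypes` (sample assignment is not stored)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {fasta_path}")
    labels = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    counts = pd.read_csv(counts_path, sep="\t", index_col="population")
    counts = counts.loc[:, list(labels)].astype(int)
    sample_hap = pd.Series(dtype=object)
    return HaplotypeTable(labels, seqs, counts, sample_hap)


def population_partition(samples: pd.DataFrame) -> dict:
    """Mapping population code -> list of sample ids (table order)."""
    out: dict = {}
    for sid, pop in zip(samples["sample_id"], samples["population"]):
        out.setdefault(pop, []).append(sid)
    return out


def drop_empty_populations(counts: pd.DataFrame) -> pd.DataFrame:
    n = counts.sum(axis=1)
    empty = n[n == 0].index.tolist()
    if empty:
        warnings.warn(f"excluding populations with no samples: {empty}")
        counts = counts.drop(index=empty)
    return counts
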