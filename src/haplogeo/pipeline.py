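"""End-to-end analysis orchestration.

``run_full_analysis`` takes two (or more) locus FASTA files plus a sample
metadata table and emits the full report bundle: per-locus diversity
tables, AMOVA blocks (per locus and concatenated), Gst/Nst with the
phylogeographic permutation test, pairwise Fst matrices, IBD fits,
diversity-elevation correlations, the per-population neutrality +
mismatch table, and (given an external mtDNA Fst) the island-model
mutation/seed-flow ratio.  Outputs are deterministic for a fixed seed:
rounded display tables under ``tables/``, full-precision values under
``raw/``, and a JSON manifest recording the seed and replicate counts.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import demography as dem
from . import diversity as dv
from . import geo
from . import island
from . import structure as st
from .io import (
    Alignment,
    clean_alignment,
    collapse_haplotypes,
    concatenate,
    read_alignment,
    read_sample_table,
    validate_sample_table,
    write_haplotypes,
)

log = logging.getLogger("haplogeo")


@dataclass(frozen=True)
class PipelineConfig:
    locus_paths: tuple          # ((locus_name, fasta_path), ...)
    metadata_path: str
    out_dir: str
    seed: int
    n_perm: int = 1000
    n_boot: int = 100
    n_neutrality: int = 1000
    fst_mt: float | None = None
    clamp_negative_fst: bool = True
    sample_sd: bool = True
    tail: str = "lower"
    run_demography: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.n_perm < 100 or self.n_boot < 100 or self.n_neutrality < 100:
            raise ValueError("replicate counts below the supported minimums")


def _spawn_seeds(seed: int, n: int) -> list:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _write(df: pd.DataFrame, out: Path, name: str):
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "raw").mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "tables" / name, sep="\t", index=False, float_format="%.4f")
    df.to_csv(out / "raw" / name, sep="\t", index=False)


def _zero_if_nan(x: float) -> float:
    return 0.0 if not math.isfinite(x) else x


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Run every stage and return {report name: DataFrame}; files under out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = (
        validate_sample_table(cfg.metadata_path)
        if isinstance(cfg.metadata_path, pd.DataFrame)
        else read_sample_table(cfg.metadata_path)
    )
    loci = []
    for name, path in cfg.locus_paths:
        aln = path if isinstance(path, Alignment) else read_alignment(path, name)
        loci.append((name, clean_alignment(aln, "complete")))
    concat = loci[0][1]
    for _, aln in loci[1:]:
        concat = concatenate(concat, aln)
    concat = clean_alignment(concat, "complete")
    all_units = loci + [("concatenated", concat)]
    seeds = _spawn_seeds(cfg.seed, 4 * len(all_units) + 2)
    seed_iter = iter(seeds)
    reports: dict = {}

    km = geo.geographic_distance_matrix(samples)
    amova_blocks = []
    structure_rows = []
    ibd_rows = []
    elev_rows = []
    for name, aln in all_units:
        log.info("analysing %s (%d samples, %d sites)", name, aln.n_samples, aln.length)
        haps = collapse_haplotypes(aln, samples)
        write_haplotypes(
            haps, out / f"haplotypes_{name}.fasta", out / f"haplotype_counts_{name}.tsv"
        )
        rows = dv.population_summary(haps, aln, samples)
        div = dv.summary_frame(rows)
        _write(div, out, f"diversity_{name}.tsv")
        reports[f"diversity_{name}"] = div

        try:
            hap_d = st.haplotype_distance_matrix(haps)
            nst_v, gst_v, p_ng = st.nst_gst_permutation_test(
                haps, hap_d, n_perm=cfg.n_perm, seed=next(seed_iter)
            )
        except Exception as exc:
            warnings.warn(f"Nst/Gst undefined for {name}: {exc}")
            nst_v = gst_v = p_ng = float("nan")
        fst_overall = st.hudson_fst(aln, samples)
        structure_rows.append(
            {"marker": name, "gst": gst_v, "nst": nst_v, "p_nst_gt_gst": p_ng,
             "fst_hudson": fst_overall}
        )

        d = st.pairwise_difference_matrix(aln)
        am = st.amova(d, samples, n_perm=cfg.n_perm, seed=next(seed_iter))
        amova_blocks.append(st.amova_frame(am, name))
        reports[f"amova_{name}"] = am

        pw = st.pairwise_hudson_fst(aln, samples)
        pd.DataFrame(pw.values, index=pw.labels, columns=pw.labels).rename_axis(
            "population"
        ).to_csv(out / f"pairwise_fst_{name}.tsv", sep="\t")
        try:
            fit = geo.ibd_regression(
                pw, km.reorder(pw.labels), n_perm=cfg.n_perm, seed=next(seed_iter),
                clamp_negative_fst=cfg.clamp_negative_fst,
            )
            ibd_rows.append({"marker": name, **fit.__dict__})
            _write(
                geo.ibd_pairs_frame(pw, km.reorder(pw.labels), cfg.clamp_negative_fst),
                out, f"ibd_pairs_{name}.tsv",
            )
        except Exception as exc:  # degenerate Fst matrices stay reported
            warnings.warn(f"IBD regression skipped for {name}: {exc}")

        pops = [r.population for r in rows if r.population != "Total"]
        hvals = [r.h for r in rows if r.population != "Total"]
        elev = geo.population_coordinates(samples).loc[pops, "elevation"]
        try:
            corr = geo.diversity_elevation_correlation(hvals, elev)
            elev_rows.append(
                {"marker": name, "r": corr.r, "p_value": corr.p_value, "n": corr.n}
            )
        except Exception as exc:
            warnings.warn(f"elevation correlation skipped for {name}: {exc}")
        next(seed_iter)  # reserved per-unit slot keeps seed layout stable

    structure_df = pd.DataFrame(structure_rows)
    _write(structure_df, out, "structure.tsv")
    reports["structure"] = structure_df
    amova_df = pd.concat(amova_blocks, ignore_index=True)
    _write(amova_df, out, "amova.tsv")
    reports["amova"] = amova_df
    ibd_df = pd.DataFrame(ibd_rows)
    _write(ibd_df, out, "ibd.tsv")
    reports["ibd"] = ibd_df
    elev_df = pd.DataFrame(elev_rows)
    _write(elev_df, out, "elevation_correlation.tsv")
    reports["elevation_correlation"] = elev_df

    if cfg.run_demography:
        demo_df, spectra = _demography_table(cfg, concat, samples, next(seed_iter))
        _write(demo_df, out, "neutrality_mismatch.tsv")
        reports["neutrality_mismatch"] = demo_df
        _write(spectra, out, "mismatch_spectra.tsv")
        reports["mismatch_spectra"] = spectra

    if cfg.fst_mt is not None:
        phi_cp = reports["amova_concatenated"].phi_st
        est = island.mu_over_ms(phi_cp, cfg.fst_mt)
        isl = pd.DataFrame(
            [{"fst_cp": est.fst_cp, "fst_mt": est.fst_mt,
              "mu_over_ms": est.mu_over_ms, "assumptions": est.assumptions}]
        )
        _write(isl, out, "island_model.tsv")
        reports["island_model"] = isl

    manifest = {
        "package": "haplogeo",
        "version": __version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "n_boot": cfg.n_boot,
        "n_neutrality": cfg.n_neutrality,
        "loci": [name for name, _ in cfg.locus_paths],
        "n_samples": int(len(samples)),
        "n_populations": int(samples["population"].nunique()),
        "reports": sorted(reports),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    reports["manifest"] = manifest
    return reports


def _demography_table(cfg: PipelineConfig, concat: Alignment, samples, seed: int):
    """Per-population neutrality + mismatch table (survey shape) and spectra."""
    from .io import population_partition

    parts = population_partition(samples)
    pops = [p for p in parts if any(s in concat.sample_ids for s in parts[p])]
    seeds = _spawn_seeds(seed, 2 * len(pops))
    rows = []
    spectra_rows = []
    for i, pop in enumerate(pops):
        ids = [s for s in parts[pop] if s in concat.sample_ids]
        if len(ids) < 2:
            log.warning("population %s has n < 2; demography skipped", pop)
            continue
        sub = concat.subset(ids)
        res = dem.neutrality_tests(
            sub, pop, n_reps=cfg.n_neutrality, seed=seeds[2 * i]
        )
        obs = dem.mismatch_observed(sub)
        fit = dem.fit_expansion(obs)
        fit = dem.bootstrap_mismatch_tests(
            fit, n=len(ids), n_reps=cfg.n_boot, seed=seeds[2 * i + 1]
        )
        rows.append(
            {
                "population": pop,
                "n": res.n,
                "S": res.s,
                "k_hat": res.k_hat,
                "tajima_d": _zero_if_nan(res.tajima_d),
                "p_d": res.p_d,
                "fu_fs": _zero_if_nan(res.fu_fs),
                "p_fs": res.p_fs,
                "ssd": fit.ssd,
                "p_ssd": fit.p_ssd,
                "raggedness": fit.raggedness,
                "p_rag": fit.p_rag,
                "theta0": fit.theta0,
                "theta1": fit.theta1,
                "tau": fit.tau,
            }
        )
        for k, (o, e) in enumerate(zip(fit.observed_spectrum, fit.expected_spectrum)):
            spectra_rows.append(
                {"population": pop, "differences": k, "observed": o, "expected": e}
            )
    return pd.DataFrame(rows), pd.DataFrame(spectra_rows)
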