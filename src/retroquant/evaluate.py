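"""End-to-end evaluation runs on the named study configurations.

Each function simulates a dataset from a preset, runs the standard
analysis chain on it, and returns the measured quantity next to the
planted value. These are the routines behind the calibration and
parameter-recovery checks and the results-reproduction script.

ChIP evaluation counts the generator's fragments directly: the simulator
emits no PCR duplicates, and on a megabase-scale genome at these depths
positional collisions are expected chance events, so rmdup-style removal
would systematically deflate enriched regions (duplicate removal is
exercised separately on inputs that do contain artifactual duplicates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import presets
from .chip import count_by_unit, enrichment, icr_occupancy, ltr_metaprofile
from .annotation import AlignedFragmentSet
from .rna import background_adjust, fpkm, log2fc, reactivation_report
from .screen import screen
from .simulate import (
    SimulationConfig,
    simulate_chip_experiment,
    simulate_genome,
    simulate_peptide_table,
    simulate_rna_counts,
)

OGLCNAC_KEY = {"assay": "chip", "target": "O-GlcNAc", "condition": "WT"}
INPUT_KEY = {"assay": "input", "target": "", "condition": "WT"}


def _seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31 - 1)) for s in ss]


def _chip_ratios(config: SimulationConfig, seed: int) -> tuple[pd.DataFrame, dict]:
    cfg = config
    build = simulate_genome(cfg, seed=seed, with_sequence=False)
    samples, manifest, truth = simulate_chip_experiment(cfg, build, seed=seed)
    counts = count_by_unit(samples, build.annotation)
    res = enrichment(counts, manifest, OGLCNAC_KEY, INPUT_KEY)
    return res.table, truth.chip_enrichment["O-GlcNAc"]


def chip_null_exceedance(n_seeds: int = 100, base_seed: int = 0, tau: float = 1.5) -> dict:
    """Fraction of units with E > tau under e = 1, pooled over seeds."""
    n_exceed = n_units = 0
    for s in _seeds(base_seed, n_seeds):
        table, _ = _chip_ratios(presets.chip_null_config(s), s)
        n_exceed += int((table["ratio"] > tau).sum())
        n_units += len(table)
    return {"fraction_exceeding": n_exceed / n_units, "n_units": n_units, "tau": tau}


def chip_recovery(seed: int = 0) -> dict:
    """Estimated enrichment of the subfamily planted at e = 4."""
    table, planted = _chip_ratios(presets.chip_recovery_config(seed), seed)
    est = float(table.loc["IAPLTR1", "ratio"])
    return {"estimated": est, "planted": planted["IAPLTR1"], "relative_error": est / 4.0 - 1.0}


def metaprofile_contrast(seed: int = 0, n_bins: int = 20) -> dict:
    """5'LTR / 3'LTR coverage contrast under a planted 3x promoter boost."""
    cfg = presets.metaprofile_config(seed)
    build = simulate_genome(cfg, seed=seed, with_sequence=False)
    samples, manifest, truth = simulate_chip_experiment(cfg, build, seed=seed)
    chip_ids = [e.sample_id for e in manifest.select(assay="chip", target="O-GlcNAc")]
    pooled = AlignedFragmentSet(
        pd.concat([samples[sid].frame for sid in chip_ids], ignore_index=True)
    ).sorted()
    mp = ltr_metaprofile(pooled, build.annotation, "IAPEz", n_bins=n_bins,
                         contig_lengths=build.contig_lengths)
    return {
        "contrast": mp.contrast,
        "planted_boost": truth.promoter_boost["O-GlcNAc"]["IAPEz"],
        "n_elements": mp.n_elements,
    }


def icr_classification(seed: int = 0, null: bool = False, tau: float = 1.5) -> dict:
    """Cross-classification of ICRs by O-GlcNAc / TRIM28 enrichment."""
    cfg = presets.icr_null_config(seed) if null else presets.icr_config(seed)
    build = simulate_genome(cfg, seed=seed, with_sequence=False)
    samples, manifest, _ = simulate_chip_experiment(cfg, build, seed=seed)
    _, summary = icr_occupancy(samples, build.icrs, manifest,
                               ["O-GlcNAc", "TRIM28"], tau=tau)
    return summary


def _rna_log2fc(config: SimulationConfig, seed: int, depth: int,
                cond_a: str, cond_b: str) -> tuple[pd.Series, dict]:
    build = simulate_genome(config, seed=seed, with_sequence=False)
    counts, manifest, truth = simulate_rna_counts(build.annotation, config.rna, depth, seed)
    expr = background_adjust(fpkm(counts), build.annotation)
    diff = log2fc(expr, manifest, cond_a, cond_b)
    return diff, truth


def rna_null_abs_log2fc(n_seeds: int = 100, base_seed: int = 0, depth: int = 100_000) -> dict:
    """|log2FC| of every expressed unit under the all-null configuration.

    Background-class (DNA-transposon) units are excluded: they are the
    subtraction reference, so their adjusted expression is the floored
    residual around zero and their fold change is not a meaningful
    estimate of anything planted.
    """
    values: list[float] = []
    for s in _seeds(base_seed, n_seeds):
        diff, _ = _rna_log2fc(presets.rna_null_config(s), s, depth, "Dnmt1KO", "WT")
        t = diff.table.drop("__background_pooled__", errors="ignore")
        lfc = t.loc[t["class_"] != "DNA", "log2fc"]
        values.extend(np.abs(lfc.to_numpy()))
    return {"median_abs_log2fc": float(np.median(values)), "n_values": len(values)}


def rna_grid_recovery(seed: int = 0, depth: int = 1_000_000) -> dict:
    """Recovery of the planted log2FC grid {0, 1, 2, 3, 4}."""
    diff, truth = _rna_log2fc(presets.rna_recovery_config(seed), seed, depth, "Dnmt1KO", "WT")
    est = {v: float(diff.table.loc[f"GRID_lfc{int(v)}", "log2fc"]) for v in presets.RNA_GRID}
    errors = [abs(est[v] - v) for v in presets.RNA_GRID]
    return {"estimates": est, "mean_abs_error": float(np.mean(errors))}


def reactivation_specificity(n_seeds: int = 100, base_seed: int = 0,
                             depth: int = 1_000_000) -> dict:
    """Fraction of seeds where exactly the planted subfamily is called."""
    n_exact = 0
    for s in _seeds(base_seed, n_seeds):
        diff, _ = _rna_log2fc(presets.rna_reactivation_config(s), s, depth,
                              "dCas9-OGA", "dCas9-OGA_D242A")
        rep = reactivation_report({"oga": diff})
        called = set(rep.loc[rep["reactivated"], "unit"])
        n_exact += called == {"IAPEz"}
    return {"specificity": n_exact / n_seeds, "n_seeds": n_seeds}


def screen_rank_first(n_seeds: int = 200, base_seed: int = 0) -> dict:
    """How often the planted interactor ranks first by the screen statistic."""
    n_first = 0
    separations = []
    for s in _seeds(base_seed, n_seeds):
        table, _ = simulate_peptide_table(presets.screen_config(s).proteomics, s)
        result = screen(table)
        n_first += result.table.index[0] == "OGT"
        top = result.table["ratio"]
        separations.append(float(top.iloc[0] / top.iloc[1]))
    return {
        "fraction_rank_first": n_first / n_seeds,
        "median_separation": float(np.median(separations)),
        "n_seeds": n_seeds,
    }


def screen_null_no_hit(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """How often an all-background table yields zero hits at default filters."""
    n_clean = 0
    for s in _seeds(base_seed, n_seeds):
        table, _ = simulate_peptide_table(presets.screen_null_config(s).proteomics, s)
        result = screen(table)
        n_clean += int(result.table["hit"].sum()) == 0
    return {"fraction_no_hit": n_clean / n_seeds, "n_seeds": n_seeds}
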