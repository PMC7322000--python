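"""Named study configurations for the synthetic experiments.

Each preset fixes one desk-scale experimental condition: genome size,
repeat landscape, planted effects, depths and replicate structure. They
are constants of the package, not tuning knobs — tests and the
reproduction script run them as given. Scaled-down dimensions (a 2 Mb
single-contig genome, 1e5 ChIP fragments, 1e5-1e6 RNA fragments) keep every
run to seconds while leaving relative sampling error far below the effects
planted.
"""

from __future__ import annotations

from .simulate import (
    ChipSpec,
    ChipTargetSpec,
    FamilySpec,
    GenomeSpec,
    IcrSpec,
    ProteomicsSpec,
    RnaSpec,
    SimulationConfig,
)

# a small mouse-like landscape: an LTR-structured IAP-like ERVK family,
# solo LTRs, a LINE, a SINE and two dead DNA-transposon families
_IAP = FamilySpec("IAPEz", "LTR", "ERVK", n_copies=10, element_length=5000,
                  has_ltr_structure=True, ltr_length=400)
_SOLO = FamilySpec("IAPLTR1", "LTR", "ERVK", n_copies=20, element_length=400)
_LINE = FamilySpec("L1Md_T", "LINE", "L1", n_copies=10, element_length=3000)
_SINE = FamilySpec("B1_Mus1", "SINE", "Alu", n_copies=60, element_length=150)
_DNA1 = FamilySpec("Charlie1", "DNA", "hAT-Charlie", n_copies=20, element_length=1000)
_DNA2 = FamilySpec("Tigger1", "DNA", "TcMar-Tigger", n_copies=20, element_length=1000)

_ICRS = (
    IcrSpec("Kcnq1ot1", 2000, "maternal"),
    IcrSpec("Peg3", 2000, "maternal"),
    IcrSpec("Impact", 2000, "maternal"),
    IcrSpec("Dlk1-Gtl2", 2000, "paternal"),
)


def chip_null_config(seed: int = 0) -> SimulationConfig:
    """Everything at e = 1: the null for enrichment-ratio calibration."""
    return SimulationConfig(
        seed=seed,
        genome=GenomeSpec(1, 2_000_000),
        families=(
            FamilySpec("IAPEz", "LTR", "ERVK", 20, 1000),
            FamilySpec("IAPLTR1", "LTR", "ERVK", 20, 1000),
            FamilySpec("L1Md_T", "LINE", "L1", 20, 1000),
            FamilySpec("B1_Mus1", "SINE", "Alu", 20, 1000),
            FamilySpec("MTA_Mm", "LTR", "ERVL-MaLR", 20, 1000),
            FamilySpec("RLTR10", "LTR", "ERVK", 20, 1000),
            FamilySpec("Charlie1", "DNA", "hAT-Charlie", 20, 1000),
            FamilySpec("Tigger1", "DNA", "TcMar-Tigger", 20, 1000),
        ),
        icrs=_ICRS,
        chip=ChipSpec(
            targets=(ChipTargetSpec("O-GlcNAc", n_chip_replicates=3, n_control_replicates=2),),
            depth=100_000,
            fragment_length=200,
        ),
    )


def chip_recovery_config(seed: int = 0) -> SimulationConfig:
    """One subfamily occupying ~1% of the genome planted at e = 4."""
    return SimulationConfig(
        seed=seed,
        genome=GenomeSpec(1, 2_000_000),
        families=(
            FamilySpec("IAPLTR1", "LTR", "ERVK", 20, 1000),  # 20 kb at e = 4
            FamilySpec("Charlie1", "DNA", "hAT-Charlie", 20, 1000),
        ),
        chip=ChipSpec(
            targets=(
                ChipTargetSpec(
                    "O-GlcNAc",
                    enrichment={"IAPLTR1": 4.0},
                    n_chip_replicates=3,
                    n_control_replicates=2,
                ),
            ),
            depth=100_000,
            fragment_length=200,
        ),
    )


def chip_gradient_config(seed: int = 0) -> SimulationConfig:
    """Graded enrichment e in {1, 2, 4, 8} across four small subfamilies."""
    return SimulationConfig(
        seed=seed,
        genome=GenomeSpec(1, 2_000_000),
        families=(
            FamilySpec("FAM_e1", "LTR", "ERVK", 10, 1000),
            FamilySpec("FAM_e2", "LTR", "ERVK", 10, 1000),
            FamilySpec("FAM_e4", "LTR", "ERVK", 10, 1000),
            FamilySpec("FAM_e8", "LTR", "ERVK", 10, 1000),
        ),
        chip=ChipSpec(
            targets=(
                ChipTargetSpec(
                    "O-GlcNAc",
                    enrichment={"FAM_e1": 1.0, "FAM_e2": 2.0, "FAM_e4": 4.0, "FAM_e8": 8.0},
                    n_chip_replicates=3,
                    n_control_replicates=2,
                ),
            ),
            depth=100_000,
            fragment_length=200,
        ),
    )


def metaprofile_config(seed: int = 0) -> SimulationConfig:
    """LTR-structured IAP family with a 3x promoter boost on the 5'LTR."""
    return SimulationConfig(
        seed=seed,
        genome=GenomeSpec(1, 2_000_000),
        families=(_IAP,),
        chip=ChipSpec(
            targets=(
                ChipTargetSpec(
                    "O-GlcNAc",
                    enrichment={"IAPEz": 4.0},
                    promoter_boost={"IAPEz": 3.0},
                    n_chip_replicates=3,
                    n_control_replicates=2,
                ),
            ),
            depth=100_000,
            fragment_length=200,
        ),
    )


def icr_config(seed: int = 0) -> SimulationConfig:
    """Both targets enriched (e = 3) at every ICR; IAP families co-enriched.

    O-GlcNAc runs as ChIP triplicates against input duplicates; TRIM28 as a
    ChIP duplicate against an IgG control, mirroring the two assay designs.
    """
    return SimulationConfig(
        seed=seed,
        genome=GenomeSpec(1, 2_000_000),
        families=(_IAP, _SOLO, _DNA1, _DNA2),
        icrs=_ICRS,
        chip=ChipSpec(
            targets=(
                ChipTargetSpec(
                    "O-GlcNAc",
                    enrichment={"IAPEz": 4.0, "IAPLTR1": 4.0},
                    icr_enrichment={"*": 3.0},
                    n_chip_replicates=3,
                    control_assay="input",
                    n_control_replicates=2,
                ),
                ChipTargetSpec(
                    "TRIM28",
                    enrichment={"IAPEz": 4.0, "IAPLTR1": 4.0},
                    icr_enrichment={"*": 3.0},
                    n_chip_replicates=2,
                    control_assay="igg",
                    n_control_replicates=1,
                ),
            ),
            depth=100_000,
            fragment_length=200,
        ),
    )


def icr_null_config(seed: int = 0) -> SimulationConfig:
    """ICR occupancy null: both targets at e = 1 everywhere."""
    cfg = icr_config(seed)
    return SimulationConfig(
        seed=seed,
        genome=cfg.genome,
        families=cfg.families,
        icrs=cfg.icrs,
        chip=ChipSpec(
            targets=(
                ChipTargetSpec("O-GlcNAc", n_chip_replicates=3, n_control_replicates=2),
                ChipTargetSpec("TRIM28", n_chip_replicates=2, control_assay="igg",
                               n_control_replicates=1),
            ),
            depth=100_000,
            fragment_length=200,
        ),
    )


# RNA landscapes: 20 copies x 1 kb per quantified subfamily so unit counts
# aggregate per-copy biological noise; DNA transposons carry background only
_RNA_FAMILIES = (
    FamilySpec("IAPEz", "LTR", "ERVK", 20, 1000),
    FamilySpec("IAPLTR1", "LTR", "ERVK", 20, 1000),
    FamilySpec("MTA_Mm", "LTR", "ERVL-MaLR", 20, 1000),
    FamilySpec("L1Md_T", "LINE", "L1", 20, 1000),
    FamilySpec("B1_Mus1", "SINE", "Alu", 20, 1000),
    FamilySpec("Charlie1", "DNA", "hAT-Charlie", 30, 1000),
    FamilySpec("Tigger1", "DNA", "TcMar-Tigger", 30, 1000),
)
_RNA_BASELINE = {
    "IAPEz": 2000.0,
    "IAPLTR1": 1000.0,
    "MTA_Mm": 1000.0,
    "L1Md_T": 1500.0,
    "B1_Mus1": 1000.0,
}


def rna_null_config(seed: int = 0) -> SimulationConfig:
    """No condition effects: the null for log2FC calibration (3 vs 3)."""
    return SimulationConfig(
        seed=seed,
        genome=GenomeSpec(1, 2_000_000),
        families=_RNA_FAMILIES,
        rna=RnaSpec(
            conditions={"WT": 3, "Dnmt1KO": 3},
            expression=_RNA_BASELINE,
            effects={},
        ),
    )


RNA_GRID = (0.0, 1.0, 2.0, 3.0, 4.0)


def rna_recovery_config(seed: int = 0) -> SimulationConfig:
    """Planted log2FC grid {0..4} across five subfamilies (Dnmt1KO vs WT).

    The landscape keeps a large majority of unchanged, expressed
    subfamilies so the median-of-ratios normalization has the stable
    reference set it assumes; with only a handful of units the median
    order statistic would sit in the tail of the stable ratios and bias
    the size factors toward the perturbed units.
    """
    filler = tuple(
        FamilySpec(f"MLT1-{chr(65 + i)}", "LTR", "ERVL-MaLR", 20, 1000) for i in range(12)
    )
    fams = (
        tuple(FamilySpec(f"GRID_lfc{int(v)}", "LTR", "ERVK", 20, 1000) for v in RNA_GRID)
        + _RNA_FAMILIES
        + filler
    )
    return SimulationConfig(
        seed=seed,
        genome=GenomeSpec(1, 2_000_000),
        families=fams,
        rna=RnaSpec(
            conditions={"WT": 3, "Dnmt1KO": 3},
            expression={
                **{f"GRID_lfc{int(v)}": 2000.0 for v in RNA_GRID},
                **_RNA_BASELINE,
                **{f"MLT1-{chr(65 + i)}": 800.0 + 100.0 * i for i in range(12)},
            },
            effects={(f"GRID_lfc{int(v)}", "Dnmt1KO"): v for v in RNA_GRID},
        ),
    )


def rna_reactivation_config(seed: int = 0) -> SimulationConfig:
    """Reactivation planted only in IAPEz (targeted deglycosylation contrast).

    One replicate per condition, as in the dCas9-OGA experiment design.
    """
    return SimulationConfig(
        seed=seed,
        genome=GenomeSpec(1, 2_000_000),
        families=_RNA_FAMILIES,
        rna=RnaSpec(
            conditions={"dCas9-OGA": 1, "dCas9-OGA_D242A": 1},
            expression=_RNA_BASELINE,
            effects={("IAPEz", "dCas9-OGA"): 3.0},
        ),
    )


def screen_config(seed: int = 0) -> SimulationConfig:
    """Planted methylation-dependent interactor at means (20, 2) over 50
    correlated Poisson(5) background proteins."""
    return SimulationConfig(
        seed=seed,
        proteomics=ProteomicsSpec(
            n_background=50,
            background_mean=5.0,
            correlation=0.9,
            planted_hits=(("OGT", 20.0, 2.0),),
        ),
    )


def screen_null_config(seed: int = 0) -> SimulationConfig:
    """Background-only peptide tables (no planted hit)."""
    return SimulationConfig(
        seed=seed,
        proteomics=ProteomicsSpec(
            n_background=50,
            background_mean=5.0,
            correlation=0.9,
            planted_hits=(),
        ),
    )


def demo_config(seed: int = 0) -> SimulationConfig:
    """Small end-to-end demonstration: all assay types in one dataset."""
    return SimulationConfig(
        seed=seed,
        genome=GenomeSpec(1, 500_000),
        families=(
            FamilySpec("IAPEz", "LTR", "ERVK", 4, 5000, has_ltr_structure=True, ltr_length=400),
            FamilySpec("IAPLTR1", "LTR", "ERVK", 10, 400),
            FamilySpec("L1Md_T", "LINE", "L1", 5, 3000),
            FamilySpec("Charlie1", "DNA", "hAT-Charlie", 10, 1000),
        ),
        icrs=_ICRS[:2],
        chip=ChipSpec(
            targets=(
                ChipTargetSpec(
                    "O-GlcNAc",
                    enrichment={"IAPEz": 4.0, "IAPLTR1": 4.0},
                    promoter_boost={"IAPEz": 3.0},
                    icr_enrichment={"*": 3.0},
                    n_chip_replicates=2,
                    n_control_replicates=2,
                ),
            ),
            depth=20_000,
            fragment_length=200,
        ),
        rna=RnaSpec(
            conditions={"WT": 2, "Dnmt1KO": 2},
            expression={"IAPEz": 2000.0, "IAPLTR1": 500.0, "L1Md_T": 1000.0},
            effects={("IAPEz", "Dnmt1KO"): 3.0},
        ),
        proteomics=ProteomicsSpec(),
    )


PRESETS = {
    "chip-null": chip_null_config,
    "chip-recovery": chip_recovery_config,
    "chip-gradient": chip_gradient_config,
    "metaprofile": metaprofile_config,
    "icr": icr_config,
    "icr-null": icr_null_config,
    "rna-null": rna_null_config,
    "rna-recovery": rna_recovery_config,
    "rna-reactivation": rna_reactivation_config,
    "screen": screen_config,
    "screen-null": screen_null_config,
    "demo": demo_config,
}
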