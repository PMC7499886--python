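"""End-to-end convenience runs used by the CLI and the acceptance suite."""
from __future__ import annotations

import logging

import pandas as pd

from . import classify, methylome, sirna, synthetic
from .config import METH_STAGES, SimConfig

logger = logging.getLogger(__name__)


def classification_benchmark_config(seed: int = 1) -> SimConfig:
    """The default stated world used for label-recovery benchmarking."""
    return SimConfig(seed=seed)


def dmr_benchmark_config(seed: int = 2, dmr_effect: float = 0.40) -> SimConfig:
    """Methylome benchmark world: a 2 x 60-kb genome with 30 planted
    300-bp DMRs (scaled down from the 2 x 500-kb default so the
    pairwise RMS testing fits interactive budgets); class B lengths are
    shortened so the smaller centromeric window still packs."""
    return SimConfig(
        seed=seed,
        chrom_length=60_000,
        centromere_half_width=12_000,
        n_te_per_class={"A": 30, "B": 12, "depleted": 10},
        length_params={"A": (400.0, 0.5), "B": (1500.0, 0.4), "depleted": (500.0, 0.5)},
        n_dmr=30,
        dmr_length=300,
        dmr_effect=dmr_effect,
    )


def nucleosome_benchmark_config(seed: int = 3) -> SimConfig:
    """World with enough long heterochromatic TEs to populate the three
    nucleosome archetypes for profile-clustering benchmarks."""
    return SimConfig(
        seed=seed,
        chrom_length=250_000,
        centromere_half_width=62_000,
        n_te_per_class={"A": 30, "B": 40, "depleted": 10},
        length_params={"A": (400.0, 0.5), "B": (3000.0, 0.4), "depleted": (500.0, 0.5)},
        n_dmr=10,
    )


def quantify_all_libraries(
    annotation: synthetic.GenomeAnnotation,
    truth: synthetic.GroundTruth,
    config: SimConfig,
    size_range: tuple[int, int] = (24, 24),
) -> pd.DataFrame:
    """Simulate, reassign, and quantify every (stage, replicate) library.

    Returns the replicate-level TE x (sample, replicate) RPM table for
    the requested size class.
    """
    per_library = {}
    for stage in config.stages:
        for rep in range(1, config.n_replicates + 1):
            table = synthetic.simulate_sirna_reads(annotation, truth, stage, rep, config)
            weighted = sirna.reassign_multimappers(table, annotation.chrom_sizes)
            total = sirna.total_genome_matching(weighted)
            track = sirna.normalize_rpm(weighted, total, annotation.chrom_sizes,
                                        size_range=size_range)
            per_library[(stage, rep)] = sirna.quantify_te(track, annotation.tes,
                                                          size_range=size_range)
            logger.info("quantified %s rep %d (%d reads)", stage, rep, total)
    return sirna.build_quant_table(per_library)


def classify_te_profiles(
    quant: pd.DataFrame,
    config: SimConfig,
    grid=tuple(range(2, 21, 2)),
    threshold_rpm: float = 2.0,
    seed: int = 0,
):
    """Replicate-mean profiles -> VEV GMM w/ BIC -> bipartite labels.

    The mixture is fitted on log2(RPM + 1) profiles (RPM spans orders of
    magnitude); detection thresholding and template correlation use the
    RPM scale.
    """
    import numpy as np

    mean = sirna.replicate_mean(quant, stage_order=config.stages)
    logX = np.log2(mean + 1.0)
    model = classify.select_model_bic(logX, G_grid=grid, seed=seed)
    labels = classify.assign_bipartite_classes(model.labels, mean,
                                               threshold_rpm=threshold_rpm)
    return mean, model, labels


def run_dmr_analysis(
    annotation: synthetic.GenomeAnnotation,
    truth: synthetic.GroundTruth,
    config: SimConfig,
    stages=METH_STAGES,
    fdr: float = 0.01,
    n_sim: int = 30000,
    seed: int = 0,
):
    """Simulate replicate methylomes, pool them per stage, and call
    merged pairwise CHH DMRs.

    Biological replicates are pooled before testing, so the effective
    per-site depth is n_replicates x coverage_per_cytosine. ``n_sim``
    defaults higher than the per-site default because the Monte-Carlo
    p-value floor 1/(n_sim+1) must undercut the Benjamini-Hochberg
    step-up threshold when tens of thousands of sites are tested.
    """
    sites = {}
    for s in stages:
        reps = [
            synthetic.simulate_methylome(annotation, truth, s, config, replicate=r)
            for r in range(1, config.n_replicates + 1)
        ]
        sites[s] = methylome.pool_replicates(reps)
    merged, per_comparison = methylome.pairwise_dmr_pipeline(
        sites, fdr=fdr, n_sim=n_sim, seed=seed
    )
    return sites, merged, per_comparison
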