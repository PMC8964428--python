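"""End-to-end orchestration of the prescription pipeline.

Stages run in dependency order on files the :mod:`cdp.io` readers understand:

1. CNS — case-control GSEA of every pathway in every cancer cohort;
2. generality — cross-cancer consistency scores from the CNS;
3. MoA — consensus clustering into LoF/SoF/GoF, generality reassignment;
4. prognostic — ssGSEA + optimal-cutoff log-rank survival screen;
5. PNS — pathway enrichment of every drug instance ranking, averaged;
6. prescription — PS = CNS - PNS, triplet filtering, network export.

Every run writes a JSON log recording the seed and every threshold applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .datatypes import ClinicalTable, ExpressionMatrix, GeneSetCollection, ScoreMatrix
from .enrichment import compute_cns
from .landscape import classify_moa, generality_frame, generality_table, reassign_moa
from .prescription import PerturbationProfile, build_triplet_network, compute_pns
from .survival import prognostic_screen

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with their published defaults.

    significance_alpha 0.05 (per-cancer enrichment significance), prognostic
    p 0.001, DEG filter |log2FC| > 2 at FDR < 0.01, |CNS| > 1.5 for the
    network, 1000 permutations, consensus clustering with 500 resamples at
    80% subsampling.
    """

    n_perm: int = 1000
    significance_alpha: float = 0.05
    p_threshold: float = 0.001
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.01
    cns_abs_threshold: float = 1.5
    min_group_frac: float = 0.1
    ssgsea_alpha: float = 0.25
    moa_resamples: int = 500
    moa_subsample: float = 0.8
    generality_reassign_threshold: float = 7.0
    metric: str = "signal_to_noise"
    permutation_scheme: str = "auto"
    top_k: int | None = None
    seed: int = 0
    outdir: str = "cdp_out"


@dataclass
class PipelineResult:
    cns: ScoreMatrix
    generality: pd.DataFrame
    moa: pd.DataFrame
    prognostic: pd.DataFrame
    pns: ScoreMatrix
    triplets: list
    log: dict = field(default_factory=dict)


def run_pipeline(
    cohorts: dict[str, ExpressionMatrix],
    sets: GeneSetCollection,
    clinical: dict[str, ClinicalTable],
    library: list[PerturbationProfile],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage and write the artifact bundle to ``config.outdir``."""
    config = config or PipelineConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config), "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        log["stages"][name] = "ok"

    try:
        stage("cns")
        cns = compute_cns(
            cohorts, sets,
            metric=config.metric,
            permutation_scheme=config.permutation_scheme,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        cio.write_score_matrix(cns, outdir / "cns.tsv")

        stage("generality")
        gen = generality_table(cns, alpha=config.significance_alpha)
        gen_df = generality_frame(gen)
        gen_df.to_csv(outdir / "generality.tsv", sep="\t")

        stage("moa")
        moa = classify_moa(
            cns,
            n_resample=config.moa_resamples,
            subsample=config.moa_subsample,
            seed=config.seed,
        )
        moa = reassign_moa(moa, gen, config.generality_reassign_threshold)
        moa_df = pd.DataFrame(
            [(a.pathway, a.cluster, a.reassigned, a.consensus_fraction) for a in moa],
            columns=["pathway", "cluster", "reassigned", "consensus_fraction"],
        ).set_index("pathway")
        moa_df.to_csv(outdir / "moa.tsv", sep="\t")

        stage("prognostic")
        if not clinical:
            raise ValueError("prognostic stage requires clinical tables")
        prog = prognostic_screen(
            cohorts, sets, clinical,
            p_threshold=config.p_threshold,
            min_group_frac=config.min_group_frac,
            alpha=config.ssgsea_alpha,
        )
        prog_df = pd.DataFrame(
            [
                (r.pathway, r.cancer, r.cutoff, r.p, r.direction, r.n_high, r.n_low)
                for r in prog
            ],
            columns=["pathway", "cancer", "cutoff", "p", "direction", "n_high", "n_low"],
        )
        prog_df.to_csv(outdir / "prognostic.tsv", sep="\t", index=False)

        stage("pns")
        pns = compute_pns(library, sets, n_perm=config.n_perm, seed=config.seed)
        cio.write_score_matrix(pns, outdir / "pns.tsv")

        stage("prescription")
        triplets = build_triplet_network(
            cns, pns, prog,
            cns_abs_threshold=config.cns_abs_threshold,
            top_k=config.top_k,
        )
        cio.export_triplet_network(triplets, outdir / "network.sif", "sif")
        cio.export_triplet_network(triplets, outdir / "network_edges.tsv", "edge-table")
    except Exception as exc:  # annotate with the failing stage and re-raise
        failed = next((s for s, v in log["stages"].items() if v == "ok"), "?")
        last = list(log["stages"])[-1] if log["stages"] else "setup"
        log["stages"][last] = f"failed: {exc}"
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {last!r} failed: {exc}") from exc

    log["n_triplets"] = len(triplets)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return PipelineResult(cns, gen_df, moa_df, prog_df, pns, triplets, log)
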