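"""Orchestration: simulate -> scan -> gene-drop -> single-locus, with a JSON report.

A single global seed deterministically derives independent per-stage seeds
via :class:`numpy.random.SeedSequence` spawning, so any stage can be rerun
on its own and reproduce the full run's result for that stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import genedrop as gd
from . import scan as sc
from . import simulate as sim
from . import single_locus as slm
from .io import extract_trios

log = logging.getLogger("embryoscan")


@dataclass
class RunConfig:
    """Top-level configuration for a full synthetic-study run."""

    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    scan_window_length: int = 400
    scan_min_freq: float = 0.001
    scan_alpha: float = 0.05
    genedrop_n_sims: int = 1000
    genedrop_n_sampled_cohorts: int = 3
    slm_generations: int = 20
    seed: int = 0
    outdir: str = "results/run"
    genotype_format: str = "haps-matrix"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_cfg = sim.SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim_cfg, **raw)


def stage_seeds(seed: int, n: int = 4) -> list:
    """Derive per-stage integer seeds (< 2**31) from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def table1_report(scan_results: pd.DataFrame, top_k: int = 3) -> pd.DataFrame:
    """Format the strongest deficiency hits as a summary table.

    Columns mirror the usual presentation of such scans: chromosome, window
    location in Mb, carrier x carrier matings, expected and observed
    homozygotes, percent fewer than expected, the chi-square p-value and df.
    Only deficits (O < E) qualify; one row per window is kept (best p).
    """
    cols = ["chr", "location_mb", "matings", "exp_hom", "obs_hom", "pct_fewer", "chi2_p", "df"]
    if scan_results.empty:
        return pd.DataFrame(columns=cols)
    df = scan_results[scan_results["o_hom"] < scan_results["e_hom"]].sort_values("p")
    df = df.head(top_k)
    return pd.DataFrame(
        {
            "chr": df["chr"].to_numpy(),
            "location_mb": [
                f"{s / 1e6:.2f}-{e / 1e6:.2f}" for s, e in zip(df["start_bp"], df["end_bp"])
            ],
            "matings": df["n_trios"].to_numpy(),
            "exp_hom": df["e_hom"].to_numpy(),
            "obs_hom": df["o_hom"].to_numpy(),
            "pct_fewer": [f"{v:.0f}%" for v in df["pct_fewer"]],
            "chi2_p": df["p"].to_numpy(),
            "df": 1,
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on one synthetic dataset; write and return the report.

    The report contains the top scan hits, gene-drop selection quantiles for
    the injected focal haplotype, and the matching deterministic single-locus
    expectations. Identical config + seed give an identical report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed, 3)

    log.info("simulate: %d cohorts from %d", config.sim.n_years, config.sim.start_year)
    cfg = dataclasses.replace(config.sim, seed=seeds[0])
    result = sim.simulate_dataset(cfg)
    sim.emit(result, outdir / "data", genotype_format=config.genotype_format)

    log.info("scan: window length %d", config.scan_window_length)
    scan_cfg = sc.ScanConfig(
        window_lengths=(config.scan_window_length,),
        min_freq=config.scan_min_freq,
        alpha=config.scan_alpha,
    )
    trios = extract_trios(result.pedigree, result.genotypes)
    scan_df = sc.scan_genome(result.genotypes, result.pedigree, scan_cfg, trios=trios)
    m_eff = sc.effective_tests_simplem(result.genotypes.allele_dosage())
    threshold = sc.significance_threshold(m_eff, config.scan_alpha)
    scan_df.to_csv(outdir / "scan.tsv", sep="\t", index=False)
    top = table1_report(scan_df)
    top.to_csv(outdir / "top_hits.tsv", sep="\t", index=False)

    log.info("gene drop: %d simulations", config.genedrop_n_sims)
    dosage = sim.focal_dosage(result.genotypes, result.pedigree, result.truth)
    gd_cfg = gd.GeneDropConfig(
        n_sims=config.genedrop_n_sims,
        n_sampled_cohorts=config.genedrop_n_sampled_cohorts,
        seed=seeds[1],
    )
    partition = gd.classify_cohorts(result.pedigree, gd_cfg)
    observed = gd.observed_series(result.pedigree, dosage, partition.years)
    sims = gd.gene_drop(result.pedigree, dosage, gd_cfg, partition=partition)
    summary = gd.gene_drop_summary(observed, sims, partition.simulated_years)

    log.info("single-locus expectations")
    q0 = float(observed.frequency[0])
    model = slm.SelectionModel.recessive(config.sim.s_embryo)
    traj = slm.trajectory(q0, model, config.slm_generations)

    truth_window = {
        "chr": result.truth.focal_chromosome,
        "start": result.truth.focal_start,
        "length": result.truth.focal_length,
    }
    report = {
        "seed": config.seed,
        "n_individuals": int(len(result.pedigree)),
        "n_trios": int(len(trios)),
        "n_culled_conceptuses": result.truth.n_culled,
        "injected_window": truth_window,
        "scan": {
            "n_tests": int(len(scan_df)),
            "m_eff": int(m_eff),
            "threshold": threshold,
            "top_hits": top.to_dict(orient="records"),
        },
        "gene_drop": {
            "observed_slope": summary.observed_slope,
            "directional_quantile": summary.directional_quantile,
            "slope_quantile_low": summary.slope_quantile_low,
            "observed_cumulative_change": summary.observed_cumulative_change,
            "balancing_quantile": summary.balancing_quantile,
        },
        "single_locus": {
            "q0": q0,
            "s": config.sim.s_embryo,
            "q_after_generations": float(traj.frequency[-1]),
            "generations": config.slm_generations,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
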