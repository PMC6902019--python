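"""End-to-end orchestration: quantify → differential → calls → classify.

One configuration drives the whole run; every random choice flows from a
single seed, so runs are idempotent.  The run report records the record
count at each stage, making the analysis funnel (identified → overlapping
→ fully quantified → candidates → calls) auditable on any input.
"""
from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import classify, quant, simulate, translocation
from .design import ExperimentDesign
from .differential import compute_differential

log = logging.getLogger("translokit")


@dataclass
class PipelineConfig:
    """Inputs, thresholds, and output location of one pipeline run."""

    psm_path: str | None = None
    design_path: str | None = None
    simulation: simulate.SimulationConfig | None = None
    fc_threshold: float = translocation.FC_THRESHOLD
    p_threshold: float = translocation.P_THRESHOLD
    protein_fdr: float = 0.01
    call_timepoint: int = 60
    k: int = 3
    seed: int = 0
    restarts: int = 25
    outdir: str | None = None

    def __post_init__(self):
        if not 0 < self.protein_fdr <= 1:
            raise ValueError("protein_fdr must lie in (0, 1]")
        if self.fc_threshold < 0 or not 0 < self.p_threshold <= 1:
            raise ValueError("thresholds out of range")
        if self.simulation is None and (self.psm_path is None or self.design_path is None):
            raise ValueError("provide either input paths or a simulation block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(
            simulation=simulate.SimulationConfig(**sim) if sim is not None else None,
            **raw,
        )
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the machine-readable run report.

    When ``config.outdir`` is set, all intermediate tables (quant matrix,
    PSM counts, differential statistics per contrast, calls, compartment
    assignments) and the report JSON are written there as TSV/JSON.
    """
    if config.simulation is not None:
        sim_cfg = config.simulation
        psms, design, ground_truth = simulate.simulate_experiment(sim_cfg)
    else:
        psms = quant.read_psm_tsv(config.psm_path)
        design = ExperimentDesign.from_tsv(config.design_path)
        ground_truth = None
    log.info("quantification: %d PSM rows", len(psms))
    matrix, funnel = quant.quantify(psms, design, fdr_threshold=config.protein_fdr)

    stats_by_tp = {}
    for tp in (15, 60):
        try:
            stats_by_tp[tp] = compute_differential(matrix, design, treatment=tp)
        except (ValueError, KeyError) as err:
            raise RuntimeError(f"differential stage failed for the {tp} min contrast: {err}") from err

    call_stats = stats_by_tp[config.call_timepoint]
    candidates = translocation.candidate_changing_set(call_stats, p_threshold=config.p_threshold)
    calls = translocation.call_translocations(
        call_stats, fc_threshold=config.fc_threshold, p_threshold=config.p_threshold
    )
    summary = translocation.summarize_calls(calls)

    assignments = classify.classify_compartments(
        matrix, design, k=config.k, seed=config.seed, restarts=config.restarts
    )
    pca = classify.pca_qc(matrix, design)

    report = {
        "seed": config.seed,
        "thresholds": {
            "fc_threshold": config.fc_threshold,
            "p_threshold": config.p_threshold,
            "protein_fdr": config.protein_fdr,
        },
        "funnel": {
            **funnel,
            "candidates_p_lt_threshold_2plus_fractions": len(candidates),
            "translocation_calls": summary["n_calls"],
        },
        "call_summary": summary,
        "pca_fraction_silhouette": pca.attrs["fraction_silhouette"],
        "compartment_counts": assignments["compartment"].value_counts().to_dict(),
    }

    if config.outdir is not None:
        out = pathlib.Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.to_tsv(out / "quant_matrix.tsv", out / "psm_counts.tsv")
        for tp, st in stats_by_tp.items():
            st.to_csv(out / f"diffstats_{tp}min.tsv", sep="\t", index=False)
        calls.to_csv(out / "translocation_calls.tsv", sep="\t")
        assignments.to_csv(out / "compartments.tsv", sep="\t")
        pca.to_csv(out / "pca_scores.tsv", sep="\t")
        if ground_truth is not None:
            ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def evaluate_calls(calls: pd.DataFrame, ground_truth: pd.DataFrame) -> dict:
    """Sensitivity and false-discovery proportion of calls vs ground truth."""
    truth = ground_truth.loc[~ground_truth["is_decoy"]].set_index("gene")["is_translocator"]
    called = set(calls.index[calls["pass"]])
    true_pos = {g for g in called if truth.get(g, False)}
    n_true = int(truth.sum())
    sensitivity = len(true_pos) / n_true if n_true else float("nan")
    fdp = (len(called) - len(true_pos)) / len(called) if called else 0.0
    return {
        "n_calls": len(called),
        "n_true_translocators": n_true,
        "sensitivity": sensitivity,
        "false_discovery_proportion": fdp,
    }
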