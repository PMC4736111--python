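"""End-to-end orchestration: simulate or ingest → QC → LD → models →
phase persistence → Ne trajectory, with a reproducible run manifest.

Every stage output is a pure function of (inputs, config, seed); a saved
:class:`RunConfig` re-executes to byte-identical TSV outputs.  A stage
failure propagates with the stage name attached and leaves the outputs of
completed stages intact on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .popdata import HaplotypeSet, read_phased_vcf, write_table
from .snpqc import QCThresholds, run_qc
from . import ldcore, ldmodels, nehist, phasepersist, synthpop

log = logging.getLogger("ldscape")


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run.

    Either ``input_vcfs`` (``{label: path}`` of phased VCFs) or
    ``simulate=True`` (two-breed synthetic study, parameters below) supplies
    the data.  All thresholds default to the standard array-QC values; bins,
    caps, thinning factors and panel sizes default to the analysis protocol
    (100 Kb bins to 10 Mb, thinning to 50/25/20/17/14/7 %, six commercial
    panels, 100 Mb cap for the Ne stage).
    """

    seed: int = 0
    simulate: bool = True
    input_vcfs: dict[str, str] = field(default_factory=dict)
    sim_params: dict[str, Any] = field(default_factory=dict)
    qc: dict[str, Any] = field(default_factory=dict)
    bin_width_bp: int = 100_000
    max_distance_bp: int = 10_000_000
    ne_max_distance_bp: int = 100_000_000
    thinning: list[int] = field(default_factory=lambda: [1, 2, 4, 5, 6, 7, 14])
    panel_sizes: list[int] = field(
        default_factory=lambda: list(ldmodels.COMMERCIAL_PANELS)
    )
    genome_mb: float = 3000.0
    ne_sample_size_correction: bool = False

    def to_dict(self) -> dict:
        # JSON round-trip normalizes tuples to lists so that a config read
        # back from YAML compares (and hashes) equal to the original
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage '{name}' failed: {e}") from e

        return wrapped

    return deco


@_stage("input")
def _load_inputs(config: RunConfig) -> dict[str, HaplotypeSet]:
    if config.simulate:
        pops = synthpop.simulate_two_breed_study(seed=config.seed, **config.sim_params)
        log.info("simulated populations: %s", {k: v.n_markers for k, v in pops.items()})
        return pops
    if not config.input_vcfs:
        raise ValueError("neither simulate=True nor input_vcfs given")
    return {
        label: read_phased_vcf(path, population_label=label)
        for label, path in config.input_vcfs.items()
    }


@_stage("qc")
def _qc_stage(pops, config: RunConfig, out_dir: str):
    thr = QCThresholds(**config.qc)
    out = {}
    reports = []
    for label, h in pops.items():
        g = h.to_genotypes()
        g_f, rpt = run_qc(g, thr, drop_monomorphic=True)
        keep = np.isin(h.map.snp_id, g_f.map.snp_id)
        out[label] = h.select_markers(keep)
        frame = rpt.to_frame()
        frame.insert(0, "population", label)
        reports.append(frame)
        log.info(
            "QC %s: %d/%d markers retained", label, g_f.n_markers, g.n_markers
        )
    write_table(pd.concat(reports, ignore_index=True), os.path.join(out_dir, "qc_report.tsv"))
    return out


@_stage("ld")
def _ld_stage(pops, config: RunConfig, out_dir: str):
    pair_tables = {}
    adj_tables = {}
    bin_frames = []
    thin_frames = []
    pair_frames = []
    for label, h in pops.items():
        h = ldcore.drop_monomorphic(h)
        pairs = ldcore.syntenic_pairs(h, config.max_distance_bp)
        adj = ldcore.adjacent_pairs(h)
        bins = ldcore.bin_by_distance(
            pairs, config.bin_width_bp, config.max_distance_bp
        )
        thin = ldcore.thinning_experiment(h, config.thinning)
        pair_tables[label] = pairs
        adj_tables[label] = adj
        bins.insert(0, "population", label)
        thin.insert(0, "population", label)
        bin_frames.append(bins)
        thin_frames.append(thin)
        pq = pairs.copy()
        pq.insert(0, "population", label)
        pair_frames.append(pq)
        log.info(
            "LD %s: %d syntenic pairs (<= %d bp), %d adjacent pairs",
            label, len(pairs), config.max_distance_bp, len(adj),
        )
    write_table(pd.concat(pair_frames, ignore_index=True), os.path.join(out_dir, "ld_pairs.tsv"))
    write_table(pd.concat(bin_frames, ignore_index=True), os.path.join(out_dir, "ld_bins.tsv"))
    write_table(pd.concat(thin_frames, ignore_index=True), os.path.join(out_dir, "thinning.tsv"))
    return pair_tables, adj_tables


@_stage("ldmodel")
def _model_stage(pair_tables, adj_tables, config: RunConfig, out_dir: str):
    if len(pair_tables) < 2:
        log.info("single population: ANCOVA stage skipped")
        return None
    rec_adj = ldmodels.make_model_records(adj_tables)
    rec_all = ldmodels.make_model_records(pair_tables)
    fit_adj = ldmodels.LDHeterogeneityModel(rec_adj, order=1).fit()
    fit_all = ldmodels.LDHeterogeneityModel(rec_all, order=3).fit()
    write_table(fit_adj.ls_means_by_chromosome(), os.path.join(out_dir, "ls_means.tsv"))
    preds = fit_all.predict_panel_grid(config.panel_sizes, config.genome_mb)
    write_table(preds, os.path.join(out_dir, "panel_predictions.tsv"))
    anova = pd.concat(
        [
            fit_adj.anova().assign(model="adjacent"),
            fit_all.anova().assign(model="syntenic"),
        ],
        ignore_index=True,
    )
    write_table(anova, os.path.join(out_dir, "model_anova.tsv"))
    with open(os.path.join(out_dir, "model_summary.txt"), "w") as fh:
        fh.write(fit_adj.summary() + "\n\n" + fit_all.summary() + "\n")
    return fit_adj, fit_all


@_stage("phase")
def _phase_stage(pair_tables, config: RunConfig, out_dir: str):
    if len(pair_tables) < 2:
        log.info("single population: phase-persistence stage skipped")
        return None
    labels = sorted(pair_tables)
    a, b = labels[0], labels[1]
    bins = phasepersist.phase_correlation(
        pair_tables[a], pair_tables[b], config.bin_width_bp, config.max_distance_bp
    )
    bins.insert(0, "pop_a", a)
    bins.insert(1, "pop_b", b)
    write_table(bins, os.path.join(out_dir, "phase_bins.tsv"))
    return bins


@_stage("ne")
def _ne_stage(pops, config: RunConfig, out_dir: str):
    frames = []
    for label, h in pops.items():
        h = ldcore.drop_monomorphic(h)
        pairs = ldcore.syntenic_pairs(h, config.ne_max_distance_bp)
        traj = nehist.ne_trajectory(
            pairs,
            sample_size_correction=config.ne_sample_size_correction,
            n_haplotypes=h.n_haplotypes,
        )
        traj.insert(0, "population", label)
        frames.append(traj)
        cur = traj[traj["available"]]
        if len(cur):
            log.info("Ne %s at t=%g: %.1f", label, cur.iloc[0]["t"], cur.iloc[0]["ne"])
    out = pd.concat(frames, ignore_index=True)
    write_table(out, os.path.join(out_dir, "ne_trajectory.tsv"))
    return out


def run_full_analysis(config: RunConfig, out_dir: str) -> dict[str, Any]:
    """Execute all stages in protocol order and write the output bundle.

    Writes ``qc_report.tsv, ld_pairs.tsv, ld_bins.tsv, thinning.tsv,
    ls_means.tsv, panel_predictions.tsv, model_anova.tsv, phase_bins.tsv,
    ne_trajectory.tsv`` and ``manifest.json`` under ``out_dir``.  Returns
    the in-memory stage results.
    """
    os.makedirs(out_dir, exist_ok=True)
    pops = _load_inputs(config)
    pops = _qc_stage(pops, config, out_dir)
    pair_tables, adj_tables = _ld_stage(pops, config, out_dir)
    fits = _model_stage(pair_tables, adj_tables, config, out_dir)
    phase = _phase_stage(pair_tables, config, out_dir)
    ne = _ne_stage(pops, config, out_dir)
    manifest = {
        "package": "ldscape",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {
            "populations": {k: [v.n_individuals, v.n_markers] for k, v in pops.items()},
            "syntenic_pairs": {k: int(len(v)) for k, v in pair_tables.items()},
            "adjacent_pairs": {k: int(len(v)) for k, v in adj_tables.items()},
            "model_fitted": fits is not None,
            "phase_bins_defined": int(phase["defined"].sum()) if phase is not None else 0,
            "ne_bins_available": int(ne["available"].sum()),
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "populations": pops,
        "pairs": pair_tables,
        "adjacent": adj_tables,
        "fits": fits,
        "phase": phase,
        "ne": ne,
        "manifest": manifest,
    }
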