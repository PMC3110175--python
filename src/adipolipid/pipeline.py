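"""End-to-end pipeline: simulate -> normalize -> diff -> ratios ->
network -> membrane -> report.

The ``replay`` pipeline reproduces the shape of the full twin-cohort
analysis on synthetic data with known ground truth: a discordant/
concordant twin lipidomics cohort, total-phospholipid normalization,
paired differential analysis with Storey q-values, fatty-acid pathway
ratio comparison, a typed mixed-variable dependency network (10 lipid,
31 gene-expression, 10 clinical and 2 pathway-profile variables, the
Table-S4-like shape), and membrane property analysis of two bilayer
mixtures emulating the lean/heavy membrane compositions. All stage
outputs are deterministic TSV/GraphML files; a manifest and a
human-readable report carry the configuration hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .diffstats import differential_analysis, twin_log_ratio
from .fatty_acids import compare_ratios_paired
from .lipids import normalize_total_pl
from .membrane import (analyze_trajectory, compare_systems, design_mixture,
                       write_trajectory)
from .network import (NetworkVariable, build_network, edge_table, hub_report,
                      write_graphml, write_sif)
from .synthetic import (CohortSpec, TrajectorySpec, random_sparse_precision,
                        simulate_cohort, simulate_fatty_acid_profiles,
                        simulate_network_data, simulate_trajectory)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_STAGES"]

log = logging.getLogger("adipolipid")

DEFAULT_STAGES = ("simulate", "normalize", "diff", "ratios", "network",
                  "membrane", "report")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration with per-stage parameters.

    Every random stage derives its seed from ``seed`` deterministically,
    so identical configs produce byte-identical outputs.
    """

    seed: int = 1
    stages: tuple = DEFAULT_STAGES
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    diff: dict = field(default_factory=lambda: {
        "method": "t", "log_transform": True})
    network: dict = field(default_factory=lambda: {
        "q": 3, "n_samplings": 500, "alpha": 0.05, "threshold": 0.55,
        "edge_rule": "rejection-rate"})
    membrane: dict = field(default_factory=lambda: {
        "n_frames": 100, "t_equil": 40.0, "n_blocks": 5,
        "low_bmi": {"pe_fraction": 0.59, "target_apl": 0.600,
                    "target_smol": 0.35},
        "high_bmi": {"pe_fraction": 0.70, "target_apl": 0.595,
                     "target_smol": 0.38}})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        base = cls()
        merged = base.to_dict()
        for key, val in d.items():
            if key not in merged:
                raise ValueError(f"unknown configuration key {key!r}")
            if isinstance(merged[key], dict) and isinstance(val, dict):
                merged[key] = {**merged[key], **val}
            else:
                merged[key] = val
        merged["stages"] = tuple(merged["stages"])
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _write_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
              index_label=index_label, lineterminator="\n")


def _network_variable_meta(diff_result: pd.DataFrame | None,
                           names: list[str],
                           types: list[str]) -> list[NetworkVariable]:
    meta = []
    for nm, ty in zip(names, types):
        reg = "ns"
        if diff_result is not None and nm in diff_result.index:
            row = diff_result.loc[nm]
            if row["significant"]:
                reg = str(row["direction"])
        meta.append(NetworkVariable(name=nm, var_type=ty, regulation=reg))
    return meta


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the enabled stages in dependency order.

    Writes per-stage outputs under ``out_dir`` and returns the manifest
    (also written as ``manifest.json``). A stage failure raises after
    the manifest records the completed stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "config": config.to_dict(), "stages": {}}
    state: dict = {}

    def record(stage: str, files: list[str], t0: float) -> None:
        # timings go to the log only: the manifest stays byte-reproducible
        manifest["stages"][stage] = {"files": files}
        log.info("stage %s done in %.2fs", stage,
                 time.perf_counter() - t0)

    try:
        if "simulate" in config.stages:
            t0 = time.perf_counter()
            spec = CohortSpec(**{"seed": _stage_seed(config.seed, "cohort"),
                                 **config.cohort})
            table, truth = simulate_cohort(spec)
            profiles = simulate_fatty_acid_profiles(
                table.metadata, seed=_stage_seed(config.seed, "fa"))
            aio.write_abundance_table(table, out / "abundance.tsv",
                                      out / "metadata.tsv")
            _write_tsv(truth, out / "truth.tsv", index_label="species")
            _write_tsv(profiles, out / "fa_profiles.tsv",
                       index_label="subject")
            state.update(table=table, truth=truth, profiles=profiles)
            record("simulate", ["abundance.tsv", "metadata.tsv", "truth.tsv",
                                "fa_profiles.tsv"], t0)

        if "normalize" in config.stages:
            t0 = time.perf_counter()
            if "table" not in state:
                state["table"] = aio.read_abundance_table(
                    out / "abundance.tsv", out / "metadata.tsv")
            normalized = normalize_total_pl(state["table"])
            aio.write_abundance_table(normalized, out / "normalized.tsv",
                                      out / "metadata.tsv")
            state["normalized"] = normalized
            record("normalize", ["normalized.tsv"], t0)

        if "diff" in config.stages:
            t0 = time.perf_counter()
            table = state.get("normalized") or state["table"]
            diff = differential_analysis(table, **config.diff)
            _write_tsv(diff, out / "differential.tsv", index_label="species")
            state["diff"] = diff
            record("diff", ["differential.tsv"], t0)

        if "ratios" in config.stages:
            t0 = time.perf_counter()
            ratios = compare_ratios_paired(
                state["profiles"], state["table"].metadata,
                method=config.diff.get("method", "t"))
            _write_tsv(ratios, out / "ratio_differential.tsv",
                       index_label="step")
            state["ratios"] = ratios
            record("ratios", ["ratio_differential.tsv"], t0)

        if "network" in config.stages:
            t0 = time.perf_counter()
            net_seed = _stage_seed(config.seed, "network")
            # Table-S4-like typed variable panel: 10 L + 31 GE + 10
            # clinical + 2 pathway profiles = 53 variables from a sparse
            # Gaussian graphical model with known structure.
            types = (["L"] * 10 + ["GE"] * 31 + ["clinical"] * 10
                     + ["pathway_profile"] * 2)
            names = ([f"lipid_{i + 1}" for i in range(10)]
                     + [f"gene_{i + 1}" for i in range(31)]
                     + [f"clin_{i + 1}" for i in range(10)]
                     + ["pathway_up", "pathway_down"])
            omega = random_sparse_precision(len(names), density=0.08,
                                            seed=net_seed)
            samples, true_edges = simulate_network_data(
                omega, n=200, seed=net_seed + 1, var_names=names)
            meta = _network_variable_meta(state.get("diff"), names, types)
            net = build_network(samples, meta, seed=net_seed + 2,
                                **config.network)
            _write_tsv(edge_table(net), out / "network_edges.tsv")
            _write_tsv(net.nrr, out / "network_nrr.tsv")
            _write_tsv(hub_report(net), out / "network_hubs.tsv")
            write_graphml(net, out / "network.graphml")
            write_sif(net, out / "network.sif")
            with open(out / "network_truth.json", "w") as fh:
                json.dump(sorted(list(e) for e in true_edges), fh, indent=0)
            state["network"] = net
            state["network_truth"] = true_edges
            record("network", ["network_edges.tsv", "network_nrr.tsv",
                               "network_hubs.tsv", "network.graphml",
                               "network.sif", "network_truth.json"], t0)

        if "membrane" in config.stages:
            t0 = time.perf_counter()
            mem = config.membrane
            props, files = [], []
            for label in ("low_bmi", "high_bmi"):
                cfg = mem[label]
                design = design_mixture(
                    [("PE(P-16:0/20:4)", cfg["pe_fraction"]),
                     ("PC(16:1/18:0)", 1.0 - cfg["pe_fraction"])], 128)
                spec = TrajectorySpec(
                    n_lipids=128, n_frames=mem["n_frames"],
                    target_apl=cfg["target_apl"],
                    target_smol_profile=cfg["target_smol"],
                    seed=_stage_seed(config.seed, f"traj-{label}"))
                traj = simulate_trajectory(spec)
                write_trajectory(traj, out / f"trajectory_{label}.txt")
                files.append(f"trajectory_{label}.txt")
                prop = analyze_trajectory(traj, t_equil=mem["t_equil"],
                                          n_blocks=mem["n_blocks"],
                                          label=label)
                prop_design = {"label": label,
                               "pe_per_leaflet": design.per_leaflet_counts[0],
                               "pe_realized": design.realized_fractions[0]}
                props.append((prop, prop_design))
                _write_tsv(prop.smol_profile.set_index("segment"),
                           out / f"smol_profile_{label}.tsv",
                           index_label="segment")
                files.append(f"smol_profile_{label}.tsv")
            comparison = compare_systems([p for p, _ in props])
            design_df = pd.DataFrame([d for _, d in props]).set_index("label") \
                .astype({"pe_per_leaflet": int})
            comparison = comparison.set_index("label").join(design_df)
            _write_tsv(comparison, out / "membrane_summary.tsv",
                       index_label="label")
            files.append("membrane_summary.tsv")
            state["membrane"] = comparison
            record("membrane", files, t0)

        if "report" in config.stages:
            t0 = time.perf_counter()
            report = _render_report(config, state)
            (out / "report.txt").write_text(report)
            record("report", ["report.txt"], t0)
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _render_report(config: PipelineConfig, state: dict) -> str:
    lines = ["adipolipid pipeline report",
             f"config hash: {config.config_hash()}", ""]
    if "table" in state:
        t = state["table"]
        n_disc = (t.metadata["group"] == "discordant").sum() // 2
        lines += [f"cohort: {len(t.species)} species, "
                  f"{len(t.subjects)} subjects, {n_disc} discordant pairs"]
    if "diff" in state:
        d = state["diff"]
        sig = d[d["significant"]]
        lines += ["", f"differential species (q < 0.05): {len(sig)} "
                  f"({(sig['direction'] == 'up').sum()} up, "
                  f"{(sig['direction'] == 'down').sum()} down); "
                  f"marginal (q < 0.1): {int(d['marginal'].sum())}"]
        top = sig.nsmallest(5, "q_value")
        for nm, row in top.iterrows():
            lines.append(f"  {nm}: log2(heavy/lean) = "
                         f"{row['log2_ratio']:+.3f}, q = {row['q_value']:.2e}")
    if "ratios" in state:
        r = state["ratios"]
        hits = r[r["p_value"] < 0.05]
        lines += ["", f"fatty-acid steps at p < 0.05: {len(hits)}"]
        for nm, row in hits.iterrows():
            lines.append(f"  {nm}: ratio heavy/lean log2 = "
                         f"{row['log2_ratio']:+.3f}, p = {row['p_value']:.3g}")
    if "network" in state:
        net = state["network"]
        hubs = hub_report(net)
        lines += ["", f"network: {len(net.nodes)} nodes, "
                  f"{len(net.edges)} edges "
                  f"(rule {net.parameters['edge_rule']}, threshold "
                  f"{net.parameters['threshold']}, q = {net.parameters['q']}, "
                  f"{net.parameters['n_samplings']} samplings)"]
        if "network_truth" in state:
            true_e = state["network_truth"]
            found = net.edge_set()
            tp = len(found & true_e)
            prec = tp / len(found) if found else float("nan")
            rec = tp / len(true_e) if true_e else float("nan")
            lines.append(f"  edge precision {prec:.3f}, recall {rec:.3f} "
                         "against generator truth")
        for _, row in hubs.head(3).iterrows():
            lines.append(f"  hub {row['node']}: degree {row['degree']}")
    if "membrane" in state:
        lines += ["", "membrane systems (ranked by area per lipid):"]
        for label, row in state["membrane"].iterrows():
            lines.append(
                f"  {label}: APL = {row['apl_mean']:.4f} +/- "
                f"{row['apl_sem']:.4f} nm^2, thickness = "
                f"{row['thickness_mean']:.3f} nm, PE "
                f"{int(row['pe_per_leaflet'])}/leaflet "
                f"(realized {100 * row['pe_realized']:.1f} mol%)")
    lines.append("")
    return "\n".join(lines)
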