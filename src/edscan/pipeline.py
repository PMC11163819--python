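"""End-to-end orchestration: simulate → call → dre → network → clinical.

A run is a pure function of (RunConfig, seed): every stage writes
deterministic TSV outputs into the run directory, a manifest records the
config hash and a SHA-256 checksum of every output, and the report stage
summarizes filter attrition, consequence categories, differential counts,
module sizes, hubs and AUCs.  Identical config + seed ⇒ byte-identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, clinical, differential, network as net
from .counts import (SiteCountTable, groups_dict, metadata_frame,
                     read_counts, read_metadata, write_counts, write_metadata)
from .genome import GenomeContext, read_genome, write_genome
from .simulate import SimulationConfig, simulate_all, write_truth

__all__ = ["RunConfig", "run_all", "report", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    ``simulation`` drives the generator; the remaining blocks parameterize
    the caller (thresholds live in :class:`~edscan.calling.CallThresholds`
    defaults), the network step and the ROC options.
    """

    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_depth: int = 10
    min_alt_depth: int = 2
    min_aaf: float = 0.01
    whitelist_rescue: bool = True
    glm_family: str = "binomial"
    alpha: float = 0.05
    powers_max: int = 20
    rsq_cut: float = 0.8
    module_min_size: int = 10
    cut_height: float = 0.9
    edge_threshold: float = 0.4
    n_hubs: int = 10
    roc_ridge: float = 1.0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_df(df: pd.DataFrame, path: Path, cfg_hash: str,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir``; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()

    # --- simulate ---------------------------------------------------------
    try:
        bundle = simulate_all(config.simulation, config.seed)
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc
    write_genome(bundle.genome, out)
    write_counts(bundle.counts, out / "counts.tsv",
                 header_comment=f"config_hash={h}")
    write_metadata(bundle.metadata, out / "metadata.tsv",
                   header_comment=f"config_hash={h}")
    write_truth(bundle.truth, out / "truth.tsv",
                header_comment=f"config_hash={h}")
    _write_df(bundle.expression.rename_axis("gene"), out / "expression.tsv",
              h, index=True)

    # --- call -------------------------------------------------------------
    thresholds = calling.CallThresholds(config.min_depth,
                                        config.min_alt_depth, config.min_aaf)
    try:
        matrix = calling.call_editing(bundle.counts, bundle.genome,
                                      thresholds, config.whitelist_rescue)
    except Exception as exc:
        raise StageError(f"call: {exc}") from exc
    _write_df(matrix.events.reset_index(), out / "events.tsv", h)
    _write_df(matrix.levels.rename_axis("event_id"), out / "matrix.tsv", h,
              index=True)
    _write_df(matrix.filter_log, out / "filter_log.tsv", h)

    # --- differential -----------------------------------------------------
    groups = groups_dict(bundle.metadata)
    try:
        dre = differential.dre_test(matrix, bundle.counts, groups,
                                    family=config.glm_family,
                                    min_depth=config.min_depth,
                                    alpha=config.alpha)
    except Exception as exc:
        raise StageError(f"dre: {exc}") from exc
    _write_df(dre.reset_index(), out / "dre.tsv", h)

    # --- network (on differential events) ---------------------------------
    sig = dre[dre["significant"].fillna(False)]
    sub = matrix.levels.loc[sig.index]
    hubs = pd.DataFrame(columns=["event_id", "degree", "module"])
    module_trait = pd.DataFrame(columns=["module", "trait", "R", "p", "n"])
    power_table = pd.DataFrame()
    modules_df = pd.DataFrame(columns=["event_id", "module"])
    eigen_df = pd.DataFrame()
    edges = pd.DataFrame(columns=["node1", "node2", "weight"])
    traits = metadata_frame(bundle.metadata).loc[list(matrix.levels.columns)]
    try:
        if len(sub) >= 20 and sub.shape[1] >= 8:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta, power_table = net.pick_soft_threshold(
                    sub, powers=range(1, config.powers_max + 1),
                    rsq_cut=config.rsq_cut)
                network = net.build_network(sub, beta)
                net.detect_modules(network, min_size=config.module_min_size,
                                   cut_height=config.cut_height)
                modules_df = pd.DataFrame(
                    sorted(network.modules.items()),
                    columns=["event_id", "module"])
                eig = net.compute_eigengenes(network, sub)
                if eig:
                    eigen_df = pd.DataFrame(
                        eig, index=list(sub.columns)).rename_axis("sample")
                    module_trait = net.module_trait_correlation(eig, traits)
                    key = net.key_module(module_trait)
                    hubs = net.hub_events(network, key, n=config.n_hubs,
                                          edge_threshold=config.edge_threshold,
                                          dre=dre)
                    edges = net.edge_list(network, key,
                                          config.edge_threshold)
    except Exception as exc:
        raise StageError(f"network: {exc}") from exc
    _write_df(power_table, out / "power_table.tsv", h)
    _write_df(modules_df, out / "modules.tsv", h)
    _write_df(eigen_df, out / "eigengenes.tsv", h, index=not eigen_df.empty)
    _write_df(module_trait, out / "module_trait.tsv", h)
    _write_df(hubs, out / "hubs.tsv", h)
    _write_df(edges, out / "edges.tsv", h)

    # --- clinical ---------------------------------------------------------
    try:
        corr = pd.DataFrame(
            columns=["event_id", "feature", "r", "p", "n", "testable"])
        auc_rows = []
        labels = traits["group"]
        if len(hubs):
            corr = clinical.hub_clinical_correlation(
                matrix.levels, list(hubs["event_id"]), traits)
            for eid in hubs["event_id"]:
                lev = matrix.levels.loc[eid]
                try:
                    roc = clinical.roc_single(lev.to_numpy(),
                                              labels.loc[lev.index],
                                              marker=eid)
                    auc_rows.append({"marker": eid,
                                     "auc": round(roc.auc, 6),
                                     "combined": False})
                except ValueError:
                    continue
            if len(hubs) >= 2:
                top = list(hubs["event_id"][: min(5, len(hubs))])
                roc = clinical.roc_combined(
                    matrix.levels.loc[top].T, labels,
                    ridge=config.roc_ridge)
                auc_rows.append({"marker": "+".join(top),
                                 "auc": round(roc.auc, 6), "combined": True})
        auc_df = pd.DataFrame(auc_rows, columns=["marker", "auc", "combined"])
    except Exception as exc:
        raise StageError(f"clinical: {exc}") from exc
    _write_df(corr, out / "correlations.tsv", h)
    _write_df(auc_df, out / "auc.tsv", h)

    # --- manifest ---------------------------------------------------------
    outputs = sorted(p.name for p in out.iterdir()
                     if p.is_file() and p.name not in ("manifest.json",
                                                       "report.json"))
    manifest = {
        "config_hash": h,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "outputs": {name: _checksum(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    report(out)
    return out


def report(run_dir: str | Path) -> dict:
    """Summaries of a completed (or partially completed) run; idempotent."""
    out = Path(run_dir)
    events_path = out / "events.tsv"
    if not events_path.exists():
        raise StageError(f"report: no call outputs under {out}")
    events = pd.read_csv(events_path, sep="\t", comment="#")
    flog = pd.read_csv(out / "filter_log.tsv", sep="\t", comment="#")
    summary: dict = {}
    if len(events):
        cons = events["consequence"].value_counts(normalize=True)
        summary["consequence_proportions"] = {
            k: round(float(v), 4) for k, v in cons.items()}
    else:
        summary["consequence_proportions"] = {}
    attrition = flog[flog["stage"] != "retained"]["reason"].value_counts()
    summary["filter_attrition"] = {k: int(v) for k, v in attrition.items()}
    summary["n_candidates"] = int(len(flog))
    summary["n_retained"] = int((flog["stage"] == "retained").sum())
    dre_path = out / "dre.tsv"
    if dre_path.exists():
        dre = pd.read_csv(dre_path, sep="\t", comment="#")
        summary["n_differential"] = int(
            (dre["p_glm"] < 0.05).fillna(False).sum())
        summary["n_untestable"] = int((~dre["testable"]).sum())
    modules_path = out / "modules.tsv"
    if modules_path.exists():
        mods = pd.read_csv(modules_path, sep="\t", comment="#")
        if len(mods):
            summary["module_sizes"] = {
                k: int(v) for k, v in
                mods["module"].value_counts().items()}
    hubs_path = out / "hubs.tsv"
    if hubs_path.exists():
        hubs = pd.read_csv(hubs_path, sep="\t", comment="#")
        summary["hubs"] = hubs.to_dict("records")
    auc_path = out / "auc.tsv"
    if auc_path.exists():
        auc = pd.read_csv(auc_path, sep="\t", comment="#")
        summary["auc"] = auc.to_dict("records")
    (out / "report.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
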