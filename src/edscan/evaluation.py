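"""Benchmarks against planted truth: caller metrics and replicated studies.

These helpers join caller/pipeline outputs back to the generator's truth
table by site key and summarize performance — precision/recall of editing
site detection, SNP removal, filter-reason agreement with the planted decoy
class, differential-test calibration and power, module/hub recovery, and
clinical-association replication over seeds.  They are used by the test
suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import EditingMatrix, call_editing
from .counts import groups_dict, metadata_frame
from .differential import binomial_lrt
from .simulate import (SimulationConfig, TruthTable, plant_truth,
                       simulate_clinical, simulate_counts, simulate_dre_counts,
                       simulate_genome)

# decoy class -> the cascade rule expected to fire first
EXPECTED_REASON = {
    "homopolymer": "homopolymer",
    "simple_repeat": "simple_repeat",
    "mito": "mitochondria",
    "junction": "splice_junction",
    "read_end": "read_end",
    "near_indel": "near_indel",
    "blacklist": "snp_blacklist",
}


@dataclass
class CallerMetrics:
    precision: float
    recall: float
    snp_removal: float
    decoy_reason_match: float
    n_called: int
    n_target: int
    n_snps: int
    n_decoys: int


def caller_metrics(truth: TruthTable, matrix: EditingMatrix) -> CallerMetrics:
    """Precision/recall vs clean planted edits, SNP removal, reason match.

    The caller's target set is the planted editing sites in clean context;
    context decoys are counted separately through their filter-log reasons.
    """
    t = truth.table
    clean = {(r.contig, int(r.pos)) for r in
             t[(t.kind == "edit") & (t.decoy_class == "")].itertuples()}
    snps = {(r.contig, int(r.pos)) for r in
            t[t.kind.isin(["het_snp", "hom_snp"])].itertuples()}
    called = {(r.contig, int(r.pos)) for r in matrix.events.itertuples()}
    tp = len(called & clean)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(clean) if clean else float("nan")
    snp_removal = (1.0 - len(called & snps) / len(snps)) if snps \
        else float("nan")

    # first firing reason for the planted alt allele of each decoy
    log = matrix.filter_log
    decoys = t[t.decoy_class != ""]
    matches, n_decoys = 0, 0
    for r in decoys.itertuples():
        sub = log[(log["contig"] == r.contig) & (log["pos"] == r.pos)
                  & (log["ref"] == r.ref) & (log["alt"] == r.alt)]
        if sub.empty:           # not even a candidate: never called
            continue
        n_decoys += 1
        if (sub["reason"] == EXPECTED_REASON[r.decoy_class]).all():
            matches += 1
    return CallerMetrics(
        precision=precision, recall=recall, snp_removal=snp_removal,
        decoy_reason_match=(matches / n_decoys) if n_decoys else float("nan"),
        n_called=len(called), n_target=len(clean), n_snps=len(snps),
        n_decoys=n_decoys)


def lrt_rejection_rate(n_events: int, n_case: int, n_control: int,
                       delta: float, seed: int,
                       depth_mean: float = 50.0,
                       alpha: float = 0.05) -> float:
    """Fraction of simulated events rejected at ``alpha`` (power; type-I
    error when delta = 0)."""
    e, u, g = simulate_dre_counts(n_events, n_case, n_control, delta,
                                  depth_mean=depth_mean, seed=seed)
    ca = g == 1
    hits = 0
    for i in range(n_events):
        _stat, p = binomial_lrt(float(e[i, ca].sum()), float(u[i, ca].sum()),
                                float(e[i, ~ca].sum()),
                                float(u[i, ~ca].sum()))
        hits += p < alpha
    return hits / n_events


@dataclass
class NetworkRecovery:
    block_coverage: float        # planted hubs inside the key module
    rand_index: float
    hub_top_recovery: int        # planted hubs among the top-10 by degree
    key_module_group_r: float
    n_module: int


def network_recovery(config: SimulationConfig, seed: int,
                     edge_threshold: float = 0.4,
                     min_size: int = 10) -> NetworkRecovery:
    """Run simulate → call → dre → network and score hub-block recovery."""
    import warnings

    from sklearn.metrics import rand_score

    from . import network as net
    from .differential import dre_test
    from .simulate import simulate_all

    bundle = simulate_all(config, seed)
    matrix = call_editing(bundle.counts, bundle.genome)
    dre = dre_test(matrix, bundle.counts, groups_dict(bundle.metadata))
    t = bundle.truth.table
    hub_keys = {(r.contig, int(r.pos)) for r in t[t.is_hub].itertuples()}
    is_hub = {eid: (r.contig, int(r.pos)) in hub_keys
              for eid, r in matrix.events.iterrows()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta, _table = net.pick_soft_threshold(matrix.levels)
        network = net.build_network(matrix.levels, beta)
        modules = net.detect_modules(network, min_size=min_size)
        eig = net.compute_eigengenes(network, matrix.levels)
        traits = metadata_frame(bundle.metadata).loc[
            list(matrix.levels.columns)]
        mt = net.module_trait_correlation(eig, traits)
        key = net.key_module(mt)
        hubs = net.hub_events(network, key, n=10,
                              edge_threshold=edge_threshold, dre=dre)
    members = network.module_members(key)
    covered = sum(1 for n_ in members if is_hub[n_])
    truth_lab = [1 if is_hub[n_] else 0 for n_ in network.nodes]
    pred_lab = [1 if modules[n_] == key else 0 for n_ in network.nodes]
    key_r = float(mt[(mt.module == key) & (mt.trait == "group")]["R"].iloc[0])
    return NetworkRecovery(
        block_coverage=covered / max(sum(truth_lab), 1),
        rand_index=float(rand_score(truth_lab, pred_lab)),
        hub_top_recovery=int(sum(is_hub[e] for e in hubs["event_id"])),
        key_module_group_r=key_r,
        n_module=len(members))


@dataclass
class ClinicalReplication:
    sig_positive_fraction: float     # hub-LH pairs significant & positive
    n_pairs: int


def clinical_replication(config: SimulationConfig, n_seeds: int,
                         seed_offset: int = 0,
                         feature: str = "LH") -> ClinicalReplication:
    """Replicated hub-hormone association over independent cohort draws.

    The genome is simulated once; truth, counts and clinical covariates are
    re-drawn per seed.  Returns the fraction of (seed, hub) pairs whose
    editing-level/hormone Pearson correlation is positive with p < 0.05.
    """
    from .clinical import pearson_assoc

    genome = simulate_genome(config, 9_999_001)
    sig, total = 0, 0
    for s in range(n_seeds):
        ss = np.random.SeedSequence(seed_offset + s)
        r1, r2, r3 = [np.random.default_rng(x) for x in ss.spawn(3)]
        truth = plant_truth(genome, config, r1)
        counts = simulate_counts(truth, genome, config, r2)
        meta = simulate_clinical(truth, config, r3)
        matrix = call_editing(counts, genome)
        val = {m.sample_id: m.hormones[feature] for m in meta}
        y = np.array([val[x] for x in matrix.levels.columns])
        hub_keys = {(r.contig, int(r.pos)) for r in
                    truth.table[truth.table.is_hub].itertuples()}
        for eid, r in matrix.events.iterrows():
            if (r.contig, int(r.pos)) not in hub_keys:
                continue
            res = pearson_assoc(matrix.levels.loc[eid].to_numpy(), y)
            if not res.testable:
                continue
            total += 1
            if res.p < 0.05 and res.r > 0:
                sig += 1
    return ClinicalReplication(sig_positive_fraction=sig / total,
                               n_pairs=total)


def clinical_false_positive_rate(config: SimulationConfig, n_seeds: int,
                                 seed_offset: int = 0,
                                 feature: str = "LH") -> ClinicalReplication:
    """Same replication but counting any p < 0.05 (two-sided FP rate).

    Use with a hormone model whose factor and group coefficients are zero.
    """
    from .clinical import pearson_assoc

    genome = simulate_genome(config, 9_999_001)
    fp, total = 0, 0
    for s in range(n_seeds):
        ss = np.random.SeedSequence(seed_offset + s)
        r1, r2, r3 = [np.random.default_rng(x) for x in ss.spawn(3)]
        truth = plant_truth(genome, config, r1)
        counts = simulate_counts(truth, genome, config, r2)
        meta = simulate_clinical(truth, config, r3)
        matrix = call_editing(counts, genome)
        val = {m.sample_id: m.hormones[feature] for m in meta}
        y = np.array([val[x] for x in matrix.levels.columns])
        hub_keys = {(r.contig, int(r.pos)) for r in
                    truth.table[truth.table.is_hub].itertuples()}
        for eid, r in matrix.events.iterrows():
            if (r.contig, int(r.pos)) not in hub_keys:
                continue
            res = pearson_assoc(matrix.levels.loc[eid].to_numpy(), y)
            if not res.testable:
                continue
            total += 1
            if res.p < 0.05:
                fp += 1
    return ClinicalReplication(sig_positive_fraction=fp / total,
                               n_pairs=total)
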