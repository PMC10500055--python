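"""Orchestration: configuration-driven end-to-end analysis runs.

A run is described by one mapping (YAML/JSON file or dict):

.. code-block:: yaml

    seed: 1
    alpha: 0.05
    simulation:              # either a simulation block ...
      strains:
        BIR: {p_mate: 0.75, mu: 30, k: 5, s_f: 0.6, infected: false}
        STU: {p_mate: 0.75, mu: 30, k: 5, s_f: 0.6, infected: true}
      directions: [[BIR, STU], [STU, BIR]]
      n_rep: 40
      ci_penetrance: 0.525
    # input: crosses.tsv     # ... or a cross-record table
    # infected_strains: [STU]  # infection metadata for file input
    run_tests: true
    bsc_threshold: 0.8
    barcode_thresholds: [0.02, 0.022]
    # alignment: barcodes.fasta   # optional barcode section
    # distances: {"BIR|STU": 0.028, "CAN|STU": 0.072}

Outputs are deterministic given config + seed: a Table-3-style ladder
report (TSV), a structured JSON report, and a run manifest capturing
config hash, seed and package versions. Every decision taken (test
selected per barrier, barriers skipped, backcross averaging) is logged
into the JSON report.
"""

from __future__ import annotations

import hashlib
import json
import math
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

import crossri
from crossri.crossdata import CrossSet, cross_label, read_cross_table, \
    write_cross_table
from crossri.distances import (DistanceMatrix, bsc_partition,
                               compare_delimitations, distance_matrix,
                               read_alignment, threshold_delimit)
from crossri.ri import (BarrierLadder, LadderConfig, available_directions,
                        build_barrier_ladder, ladders_to_table)
from crossri.simulate import SimulationConfig, simulate_cross_series


class ConfigError(ValueError):
    """Inconsistent run configuration, raised before any computation."""


def load_config(source) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    text = Path(source).read_text()
    return yaml.safe_load(text)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _validate(config: dict) -> None:
    if ("simulation" in config) == ("input" in config):
        raise ConfigError(
            "config needs exactly one of 'simulation' or 'input'")
    if config.get("ci_variant") in ("with_CI", "without_CI"):
        has_infection = ("simulation" in config
                         or config.get("infected_strains"))
        if not has_infection:
            raise ConfigError(
                "CI variant requested but no infection metadata "
                "(simulation block or infected_strains)")
    for t in config.get("barcode_thresholds", []):
        if not 0 < t < 1:
            raise ConfigError(f"barcode threshold out of (0,1): {t}")


def run_full_analysis(config_source, out_dir, seed: int | None = None
                      ) -> dict:
    """Run the complete pipeline and write report files.

    Returns the structured report (also written as ``report.json``).
    """
    config = load_config(config_source)
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    alpha = float(config.get("alpha", 0.05))
    log: list[str] = []

    # 1. obtain cross records
    sim_cfg = None
    if "simulation" in config:
        sim_cfg = _simulation_config(config["simulation"], seed)
        cs = simulate_cross_series(sim_cfg, seed=seed)
        write_cross_table(cs, out / "crosses.tsv")
        log.append(f"simulated {len(cs)} replicate crosses (seed {seed})")
        infected = {s for s, sp in sim_cfg.strains.items() if sp.infected}
    else:
        cs = read_cross_table(config["input"],
                              strict=bool(config.get("strict", True)))
        infected = set(config.get("infected_strains", []))
        log.append(f"read {len(cs)} replicate crosses from {config['input']}")

    # 2. barrier ladders per direction (both CI variants where CI applies)
    directions = [tuple(d) for d in config.get("directions", [])] \
        or available_directions(cs)
    ladders: list[BarrierLadder] = []
    for direction in directions:
        f, m = direction
        ci_here = m in infected and f not in infected
        variants = (("without_CI", "with_CI") if ci_here
                    else ("not_applicable",))
        for variant in variants:
            lcfg = LadderConfig(ci_variant=variant,
                                run_tests=bool(config.get("run_tests", False)),
                                alpha=alpha, test_seed=seed)
            ladder = build_barrier_ladder(cs, direction, lcfg)
            ladders.append(ladder)
            if ladder.skipped:
                log.append(
                    f"{cross_label(f, m)} [{variant}]: skipped "
                    f"{[b.value for b in ladder.skipped]}")
            for e in ladder.estimates:
                if e.test_name:
                    log.append(f"{cross_label(f, m)} {e.barrier.value}: "
                               f"{e.test_name}, p={e.p_value:.4g}")
                if e.components:
                    log.append(
                        f"{cross_label(f, m)} {e.barrier.value}: averaged "
                        f"over {len(e.components)} backcross female strains")

    table = ladders_to_table(ladders)
    table.to_csv(out / "ladders.tsv", sep="\t")

    # 3. pairwise total isolation (max of the two directions per pair)
    isolation = {}
    for lad in ladders:
        variant_ok = lad.ci_variant in ("with_CI", "not_applicable")
        if variant_ok and not math.isnan(lad.T):
            isolation[lad.direction] = lad.T

    # 4. optional barcode section
    barcode_report = _barcode_section(config, isolation, out, log)

    report = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "versions": {"crossri": crossri.__version__,
                     "numpy": np.__version__},
        "directions": [cross_label(*d) for d in directions],
        "ladders": [_ladder_json(l) for l in ladders],
        "pairwise_total_isolation": {
            cross_label(*d): t for d, t in sorted(isolation.items())},
        "barcode": barcode_report,
        "log": log,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                default=_jsonable))
    (out / "manifest.json").write_text(json.dumps({
        "seed": seed, "config_hash": report["config_hash"],
        "versions": report["versions"],
        "outputs": sorted(p.name for p in out.iterdir())}, indent=2))
    return report


def _simulation_config(block: Mapping, seed: int) -> SimulationConfig:
    data = dict(block)
    data.setdefault("seed", seed)
    try:
        return SimulationConfig.from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation block: {exc}") from exc


def _barcode_section(config, isolation, out: Path, log) -> dict | None:
    dm = None
    if "alignment" in config:
        aln = read_alignment(config["alignment"])
        if "clades" in config:
            aln.clade_of = dict(config["clades"])
        dm = distance_matrix(aln, policy=config.get("deletion_policy",
                                                    "pairwise"))
        dm.write_phylip(out / "distances.phy")
        dm.write_tsv(out / "distances.tsv")
        log.append(f"distance matrix over {len(dm.taxa)} taxa")
    elif "distances" in config:
        pairs = {tuple(k.split("|")): float(v)
                 for k, v in config["distances"].items()}
        taxa = sorted({t for p in pairs for t in p})
        d = np.zeros((len(taxa), len(taxa)))
        for (a, b), v in pairs.items():
            i, j = taxa.index(a), taxa.index(b)
            d[i, j] = d[j, i] = v
        dm = DistanceMatrix(taxa=taxa, d=d)
    if dm is None:
        return None

    bsc_threshold = float(config.get("bsc_threshold", 0.8))
    strain_iso = {}
    for (f, m), t in isolation.items():
        strain_iso[(f, m)] = t
    strains_in_dm = [t for t in dm.taxa]
    bsc = bsc_partition(strains_in_dm, strain_iso, threshold=bsc_threshold)
    section = {"bsc_threshold": bsc_threshold, "bsc_partition": bsc,
               "thresholds": {}}
    for thr in config.get("barcode_thresholds", [0.02, 0.022]):
        clusters = threshold_delimit(dm, thr)
        rep = compare_delimitations(clusters, bsc)
        section["thresholds"][str(thr)] = {
            "clusters": clusters,
            "n_clusters": len(set(clusters.values())),
            "conflicts": rep.conflicts,
            "rand_index": rep.rand_index,
        }
        log.append(f"barcode threshold {thr}: "
                   f"{len(set(clusters.values()))} clusters, "
                   f"{len(rep.conflicts)} conflict pair(s) with BSC")
    return section


def _ladder_json(ladder: BarrierLadder) -> dict:
    return {
        "direction": cross_label(*ladder.direction),
        "ci_variant": ladder.ci_variant,
        "ecological": ladder.ecological,
        "barriers": [
            {"barrier": e.barrier.value, "metric": e.metric,
             "H": e.H, "C": e.C, "RI": e.RI,
             "n_H": e.n_H, "n_C": e.n_C,
             "significant": e.significant, "p_value": e.p_value,
             "test": e.test_name}
            for e in ladder.estimates],
        "AC": ladder.AC,
        "total_isolation": ladder.T,
        "skipped": [b.value for b in ladder.skipped],
    }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
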