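"""Config-driven orchestration of the full analysis battery.

A run config (YAML or dict) names a dataset — an EIGENSTRAT prefix or the
built-in synthetic fixture — and an ordered list of analyses among
``kin``, ``fstats``, ``het``, ``fst``, ``qpadm``, ``qpwave``,
``modelsearch``, ``ycall`` and ``freqml``.  The kinship screen always runs
before population statistics so that related-individual exclusions propagate
into the population groupings, matching the practice of building an
"unrelated" analysis set first.  Each stage appends TSV tables to the output
directory and a machine-readable ``results.json`` collects everything; a
failed stage aborts its dependents but earlier outputs are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import admix, biomarkers, fstats, kinship, yhaplo
from .dataset import (Dataset, assign_blocks, compute_pop_counts,
                      filter_individuals, read_eigenstrat)
from .simulate import peqiin_fixture

logger = logging.getLogger(__name__)

KNOWN_ANALYSES = {"kin", "fstats", "het", "fst", "qpadm", "qpwave",
                  "modelsearch", "ycall", "freqml"}


@dataclasses.dataclass
class RunConfig:
    dataset: dict[str, Any]
    analyses: list[dict[str, Any]]
    seed: int = 1
    output_dir: str = "levantadmix_out"
    min_snps: int = 5000
    block_size_morgans: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for a in self.analyses:
            kind = a.get("type")
            if kind not in KNOWN_ANALYSES:
                raise ValueError(f"unknown analysis type {kind!r}")


def _load_dataset(cfg: RunConfig) -> tuple[Dataset, dict]:
    ds_cfg = cfg.dataset
    if "prefix" in ds_cfg:
        p = ds_cfg["prefix"]
        return read_eigenstrat(p + ".geno", p + ".snp", p + ".ind"), {}
    if ds_cfg.get("fixture") == "peqiin":
        return peqiin_fixture(seed=int(ds_cfg.get("seed", cfg.seed)),
                              n_snps=int(ds_cfg.get("n_snps", 100_000)))
    raise ValueError("dataset must give an EIGENSTRAT 'prefix' or "
                     "fixture: peqiin")


def _check_pops(analysis: dict, pops: set[str]) -> None:
    referenced: list[str] = []
    for key in ("pops", "target", "sources", "right", "left",
                "candidate_pool", "core_sources", "augmenting_outgroups"):
        v = analysis.get(key)
        if v is None:
            continue
        stack = [v]
        while stack:
            item = stack.pop()
            if isinstance(item, str):
                referenced.append(item)
            else:
                stack.extend(item)
    unknown = [p for p in referenced if p not in pops]
    if unknown:
        raise ValueError(f"analysis {analysis.get('type')}: unknown "
                         f"populations {unknown}")


def _res_row(r: fstats.FStatResult) -> dict:
    return {"statistic": r.statistic, "pops": list(r.pops),
            "estimate": r.estimate, "se": r.se, "z": r.z,
            "n_snps": r.n_snps_used, "n_blocks": r.n_blocks}


def run(config: RunConfig | dict | str) -> dict:
    """Execute the configured battery; returns the results bundle."""
    if isinstance(config, str):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(**config)
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    logger.info("run: seed=%d", config.seed)

    dataset, truth = _load_dataset(config)
    dataset = filter_individuals(dataset, config.min_snps)
    results: dict[str, Any] = {"seed": config.seed}
    if truth:
        results["fixture_truth"] = truth

    # validate all referenced populations before any execution
    pops_avail = set(dataset.individuals["group"].astype(str))
    for analysis in config.analyses:
        if analysis.get("type") in {"kin", "ycall", "freqml"}:
            continue
        _check_pops(analysis, pops_avail)

    # kinship screen first: exclusions feed the groupings downstream
    # The PMR baseline (cohort median) is only meaningful within a
    # homogeneous group, so the screen runs separately per population.
    excluded: list[str] = []
    for analysis in config.analyses:
        if analysis.get("type") != "kin":
            continue
        partition = assign_blocks(dataset.snps, config.block_size_morgans)
        min_overlap = int(analysis.get("min_overlap", 5000))
        groups = analysis.get("pops") or sorted(
            dataset.individuals["group"].astype(str).unique())
        all_calls, n_pairs = [], 0
        for group in groups:
            mask = (dataset.individuals["group"].astype(str) == group).to_numpy()
            if mask.sum() < 3:   # need >= 3 pairs for median normalization
                logger.info("kin: skipping group %s (<3 individuals)", group)
                continue
            sub = dataset.take_individuals(mask)
            pairs = kinship.pmr_matrix(sub, partition, min_overlap)
            n_pairs += len(pairs)
            cov = dict(zip(sub.individuals["individual_id"],
                           sub.n_snps_covered()))
            try:
                calls, dropped = kinship.classify_relatives(pairs, cov)
            except ValueError as exc:
                logger.info("kin: skipping group %s (%s)", group, exc)
                continue
            all_calls += calls
            excluded += dropped
        pd.DataFrame([dataclasses.asdict(c) for c in all_calls]).to_csv(
            out_dir / "kin_pairs.tsv", sep="\t", index=False)
        (out_dir / "kin_exclusions.tsv").write_text(
            "\n".join(excluded) + ("\n" if excluded else ""))
        results["kin"] = {
            "n_pairs": n_pairs,
            "related": [dataclasses.asdict(c) for c in all_calls
                        if c.relationship != "unrelated"],
            "excluded": excluded,
        }
    if excluded:
        keep = ~dataset.individuals["individual_id"].isin(excluded).to_numpy()
        dataset = dataset.take_individuals(keep)
        logger.info("run: excluded %d related individuals", len(excluded))

    partition = assign_blocks(dataset.snps, config.block_size_morgans)
    counts = compute_pop_counts(dataset)
    fstat_rows: list[dict] = []

    for analysis in config.analyses:
        kind = analysis["type"]
        try:
            if kind == "kin":
                continue
            elif kind == "fstats":
                for quad in analysis.get("f4", []):
                    fstat_rows.append(_res_row(
                        fstats.f4_stat(counts, tuple(quad), partition,
                                       analysis.get("allsnps", True))))
                for trip in analysis.get("f3", []):
                    fstat_rows.append(_res_row(
                        fstats.f3_stat(counts, *trip, partition)))
            elif kind == "het":
                for pop in analysis["pops"]:
                    fstat_rows.append(_res_row(
                        fstats.conditional_heterozygosity(counts, pop,
                                                          partition)))
            elif kind == "fst":
                for a, b in analysis["pops"]:
                    fstat_rows.append(_res_row(
                        fstats.hudson_fst(counts, a, b, partition)))
            elif kind == "qpadm":
                model = admix.qpadm(counts, analysis["target"],
                                    analysis["sources"], analysis["right"],
                                    partition, analysis.get("allsnps", True))
                results.setdefault("qpadm", []).append({
                    "target": model.target, "sources": list(model.sources),
                    "right": list(model.right),
                    "weights": model.weights.tolist(),
                    "ses": model.ses.tolist(), "p": model.p,
                    "feasible": model.feasible, "plausible": model.plausible})
            elif kind == "qpwave":
                n, ranks, saturated = admix.qpwave_min_streams(
                    counts, analysis["left"], analysis["right"], partition,
                    analysis.get("allsnps", True))
                results.setdefault("qpwave", []).append({
                    "left": list(analysis["left"]),
                    "right": list(analysis["right"]),
                    "min_streams": n, "saturated": saturated,
                    "ranks": [dataclasses.asdict(r) for r in ranks]})
            elif kind == "modelsearch":
                ledger = admix.model_search(
                    counts, analysis["target"], analysis["candidate_pool"],
                    analysis.get("core_sources", analysis["candidate_pool"]),
                    analysis["right"],
                    analysis.get("augmenting_outgroups", []), partition,
                    analysis.get("allsnps", True))
                pd.DataFrame([{
                    "stage": r.stage, "sources": "+".join(r.sources),
                    "right": "+".join(r.right), "p": r.p,
                    "weights": ",".join(f"{w:.4f}" for w in r.weights),
                    "ses": ",".join(f"{s:.4f}" for s in r.ses),
                    "plausible": r.plausible} for r in ledger.rows]
                ).to_csv(out_dir / "modelsearch.tsv", sep="\t", index=False)
                results["modelsearch"] = {
                    "final_survivors": ["+".join(s)
                                        for s in ledger.final_survivors],
                    "n_models_tested": len(ledger.rows)}
            elif kind == "ycall":
                tree = yhaplo.load_haplotree(analysis["tree"])
                rows = []
                for sample, path in analysis["samples"].items():
                    calls = yhaplo.read_calls(path)
                    res = yhaplo.call_y_haplogroup(calls, tree)
                    rows.append({"sample": sample, **dataclasses.asdict(res)})
                pd.DataFrame(rows).to_csv(out_dir / "ycalls.tsv", sep="\t",
                                          index=False)
                results["ycall"] = rows
            elif kind == "freqml":
                table = biomarkers.population_frequency_table(
                    biomarkers.read_counts_table(analysis["counts"]),
                    analysis.get("epsilon", 0.001))
                table.to_csv(out_dir / "allele_frequencies.tsv", sep="\t",
                             index=False)
                results["freqml"] = table.to_dict(orient="records")
        except Exception:
            logger.exception("run: stage %s failed; aborting dependents", kind)
            results.setdefault("failed_stages", []).append(kind)
            break

    if fstat_rows:
        pd.DataFrame(fstat_rows).to_csv(out_dir / "fstats.tsv", sep="\t",
                                        index=False)
        results["fstats"] = fstat_rows

    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=_json_default)
    return results


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
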