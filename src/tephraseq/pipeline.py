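"""End-to-end orchestration: simulate (or load) -> decontaminate -> community
statistics -> differential abundance, with a machine-readable run manifest.

One global seed derives per-stage seeds by fixed offsets so a single integer
reproduces a full run; every randomized stage consumes only its own seed.
Reruns with the same config byte-reproduce all TSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import community_stats as cs
from . import decontamination as dc
from . import differential_abundance as da
from . import synthetic_community as sc
from . import tables_io as tio

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (kept < 2**31 after adding a small user seed)
STAGE_OFFSETS = {
    "simulate": 101,
    "rarefy": 202,
    "nmds": 303,
    "permanova": 404,
    "envfit": 505,
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Inputs and knobs of one pipeline run."""

    out_dir: Path
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    simulation: sc.SimulationConfig | None = None
    # ... or load from files
    table_path: Path | None = None
    metadata_path: Path | None = None
    taxonomy_path: Path | None = None
    blocklist: tuple[str, ...] = sc.DEFAULT_BLOCKLIST
    groups: Mapping[str, list[str]] | None = None
    prevalence_threshold: float = 0.5
    rarefy_depth: int | None = None  # None = minimum column sum
    n_permutations: int = 999
    da_groups: tuple[str, str] = ("drill_core", "borehole_fluid")

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + STAGE_OFFSETS[stage]) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _test_result_dict(r: cs.TestResult) -> dict:
    d = {k: v for k, v in dataclasses.asdict(r).items() if k != "payload"}
    d.update(r.payload)
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in fixed order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}
    t_all = time.time()

    def stage_entry(name: str, **info) -> None:
        manifest["stages"][name] = info
        logger.info("stage=%s %s", name, json.dumps(info, default=str, sort_keys=True))

    try:
        # ---- input ------------------------------------------------------
        t0 = time.time()
        if config.simulate:
            sim_cfg = config.simulation or sc.SimulationConfig()
            sim_cfg = dataclasses.replace(sim_cfg, seed=config.stage_seed("simulate"))
            dataset, truth = sc.simulate_dataset(sim_cfg)
            tio.write_feature_table(dataset.table, out / "table.tsv")
            tio.write_metadata(dataset.metadata, out / "metadata.tsv")
            tio.write_taxonomy(dataset.taxonomy, out / "taxonomy.tsv")
            pd.DataFrame(
                {"feature_id": list(truth.origins),
                 "origin": list(truth.origins.values())}
            ).to_csv(out / "truth.tsv", sep="\t", index=False, lineterminator="\n")
            _write_json(
                {"contamination_fraction": truth.contamination_fraction,
                 "library_sizes": truth.library_sizes},
                out / "simulation_manifest.json",
            )
        else:
            for p, what in ((config.table_path, "table"),
                            (config.metadata_path, "metadata")):
                if p is None or not Path(p).exists():
                    raise ConfigError(f"missing {what} file: {p}")
            table = tio.read_feature_table(config.table_path)
            metadata = tio.read_metadata(config.metadata_path)
            taxonomy = (
                tio.read_taxonomy(config.taxonomy_path)
                if config.taxonomy_path and Path(config.taxonomy_path).exists()
                else {}
            )
            dataset = tio.harmonize(table, metadata, taxonomy)
            truth = None
        stage_entry(
            "input", elapsed_s=round(time.time() - t0, 3),
            n_features=dataset.table.shape[0], n_samples=dataset.table.shape[1],
            seed=config.stage_seed("simulate") if config.simulate else None,
        )

        # ---- decontamination --------------------------------------------
        t0 = time.time()
        calls, patterns = dc.run_cascade(
            dataset, blocklist_genera=config.blocklist, groups=config.groups,
            threshold=config.prevalence_threshold,
        )
        cleaned, report = dc.apply_calls(dataset, calls)
        calls_df = pd.DataFrame(
            [{"feature_id": c.feature_id, "stage": c.stage, "verdict": c.verdict,
              "rule": c.rule,
              "evidence": c.evidence if c.p_value is None else f"p={c.p_value:.6g}"}
             for c in calls]
        )
        calls_df.to_csv(out / "calls.tsv", sep="\t", index=False, lineterminator="\n")
        census = dc.venn_census(patterns)
        pd.DataFrame({"region": list(census), "n_features": list(census.values())}).to_csv(
            out / "census.tsv", sep="\t", index=False, lineterminator="\n")
        tio.write_feature_table(cleaned.table, out / "cleaned_table.tsv")
        rule_tally = {
            k: int(v)
            for k, v in calls_df[calls_df["verdict"] == "remove"]
            .groupby("rule")["feature_id"].nunique().items()
        }
        _write_json(
            {"per_rule_removed": rule_tally,
             "n_features_removed": len(report.removed_features),
             "reads_removed_per_sample": report.removed_reads_per_sample,
             "removed_fraction_per_sample": report.removed_fraction_per_sample},
            out / "decontamination_summary.json",
        )
        stage_entry(
            "decontamination", elapsed_s=round(time.time() - t0, 3),
            n_features_before=dataset.table.shape[0],
            n_features_after=cleaned.table.shape[0],
            n_samples_after=cleaned.table.shape[1],
            per_rule_removed=rule_tally,
        )

        # ---- community statistics ---------------------------------------
        t0 = time.time()
        depth = config.rarefy_depth
        if depth is None:
            sums = cleaned.table.column_sums()
            # zero-read samples (possible when cleaning strips a whole
            # habitat's features) are dropped by rarefaction, not counted
            depth = int(sums[sums > 0].min())
        rarefied = cs.rarefy_even_depth(
            cleaned.table, depth=depth, seed=config.stage_seed("rarefy"))
        alpha = cs.alpha_diversity_frame(rarefied)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", lineterminator="\n")
        sample_types = np.array(
            [cleaned.metadata[s].sample_type.value for s in rarefied.sample_ids])
        tests: dict[str, Any] = {}
        if len(set(sample_types)) >= 2:
            for metric in ("observed_richness", "shannon"):
                vals = alpha[metric].to_numpy(dtype=float)
                res = cs.anova_oneway(vals, sample_types)
                tests[f"anova_{metric}"] = _test_result_dict(res)
                if all((sample_types == g).sum() >= 2 for g in set(sample_types)):
                    tests[f"tukey_{metric}"] = [
                        _test_result_dict(r) for r in cs.tukey_hsd(vals, sample_types)]
        dist = cs.bray_curtis_matrix(rarefied)
        dist_df = pd.DataFrame(dist.values, index=dist.sample_ids, columns=dist.sample_ids)
        dist_df.to_csv(out / "bray_curtis.tsv", sep="\t", lineterminator="\n")
        ordination = cs.nmds(dist, seed=config.stage_seed("nmds"))
        ord_df = pd.DataFrame(
            ordination.coordinates,
            index=ordination.sample_ids,
            columns=[f"axis{i + 1}" for i in range(ordination.coordinates.shape[1])],
        )
        with open(out / "ordination.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# stress={ordination.stress:.6f}\n")
            ord_df.to_csv(fh, sep="\t", lineterminator="\n")
        if len(set(sample_types)) >= 2:
            res = cs.permanova(dist, sample_types,
                               n_permutations=config.n_permutations,
                               seed=config.stage_seed("permanova"))
            tests["permanova_sample_type"] = _test_result_dict(res)
            if len(set(sample_types)) >= 3:
                tests["pairwise_permanova"] = [
                    _test_result_dict(r)
                    for r in cs.pairwise_permanova(
                        dist, sample_types, n_permutations=config.n_permutations,
                        seed=config.stage_seed("permanova"))
                ]
        env = pd.DataFrame(
            {"depth_m": [cleaned.metadata[s].depth_m for s in ordination.sample_ids],
             "temperature_C": [cleaned.metadata[s].temperature_C
                               for s in ordination.sample_ids]},
            index=ordination.sample_ids, dtype=float)
        usable = [c for c in env.columns if env[c].notna().sum() >= 3
                  and env[c].dropna().nunique() > 1]
        if usable:
            fits = cs.envfit(ordination, env[usable],
                             n_permutations=config.n_permutations,
                             seed=config.stage_seed("envfit"))
            tests["envfit"] = {k: _test_result_dict(v) for k, v in fits.items()}
        _write_json(tests, out / "tests.json")
        stage_entry(
            "community_stats", elapsed_s=round(time.time() - t0, 3),
            rarefaction_depth=int(rarefied.column_sums().iloc[0]),
            n_samples=rarefied.shape[1], stress=round(ordination.stress, 6),
            seeds={k: config.stage_seed(k) for k in ("rarefy", "nmds", "permanova", "envfit")},
        )

        # ---- differential abundance --------------------------------------
        t0 = time.time()
        g_a, g_b = config.da_groups
        types_present = {cleaned.metadata[s].sample_type.value
                         for s in cleaned.table.sample_ids}
        if g_a in types_present and g_b in types_present:
            results = da.nb_wald_two_group(cleaned.table, cleaned.metadata, g_a, g_b)
            frame = da.results_frame(results)
            frame.to_csv(out / "differential_abundance.tsv", sep="\t",
                         index=False, lineterminator="\n")
            stage_entry("differential_abundance", elapsed_s=round(time.time() - t0, 3),
                        comparison=f"{g_b} vs {g_a}", n_tested=len(results),
                        n_significant=int(frame["significant"].sum()) if len(frame) else 0)
        else:
            stage_entry("differential_abundance", skipped=True,
                        reason=f"groups {g_a!r}/{g_b!r} not both present")

        # ---- manifest ----------------------------------------------------
        manifest["outputs"] = {
            p.name: _sha256(p) for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        }
        manifest["elapsed_s"] = round(time.time() - t_all, 3)
        if truth is not None:
            metrics = sc.evaluate_calls(calls, truth)
            manifest["recovery"] = dataclasses.asdict(metrics)
            manifest["composition_error_before"] = sc.composition_error(
                dataset.table.drop_samples(
                    [s for s in dataset.table.sample_ids
                     if dataset.metadata[s].sample_type
                     in (tio.SampleType.DRILLING_FLUID, tio.SampleType.NEGATIVE_CONTROL)]),
                truth)
            manifest["composition_error_after"] = sc.composition_error(cleaned.table, truth)
        _write_json(manifest, out / "manifest.json")
        return manifest
    except Exception:
        # retain partial outputs under a .partial suffix for post-mortem
        for p in out.glob("*"):
            if p.is_file() and not p.name.endswith(".partial"):
                p.rename(p.with_name(p.name + ".partial"))
        raise
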