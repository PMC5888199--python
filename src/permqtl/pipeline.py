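"""End-to-end pipeline: QC -> normalize -> LD blocks -> scans -> permutation
thresholds -> covariate robustness -> report.

Every stage writes its artifact plus a JSON provenance record (input
hashes, parameters, seed, package version) so any stage can be re-run in
isolation; a stage failure halts the run with the stage name while partial
outputs are retained.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assoc, covars, exprprep, genoqc, io, loci, permnull
from .config import PipelineConfig
from .errors import EmptyResultError, StageError


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _Runner:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    def provenance(self, stage: str, params: dict, inputs: dict) -> None:
        record = {
            "stage": stage,
            "version": __version__,
            "seed": self.cfg.seed,
            "params": params,
            "inputs": {k: _sha256(v) for k, v in inputs.items() if Path(v).exists()},
        }
        (self.out / f"{stage}.provenance.json").write_text(
            json.dumps(record, indent=2, sort_keys=True)
        )

    def run_stage(self, stage: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(stage, exc) from exc


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    cfg.validate()
    runner = _Runner(cfg)
    out = runner.out

    # ---- load inputs
    geno = runner.run_stage("load", io.read_genotypes, cfg.genotypes)
    expr = runner.run_stage(
        "load", io.read_expression, cfg.expression, cfg.probe_annotation
    )
    meta = runner.run_stage("load", io.read_sample_metadata, cfg.metadata)
    risk = runner.run_stage("load", io.read_index_snps, cfg.index_snps)

    # ---- genotype QC
    thresholds = genoqc.QCThresholds(cfg.min_call_rate, cfg.min_maf, cfg.min_info)
    regions = [tuple(r) for r in cfg.region_blacklist]
    geno, report = runner.run_stage(
        "qc", genoqc.apply_filters, geno, thresholds, regions, cfg.quality_blacklist
    )
    qc_df = pd.DataFrame(
        [
            {"rule": "samples_call_rate", "removed": report.samples_removed_call_rate},
            *[
                {"rule": f"variants_{rule}", "removed": n}
                for rule, n in report.variants_removed.items()
            ],
            {"rule": "survivors_samples", "removed": report.survivors_samples},
            {"rule": "survivors_variants", "removed": report.survivors_variants},
        ]
    )
    io.write_table(qc_df, out / "qc_report.tsv")
    runner.provenance(
        "qc",
        {"thresholds": thresholds.__dict__, "regions": regions},
        {"genotypes": cfg.genotypes},
    )

    # ---- expression preparation
    def _prep():
        e = expr
        if cfg.probe_blacklist:
            e = exprprep.exclude_probes(e, cfg.probe_blacklist)
        if cfg.normalize_method != "none" and e.state == "raw":
            e = exprprep.normalize(e, cfg.normalize_method)
        if cfg.batch_column in meta.columns:
            labels = meta.loc[e.sample_ids, cfg.batch_column]
            if labels.nunique() > 1:
                e = exprprep.regress_out_batch(e, labels)
        return e

    expr = runner.run_stage("normalize", _prep)
    expr.values.T.to_csv(out / "expression_prepared.tsv", sep="\t", index_label="probe_id")
    runner.provenance(
        "normalize",
        {"method": cfg.normalize_method, "batch_column": cfg.batch_column},
        {"expression": cfg.expression},
    )

    # ---- LD blocks and cis/trans assignments
    blocks, skipped = runner.run_stage(
        "map-loci",
        loci.build_ld_blocks,
        risk,
        geno,
        cfg.r2_min,
        cfg.search_window_bp,
    )
    if not blocks:
        raise StageError("map-loci", EmptyResultError("no index SNP could be resolved"))
    io.write_blocks(blocks, out / "blocks.bed", out / "block_members.tsv")
    placed = expr.probes.dropna(subset=["chrom", "start_pos"])
    assignments = loci.classify_probes(blocks, placed, cfg.cis_window_bp)
    io.write_table(assignments, out / "assignments.tsv")
    runner.provenance(
        "map-loci",
        {"r2_min": cfg.r2_min, "skipped_index_snps": skipped},
        {"index_snps": cfg.index_snps},
    )

    # ---- scans, permutation nulls, thresholds
    summary: dict = {"alphas": list(cfg.alphas), "modes": {}}
    results_by_mode: dict[str, pd.DataFrame] = {}
    for mode in ("cis", "trans"):
        results = runner.run_stage(
            f"scan-{mode}", assoc.scan, geno, expr, blocks, assignments, mode
        )
        results["p_bh"] = assoc.bh_adjust(results["p_nominal"]) if len(results) else []
        io.write_table(results, out / f"results_{mode}.tsv")
        results_by_mode[mode] = results
        if results.empty:
            summary["modes"][mode] = {"n_tests": 0}
            continue
        null = runner.run_stage(
            f"permute-{mode}",
            permnull.permute_scan,
            geno,
            expr,
            blocks,
            assignments,
            cfg.permutations,
            cfg.seed,
            mode,
            tuple(cfg.alphas),
        )
        np.savetxt(out / f"null_min_p_{mode}.tsv", null.min_p, header="min_p", comments="")
        results[f"p_perm"] = permnull.empirical_adjusted_p(
            results["p_nominal"].to_numpy(), null
        )
        io.write_table(results, out / f"results_{mode}.tsv")
        summary["modes"][mode] = null.summary()
        runner.provenance(
            f"permute-{mode}",
            {"R": cfg.permutations, "alphas": list(cfg.alphas)},
            {},
        )
    (out / "thresholds.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    # ---- covariate robustness on experiment-wide significant cis results
    cis = results_by_mode["cis"]
    robustness = pd.DataFrame()
    if not cis.empty and summary["modes"]["cis"].get("alpha_thresholds"):
        thr = summary["modes"]["cis"]["alpha_thresholds"][str(cfg.alphas[0])]
        significant = cis[cis["p_nominal"] <= thr]
        if not significant.empty:
            robustness = runner.run_stage(
                "covars",
                covars.robustness_sweep,
                significant,
                geno,
                expr,
                meta,
                cfg.covariates,
                cfg.delta_tolerance,
            )
    io.write_table(robustness, out / "robustness.tsv")

    # ---- report: lead SNP per probe and Manhattan table
    def _report():
        thr_map = summary["modes"]["cis"].get("alpha_thresholds", {})
        thr = thr_map.get(str(cfg.alphas[0]), 0.0)
        lead = assoc.lead_per_gene(cis, thr) if not cis.empty else pd.DataFrame()
        io.write_table(lead, out / "lead_eqtls.tsv")
        manh = (
            pd.concat(
                [assoc.manhattan_table(df) for df in results_by_mode.values() if not df.empty],
                ignore_index=True,
            )
            if any(not df.empty for df in results_by_mode.values())
            else pd.DataFrame()
        )
        io.write_table(manh, out / "manhattan.tsv")

    runner.run_stage("report", _report)
    runner.provenance("report", {"alphas": list(cfg.alphas)}, {})
    return out
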