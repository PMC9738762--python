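"""Pipeline configuration and end-to-end orchestration.

A :class:`PipelineConfig` collects the input paths and the analysis
thresholds that the underlying stages leave open (resistance quantile, kill
rule, DE thresholds, fa clipping, positivity rule, seeds), round-trips
losslessly through YAML, and is validated before a run. :func:`run_pipeline`
executes the stages in dependency order — rank, single-cell screen,
double-hit, synergy, differential expression, reverse match — writing one
TSV/JSON artifact per stage plus a provenance manifest (package version,
settings, SHA-256 of every input) sufficient to reproduce the run. A failed
stage halts its dependents; independent stages still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import KillRule, classify_resistance, rank_secdrugs
from .de_match import differential_expression, reverse_match
from .pgx_io import read_annotations, read_drug_annotations, read_panel
from .sc_screen import (
    GeneProgram,
    detect_cluster_erosion,
    double_hit,
    normalize_counts,
    read_cell_matrix,
    read_programs_yaml,
    score_program,
)
from .synergy import DEFAULT_EPS, CombinationMeasurement, compute_ci, fit_median_effect
from .dose_response import CytotoxicityCurve, fit_4pl

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds for an end-to-end run."""

    out_dir: str = "secdrug_out"
    # inputs (any may be None to skip the stage)
    panel: str | None = None
    line_annotations: str | None = None
    drug_annotations: str | None = None
    single_agent: list = field(default_factory=list)  # CSV per drug
    combination: str | None = None
    sc_pre_counts: str | None = None
    sc_pre_metadata: str | None = None
    sc_post_counts: str | None = None
    sc_post_metadata: str | None = None
    programs: str | None = None
    patient_expr: str | None = None
    patient_labels: str | None = None
    treatment_pre: str | None = None
    treatment_post: str | None = None
    # thresholds
    primary_drug: str = "docetaxel"
    q: float = 0.75
    kill_mode: str = "per_drug_quantile"
    q_kill: float = 0.5
    kill_cutoff_nM: float | None = None
    p_threshold: float = 0.05
    fc_threshold: float = 1.0
    eps: float = DEFAULT_EPS
    positivity_fraction: float = 0.5
    flagged_clusters: list = field(default_factory=list)
    tissues: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in (
            ("q", 0.0, 1.0), ("q_kill", 0.0, 1.0), ("p_threshold", 0.0, 1.0),
            ("eps", 0.0, 0.5), ("positivity_fraction", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be >= 0")
        if self.kill_mode not in ("per_drug_quantile", "absolute"):
            raise ValueError(f"unknown kill_mode {self.kill_mode!r}")

    def kill_rule(self) -> KillRule:
        if self.kill_mode == "absolute":
            return KillRule(mode="absolute", q_kill=None, cutoff_nM=self.kill_cutoff_nM)
        return KillRule(mode="per_drug_quantile", q_kill=self.q_kill)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_curve(path) -> CytotoxicityCurve:
    df = pd.read_csv(path)
    drug = str(df["drug_id"].iloc[0]) if "drug_id" in df.columns else Path(path).stem
    if "replicate_id" not in df.columns:
        df["replicate_id"] = 1
    return CytotoxicityCurve(
        drug, df[["concentration_nM", "percent_survival", "replicate_id"]]
    )


def _load_sc(counts_path, metadata_path):
    adata = read_cell_matrix(counts_path, metadata_path=metadata_path)
    return normalize_counts(adata)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage whose inputs are configured; return a report.

    The report maps stage name -> {"status": ok|failed|skipped, ...}; the
    provenance manifest is written to ``out_dir/run_manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, dict] = {}
    artifacts: dict[str, object] = {}

    def stage(name, requires, inputs, fn):
        missing = [p for p in inputs if p and not Path(p).exists()]
        if any(i is None for i in inputs) or not inputs:
            report[name] = {"status": "skipped", "reason": "inputs not configured"}
            return
        if missing:
            report[name] = {"status": "failed", "reason": f"missing input file(s): {missing}"}
            logger.error("stage %s: missing inputs %s", name, missing)
            return
        failed_deps = [r for r in requires if report.get(r, {}).get("status") != "ok"]
        if failed_deps:
            report[name] = {"status": "skipped", "reason": f"dependency failed: {failed_deps}"}
            return
        try:
            outputs = fn()
            report[name] = {"status": "ok", "outputs": outputs}
            logger.info("stage %s: ok", name)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            report[name] = {"status": "failed", "reason": str(exc)}
            logger.error("stage %s: %s", name, exc)

    def do_rank():
        ann = read_annotations(config.line_annotations) if config.line_annotations else None
        panel = read_panel(config.panel, annotations=ann)
        if config.tissues:
            from .pgx_io import filter_by_tissue

            panel = filter_by_tissue(panel, config.tissues)
        drug_ann = (
            read_drug_annotations(config.drug_annotations)
            if config.drug_annotations else None
        )
        cls = classify_resistance(panel, config.primary_drug, config.q)
        ranking = rank_secdrugs(panel, cls, config.kill_rule(), drug_ann)
        path = out / "ranking.tsv"
        ranking.table.to_csv(path, sep="\t", index=False)
        sidecar = out / "ranking_settings.json"
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "primary_drug": config.primary_drug, "q": config.q,
                    "threshold_nM": cls.threshold_value,
                    "n_resistant": len(cls.resistant_lines),
                    "kill_rule": dataclasses.asdict(config.kill_rule()),
                },
                fh, indent=2,
            )
        artifacts["ranking"] = ranking
        return [str(path), str(sidecar)]

    stage("rank", [], [config.panel], do_rank)

    def do_screen():
        adata = _load_sc(config.sc_pre_counts, config.sc_pre_metadata)
        programs = read_programs_yaml(config.programs)
        tables = []
        screens = {}
        for prog in programs:
            res = score_program(adata, prog, config.positivity_fraction)
            tables.append(res.reset_index())
            screens[prog.name] = res
        path = out / "sc_screen.tsv"
        pd.concat(tables, ignore_index=True).to_csv(path, sep="\t", index=False)
        artifacts["screens"] = screens
        return [str(path)]

    stage("screen-sc", [], [config.sc_pre_counts, config.sc_pre_metadata,
                            config.programs], do_screen)

    def do_doublehit():
        ranking = artifacts["ranking"]
        screens = artifacts["screens"]
        drug_ann = read_drug_annotations(config.drug_annotations)
        by_drug = {}
        for drug in ranking.table["drug_id"]:
            pw = drug_ann["target_pathway"].get(drug)
            for name, screen in screens.items():
                if pw and (name == drug or name.lower() in str(pw).lower()
                           or str(pw).lower() in name.lower()):
                    by_drug[drug] = screen
                    break
        table = double_hit(ranking, by_drug, config.flagged_clusters)
        path = out / "double_hit.tsv"
        table.to_csv(path, sep="\t", index=False)
        return [str(path)]

    stage("double-hit", ["rank", "screen-sc"], [config.drug_annotations], do_doublehit)

    def do_synergy():
        curves = [_read_curve(p) for p in config.single_agent[:2]]
        fits = [fit_median_effect(c, config.eps) for c in curves]
        combo_df = pd.read_csv(config.combination)
        combo = CombinationMeasurement(combo_df[["d1", "d2", "fa"]])
        res = compute_ci(fits[0], fits[1], combo, config.eps)
        path = out / "combination_index.tsv"
        res.table.to_csv(path, sep="\t", index=False)
        return [str(path)]

    stage(
        "synergy", [],
        (list(config.single_agent[:2]) + [config.combination])
        if len(config.single_agent) >= 2 else [None],
        do_synergy,
    )

    def do_de():
        patients = pd.read_csv(config.patient_expr, index_col=0)
        labels = pd.read_csv(config.patient_labels, index_col=0).iloc[:, 0]
        groups = sorted(labels.unique())
        de_pat = differential_expression(
            patients.loc[labels == "BCR" if "BCR" in set(labels) else labels == groups[0]],
            patients.loc[labels != "BCR" if "BCR" in set(labels) else labels == groups[1]],
            config.p_threshold, config.fc_threshold,
            group_names=("BCR", "no_BCR") if "BCR" in set(labels) else tuple(groups[:2]),
        )
        post = pd.read_csv(config.treatment_post, index_col=0)
        pre = pd.read_csv(config.treatment_pre, index_col=0)
        de_tx = differential_expression(
            post, pre, config.p_threshold, config.fc_threshold,
            group_names=("post", "pre"),
        )
        p1 = out / "de_patient.tsv"
        p2 = out / "de_treatment.tsv"
        de_pat.table.to_csv(p1, sep="\t")
        de_tx.table.to_csv(p2, sep="\t")
        artifacts["de"] = (de_pat, de_tx)
        return [str(p1), str(p2)]

    stage("de", [], [config.patient_expr, config.patient_labels,
                     config.treatment_pre, config.treatment_post], do_de)

    def do_revmatch():
        de_pat, de_tx = artifacts["de"]
        res = reverse_match(de_pat, de_tx)
        path = out / "reverse_match.tsv"
        res.table.to_csv(path, sep="\t")
        jpath = out / "reverse_match_summary.json"
        with open(jpath, "w") as fh:
            json.dump(res.summary, fh, indent=2)
        return [str(path), str(jpath)]

    stage("revmatch", ["de"], [config.patient_expr], do_revmatch)

    def do_erosion():
        pre = _load_sc(config.sc_pre_counts, config.sc_pre_metadata)
        post = _load_sc(config.sc_post_counts, config.sc_post_metadata)
        table = detect_cluster_erosion(pre, post)
        path = out / "cluster_erosion.tsv"
        table.to_csv(path, sep="\t")
        return [str(path)]

    stage("erosion", [], [config.sc_pre_counts, config.sc_pre_metadata,
                          config.sc_post_counts, config.sc_post_metadata], do_erosion)

    input_paths = [
        p for p in (
            [config.panel, config.line_annotations, config.drug_annotations,
             config.combination, config.sc_pre_counts, config.sc_pre_metadata,
             config.sc_post_counts, config.sc_post_metadata, config.programs,
             config.patient_expr, config.patient_labels, config.treatment_pre,
             config.treatment_post] + list(config.single_agent)
        )
        if p and Path(p).exists()
    ]
    manifest = {
        "secdrug_version": __version__,
        "settings": dataclasses.asdict(config),
        "input_checksums": {p: _sha256(p) for p in input_paths},
        "stages": report,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report
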