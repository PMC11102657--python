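"""End-to-end orchestration: simulate → construct → metrics → hubs → stats.

A :class:`PipelineConfig` bundles every stage's configuration; every stage
config is validated before any stage runs.  :func:`run_pipeline` writes all
stage outputs under an output directory and returns a :class:`RunReport`
that records inputs, parameters, warnings and output paths — enough to
re-run the pipeline bit-identically.

Per-subject randomness derives from a single global seed through named
substreams (stable CRC hashing of subject id and stage name), so the order
in which subjects are processed cannot change any result.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .construct import ConstructionConfig, sweep_sparsity
from .hubs import HubConfig, group_hub_report
from .metrics import NODAL_METRICS, NullModelConfig, subject_profiles
from .stats import InferenceConfig, run_group_analysis
from .synth import (
    CohortConfig,
    StreamlineMatrix,
    SubjectRecord,
    generate_cohort,
    load_cohort,
    write_cohort,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_inputs",
           "cohort_metric_tables"]

log = logging.getLogger("wmtopo")


@dataclass
class PipelineConfig:
    """Configuration of every pipeline stage.

    Either ``manifest`` (load an existing cohort) or ``cohort`` (simulate
    one) must be provided.  ``seed`` overrides the cohort config's seed so a
    single flag controls all randomness.
    """

    outdir: Path
    manifest: Path | None = None
    cohort: CohortConfig | None = None
    construction: ConstructionConfig = field(default_factory=ConstructionConfig)
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    hubs: HubConfig = field(default_factory=HubConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    nodal_metrics: tuple[str, ...] = NODAL_METRICS
    compute_smallworld: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.manifest is None and self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        elif self.cohort is not None and self.cohort.seed != self.seed:
            self.cohort = dataclasses.replace(self.cohort, seed=self.seed)


@dataclass
class RunReport:
    """Record of one pipeline run: parameters, warnings, outputs."""

    version: str = __version__
    schema_version: int = 1
    seed: int = 0
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, **params) -> None:
        self.stages[name] = params

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def validate_inputs(manifest_path: str | Path) -> list[dict]:
    """Itemized validation of a cohort manifest.

    Checks matrix squareness/symmetry/nonnegativity, dimension consistency
    with the node-label table, and metadata completeness.  Returns one
    record per check: ``{"check", "subject", "ok", "detail"}``.
    """
    import csv
    import json as _json

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    checks: list[dict] = []
    try:
        manifest = _json.loads(manifest_path.read_text())
        n_ref = int(manifest["n_nodes"])
        labels = [
            row[1]
            for row in csv.reader(
                open(root / manifest["node_labels"]), delimiter="\t"
            )
        ]
        meta = {
            row["id"]: row for row in csv.DictReader(open(root / manifest["metadata"]))
        }
    except Exception as exc:  # malformed manifest: itemized, not raised
        return [{"check": "load", "subject": None, "ok": False, "detail": str(exc)}]
    checks.append({
        "check": "labels", "subject": None, "ok": len(labels) == n_ref,
        "detail": f"{len(labels)} labels for {n_ref} nodes",
    })
    for entry in manifest["subjects"]:
        sid = entry["id"]
        try:
            c = np.loadtxt(root / entry["matrix"], delimiter="\t")
        except Exception as exc:
            checks.append({"check": "matrix", "subject": sid, "ok": False,
                           "detail": str(exc)})
            continue
        asym = np.argwhere(c != c.T)
        checks.append({
            "check": "symmetric", "subject": sid, "ok": len(asym) == 0,
            "detail": "" if len(asym) == 0
            else f"first offending pair {tuple(int(v) for v in asym[0])}",
        })
        checks.append({
            "check": "dimension", "subject": sid,
            "ok": c.ndim == 2 and c.shape == (n_ref, n_ref),
            "detail": f"{c.shape}",
        })
        checks.append({
            "check": "nonnegative", "subject": sid, "ok": bool(np.all(c >= 0)),
            "detail": "",
        })
        row = meta.get(sid)
        if row is None:
            checks.append({"check": "metadata", "subject": sid, "ok": False,
                           "detail": "subject missing from metadata"})
            continue
        missing = [k for k, v in row.items() if v in ("", None)]
        checks.append({
            "check": "metadata", "subject": sid, "ok": not missing,
            "detail": ",".join(missing),
        })
    return checks


def cohort_metric_tables(
    cohort: list[tuple[SubjectRecord, StreamlineMatrix]],
    construction: ConstructionConfig,
    null_model: NullModelConfig | None,
    nodal_metrics: tuple[str, ...] = NODAL_METRICS,
    report: RunReport | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-subject AUC tables for group analysis.

    Returns ``(global_aucs, nodal_aucs, metadata)``: subjects x metrics,
    per-metric subjects x nodes, and the metadata frame.  ``null_model=None``
    skips the normalized metrics (gamma/lambda/sigma and their AUCs).
    """
    glob_rows, meta_rows = [], []
    nodal_acc: dict[str, list[np.ndarray]] = {m: [] for m in nodal_metrics}
    ids = []
    labels = cohort[0][1].node_labels
    for subj_i, (rec, mat) in enumerate(cohort):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            nets = sweep_sparsity(mat.counts, construction)
            nm = (
                dataclasses.replace(null_model, seed=null_model.seed + 1000 * subj_i)
                if null_model is not None
                else None
            )
            gp, np_tab = subject_profiles(nets, labels, nm, nodal_metrics)
        if report is not None:
            for w in caught:
                report.warnings.append(f"{rec.id}: {w.message}")
            if any(net.connected is False for net in nets):
                bad = [net.sparsity for net in nets if net.connected is False]
                report.warnings.append(f"{rec.id}: disconnected at sparsity {bad}")
        ids.append(rec.id)
        glob_rows.append(gp.auc)
        for m in nodal_metrics:
            nodal_acc[m].append(np_tab.auc[m])
        meta_rows.append({
            "id": rec.id, "group": rec.group, "age": rec.age, "sex": rec.sex,
            "education": rec.education, **rec.scores,
        })
    global_aucs = pd.DataFrame(glob_rows, index=ids)
    nodal_aucs = {
        m: pd.DataFrame(np.vstack(v), index=ids, columns=labels)
        for m, v in nodal_acc.items()
    }
    metadata = pd.DataFrame(meta_rows).set_index("id")
    return global_aucs, nodal_aucs, metadata


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write all outputs under ``config.outdir``.

    The report's ``outputs`` map names every written file; a human-readable
    ``summary.txt`` lists group mean ± SD of each global AUC metric, the
    hub partition, and FDR-significant correlations.
    """
    report = RunReport(seed=config.seed)
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: cohort -----------------------------------------------------
    if config.manifest is not None:
        cohort = load_cohort(config.manifest)
        report.add_stage("cohort", mode="load", manifest=str(config.manifest),
                         n_subjects=len(cohort))
    else:
        cohort = generate_cohort(config.cohort, config.construction)
        manifest = write_cohort(cohort, out / "cohort", seed=config.seed)
        report.add_stage("cohort", mode="simulate",
                         **dataclasses.asdict(config.cohort))
        report.outputs["cohort_manifest"] = str(manifest)
    log.info("cohort ready: %d subjects", len(cohort))

    # -- stage 2+3: construction and metrics ---------------------------------
    null_model = config.null_model if config.compute_smallworld else None
    global_aucs, nodal_aucs, metadata = cohort_metric_tables(
        cohort, config.construction, null_model, config.nodal_metrics, report
    )
    report.add_stage("construction", **dataclasses.asdict(config.construction))
    report.add_stage(
        "metrics",
        null_model=dataclasses.asdict(config.null_model) if null_model else None,
        nodal_metrics=list(config.nodal_metrics),
    )
    global_aucs.rename_axis("id").to_csv(out / "global_auc.csv")
    report.outputs["global_auc"] = str(out / "global_auc.csv")
    for m, table in nodal_aucs.items():
        p = out / f"nodal_auc_{m}.csv"
        table.rename_axis("id").to_csv(p)
        report.outputs[f"nodal_auc_{m}"] = str(p)
    log.info("metrics computed for %d subjects", len(global_aucs))

    # -- stage 4: hubs --------------------------------------------------------
    labels = cohort[0][1].node_labels
    grp = metadata["group"].to_numpy()
    deg = nodal_aucs["degree"].to_numpy()
    hub_report = group_hub_report(
        deg[grp == "control"], deg[grp == "patient"], labels, config.hubs
    )
    (out / "hubs.json").write_text(json.dumps(hub_report.to_dict(), indent=2))
    report.add_stage("hubs", **dataclasses.asdict(config.hubs))
    report.outputs["hubs"] = str(out / "hubs.json")

    # -- stage 5: inference ---------------------------------------------------
    analysis = run_group_analysis(global_aucs, nodal_aucs, metadata, config.inference)
    analysis.global_frame().to_csv(out / "group_tests_global.csv", index=False)
    analysis.nodal_frame().to_csv(out / "group_tests_nodal.csv", index=False)
    analysis.correlation_frame().to_csv(out / "correlations.csv", index=False)
    report.add_stage("inference", **dataclasses.asdict(config.inference))
    for key in ("group_tests_global", "group_tests_nodal", "correlations"):
        report.outputs[key] = str(out / f"{key}.csv")

    # -- summary --------------------------------------------------------------
    lines = [f"wmtopo {__version__} run (seed={config.seed})", ""]
    lines.append("Global AUC metrics, group mean ± SD:")
    for col in global_aucs.columns:
        mp = global_aucs.loc[grp == "patient", col]
        mc = global_aucs.loc[grp == "control", col]
        test = next((t for t in analysis.global_tests if t.name == col), None)
        extra = (
            f"  t={test.t:+.2f} p_fdr={test.p_fdr:.4f} d={test.d:.3f}"
            if test else ""
        )
        lines.append(
            f"  {col:>8}: patient {mp.mean():.3f} ± {mp.std():.3f}   "
            f"control {mc.mean():.3f} ± {mc.std():.3f}{extra}"
        )
    hub_d = hub_report.to_dict()
    lines += ["", "Hub partition:"]
    for key in ("lost", "preserved", "reconfigured"):
        lines.append(f"  {key} ({len(hub_d[key])}): {', '.join(hub_d[key])}")
    sig = [c for c in analysis.correlations if c.p_fdr < config.inference.alpha]
    lines += ["", f"FDR-significant correlations (alpha={config.inference.alpha}):"]
    if sig:
        for c in sorted(sig, key=lambda c: c.p_fdr):
            lines.append(
                f"  {c.node} x {c.score}: r={c.r:+.4f} p_fdr={c.p_fdr:.4g} (n={c.n})"
            )
    else:
        lines.append("  none")
    if report.warnings:
        lines += ["", f"Warnings ({len(report.warnings)}):"]
        lines += [f"  {w}" for w in report.warnings[:20]]
    summary = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(summary)
    report.outputs["summary"] = str(out / "summary.txt")
    report.to_json(out / "run_report.json")
    report.outputs["report"] = str(out / "run_report.json")
    log.info("pipeline complete: %s", out)
    return report
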