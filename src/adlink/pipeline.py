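"""End-to-end orchestration: ingest/simulate -> abundance -> membership ->
ordination/diversity/Mantel -> performance correlation, with one master
seed, structured logging to stderr and a JSON run report.

Per-stage seeds are derived deterministically from the master seed by
hashing the stage name, so any stage re-run in isolation reproduces its
part of a full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, performance, qpcr, simulate
from .membership import membership as compute_membership, membership_report
from .datamodel import (
    CountTable,
    Feed,
    Stage,
    align_tables,
    file_digest,
    read_count_table,
    read_metadata,
    read_qpcr,
    read_scod,
)

log = logging.getLogger("adlink")


def setup_logging(level: int = logging.INFO) -> None:
    """Log to stderr; result files are the only stdout-free outputs."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("adlink")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run."""

    outdir: str = "adlink_out"
    # either all four input paths, or simulate=True
    counts_path: str | None = None
    metadata_path: str | None = None
    qpcr_path: str | None = None
    scod_path: str | None = None
    simulate: bool = False
    # analysis constants
    rarefaction_depth: int = 3000
    prevalence_threshold: float = 0.5
    detection_threshold: int = 1
    prevalence_scope: str = "pooled"
    nmds_k: int = 4
    nmds_trymax: int = 100
    mantel_permutations: int = 999
    mantel_method: str = "pearson"
    alpha: float = 0.05
    window_days: int = 5
    pairing_window: int = 3
    min_n: int = 6
    detection_limit: float = qpcr.DETECTION_LIMIT_COPIES_PER_ML
    below_detection: str = "exclude"  # or "half-limit"
    seed: int = 0
    generator: simulate.GeneratorConfig | None = None


def derive_seed(master: int, stage_name: str) -> int:
    """Stable per-stage seed below 2**31 from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def validate_config(config: RunConfig) -> list[str]:
    """Collect every violation at once (findings, not exceptions)."""
    findings = []
    if config.rarefaction_depth <= 0:
        findings.append("rarefaction_depth must be >= 1")
    if not 0.0 < config.prevalence_threshold <= 1.0:
        findings.append("prevalence_threshold must be in (0, 1]")
    if config.detection_threshold < 1:
        findings.append("detection_threshold must be >= 1")
    if config.nmds_k < 1:
        findings.append("k must be >= 1")
    if config.nmds_trymax < 1:
        findings.append("trymax must be >= 1")
    if config.mantel_permutations < 1:
        findings.append("mantel_permutations must be >= 1")
    if not 0.0 < config.alpha < 1.0:
        findings.append("alpha must be in (0, 1)")
    if config.window_days < 0:
        findings.append("window_days must be >= 0")
    if config.pairing_window < 0:
        findings.append("pairing_window must be >= 0")
    if config.min_n < 3:
        findings.append("min_n must be >= 3")
    if config.prevalence_scope not in ("pooled", "per-reactor"):
        findings.append("prevalence_scope must be 'pooled' or 'per-reactor'")
    if config.below_detection not in ("exclude", "half-limit"):
        findings.append("below_detection must be 'exclude' or 'half-limit'")
    if not config.simulate:
        for name in ("counts_path", "metadata_path", "qpcr_path", "scod_path"):
            if getattr(config, name) is None:
                findings.append(f"{name} required unless simulate=true")
    return findings


def load_config(path: str | Path) -> RunConfig:
    """Read a flat TOML config file into a RunConfig."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    gen_raw = raw.pop("generator", None)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    config = RunConfig(**raw)
    if gen_raw is not None:
        gen_known = {f.name for f in fields(simulate.GeneratorConfig)}
        bad = set(gen_raw) - gen_known
        if bad:
            raise ValueError(f"unknown generator key(s): {sorted(bad)}")
        if "feed_removal_mean" in gen_raw:
            gen_raw["feed_removal_mean"] = {
                Feed(k): float(v) for k, v in gen_raw["feed_removal_mean"].items()
            }
        config.generator = simulate.GeneratorConfig(**gen_raw)
    return config


@dataclass
class RunReport:
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    record_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "input_digests": self.input_digests,
            "record_counts": self.record_counts,
            "warnings": self.warnings,
            "outputs": self.outputs,
            "failed_stage": self.failed_stage,
            "error": self.error,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


class _ReportHandler(logging.Handler):
    """Capture pipeline warnings into the run report."""

    def __init__(self, report: RunReport):
        super().__init__(level=logging.WARNING)
        self.report = report

    def emit(self, record: logging.LogRecord) -> None:
        self.report.warnings.append(record.getMessage())


def total_copies_per_ml(
    qpcr_df: pd.DataFrame, meta, curve: qpcr.StandardCurve | None = None
) -> pd.Series:
    """Per-sample N (copies/mL) from the qPCR table.

    Prefers a direct ``copies_per_ul_template`` column; otherwise quantifies
    the mean of the ``cq_*`` replicate columns against the standard curve.
    """
    by_id = {r.sample_id: r for r in meta}
    cq_cols = [c for c in qpcr_df.columns if c.startswith("cq_")]
    values = {}
    for _, row in qpcr_df.iterrows():
        sid = row["sample_id"]
        if sid not in by_id:
            continue
        if "copies_per_ul_template" in qpcr_df.columns and not pd.isna(
            row.get("copies_per_ul_template")
        ):
            per_ul = float(row["copies_per_ul_template"])
        else:
            if curve is None:
                raise ValueError(
                    "qPCR table has only Cq values; a standard curve is required"
                )
            per_ul = qpcr.quantify_copies(
                float(np.mean([row[c] for c in cq_cols])), curve
            )
        rec = by_id[sid]
        values[sid] = qpcr.normalized_copy_number(per_ul, rec.v_t, rec.v_s)
    return pd.Series(values, name="copies_per_ml")


def run_all(config: RunConfig) -> RunReport:
    """Execute the whole pipeline; write all result TSVs plus the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: str(v) for k, v in vars(config).items()
                               if k != "generator"})
    capture = _ReportHandler(report)
    logging.getLogger("adlink").addHandler(capture)
    try:
        _run_all_inner(config, outdir, report)
    except Exception as exc:  # noqa: BLE001 - report, then re-raise
        report.error = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        logging.getLogger("adlink").removeHandler(capture)
        report.write(outdir / "run_report.json")
    return report


def _write_tsv(df: pd.DataFrame, path: Path, report: RunReport, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)
    report.outputs.append(path.name)


def _run_all_inner(config: RunConfig, outdir: Path, report: RunReport) -> None:
    findings = validate_config(config)
    if findings:
        report.failed_stage = "validate_config"
        raise ValueError("invalid config: " + "; ".join(findings))

    # --- ingest or simulate ------------------------------------------------
    report.failed_stage = "ingest"
    if config.simulate:
        gen = config.generator or simulate.GeneratorConfig()
        gen.seed = derive_seed(config.seed, "simulate")
        bundle = simulate.generate_experiment(gen)
        bundle.write(outdir / "simulated")
        counts, meta = bundle.counts, bundle.metadata
        qpcr_df, scod = bundle.qpcr, bundle.scod
    else:
        report.failed_stage = "read_count_table"
        counts = read_count_table(config.counts_path)
        report.failed_stage = "read_metadata"
        meta = read_metadata(config.metadata_path)
        report.failed_stage = "read_qpcr"
        qpcr_df = read_qpcr(config.qpcr_path)
        report.failed_stage = "read_scod"
        scod = read_scod(config.scod_path)
        report.failed_stage = "ingest"
        for key in ("counts_path", "metadata_path", "qpcr_path", "scod_path"):
            report.input_digests[key] = file_digest(getattr(config, key))
    counts, meta = align_tables(counts, meta)
    report.record_counts["samples"] = len(meta)
    report.record_counts["taxa"] = counts.shape[0]

    # --- abundance ---------------------------------------------------------
    report.failed_stage = "abundance"
    n = total_copies_per_ml(qpcr_df, meta)
    missing_n = [s for s in counts.samples if s not in n.index]
    if missing_n:
        log.warning("no qPCR value for sample(s) %s; excluded from EAA", missing_n)
    below = n[n < config.detection_limit]
    if len(below):
        if config.below_detection == "exclude":
            log.warning(
                "%d sample(s) below qPCR detection limit excluded: %s",
                len(below), sorted(below.index),
            )
            n = n[n >= config.detection_limit]
        else:
            n.loc[below.index] = config.detection_limit / 2.0
    eaa_samples = [s for s in counts.samples if s in n.index]
    ra, zero_depth = qpcr.relative_abundance(counts.select_samples(eaa_samples))
    eaa = qpcr.estimated_absolute_abundance(n[ra.columns], ra)
    _write_tsv(
        eaa.eaa.round(4), outdir / "eaa.tsv", report, index=True, index_label="taxon"
    )

    # --- membership --------------------------------------------------------
    report.failed_stage = "membership"
    member = compute_membership(
        counts, meta,
        prevalence_threshold=config.prevalence_threshold,
        detection_threshold=config.detection_threshold,
        prevalence_scope=config.prevalence_scope,
    )
    rows = [r.as_row() for r in membership_report(member)]
    _write_tsv(pd.DataFrame(rows), outdir / "membership.tsv", report)

    # --- rarefaction + diversity + ordination + Mantel ----------------------
    report.failed_stage = "rarefaction"
    rare = qpcr.rarefy(
        counts, depth=config.rarefaction_depth, seed=derive_seed(config.seed, "rarefy")
    )
    report.record_counts["rarefied_samples"] = rare.shape[1]

    report.failed_stage = "diversity"
    shannon_rows = [
        {"sample_id": d.sample_id, "shannon_h": round(d.shannon_h, 6)}
        for d in diversity.shannon_per_sample(rare)
    ]
    _write_tsv(pd.DataFrame(shannon_rows), outdir / "diversity.tsv", report)

    report.failed_stage = "ordination"
    bc = diversity.bray_curtis(rare)
    ord_res = diversity.nmds(
        bc, k=config.nmds_k, trymax=config.nmds_trymax,
        seed=derive_seed(config.seed, "nmds"),
    )
    coords = pd.DataFrame(
        np.round(ord_res.coordinates, 6),
        index=ord_res.labels,
        columns=[f"nmds{i + 1}" for i in range(config.nmds_k)],
    )
    _write_tsv(coords, outdir / "ordination.tsv", report, index=True,
               index_label="sample_id")
    report.record_counts["nmds_stress"] = round(ord_res.stress, 6)
    report.record_counts["nmds_converged"] = ord_res.converged

    report.failed_stage = "mantel"
    mantel_rows = []
    rare_meta = {r.sample_id: r for r in meta}
    for stage in sorted({r.stage for r in meta}, key=lambda s: s.value):
        stage_ids = [s for s in rare.samples if rare_meta[s].stage == stage]
        if len(stage_ids) < 4:
            continue
        sub_bc = diversity.bray_curtis(rare.select_samples(stage_ids))
        for factor in ("feed", "day"):
            fd = diversity.factor_distance(meta, factor, ids=stage_ids)
            res = diversity.mantel(
                sub_bc, fd,
                n_permutations=config.mantel_permutations,
                method=config.mantel_method,
                seed=derive_seed(config.seed, f"mantel:{stage.value}:{factor}"),
            )
            mantel_rows.append(
                {
                    "stage": stage.value, "factor": factor,
                    "r": round(res.r, 6) if not res.degenerate else "",
                    "p": round(res.p, 6),
                    "n_permutations": res.n_permutations,
                    "method": res.method, "degenerate": res.degenerate,
                }
            )
    _write_tsv(pd.DataFrame(mantel_rows), outdir / "mantel.tsv", report)

    # --- performance + correlation ------------------------------------------
    report.failed_stage = "performance"
    perf_rows = []
    for series in scod:
        performance.smooth_performance(series, config.window_days)
        raw = dict(performance.removal_series(series))
        for day, sm in series.smoothed:
            perf_rows.append(
                {
                    "pair_id": series.pair_id, "day": day,
                    "removal_percent": round(raw[day], 4),
                    "removal_smoothed": round(sm, 4),
                }
            )
    _write_tsv(pd.DataFrame(perf_rows), outdir / "performance.tsv", report)

    by_feed = performance.series_by_feed(scod, meta)
    groups = [
        [v for _, v in by_feed[f].smoothed]
        for f in sorted(by_feed, key=lambda f: f.value)
    ]
    if len(groups) >= 2:
        kw = performance.kruskal_wallis(groups)
        report.record_counts["kruskal_h"] = round(kw.h, 4)
        report.record_counts["kruskal_p"] = float(f"{kw.p_value:.6g}")

    report.failed_stage = "correlation"
    corr = performance.correlate_taxa_performance(
        eaa, scod, meta, membership=member,
        alpha=config.alpha, min_n=config.min_n,
        pairing_window=config.pairing_window,
        smoothing_window=config.window_days,
    )
    corr_rows = [
        {
            "stage": c.stage.value, "feed": c.feed.value, "genus": c.genus,
            "class": c.membership_class, "rho": round(c.rho, 4),
            "p": float(f"{c.p_value:.6g}"), "n": c.n,
            "passed_filter": c.passed_filter,
        }
        for c in corr
    ]
    _write_tsv(pd.DataFrame(corr_rows), outdir / "correlations.tsv", report)
    report.record_counts["correlation_records"] = len(corr_rows)
    report.record_counts["significant_correlations"] = sum(
        1 for c in corr if c.passed_filter
    )

    # Spearman of total biomass N vs removal, per stage (biomass null check)
    report.failed_stage = "biomass_null"
    for stage in sorted({r.stage for r in meta}, key=lambda s: s.value):
        xs, ys = [], []
        for rec in meta:
            if rec.stage != stage or rec.sample_id not in n.index:
                continue
            if rec.feed not in by_feed:
                continue
            sm = dict(by_feed[rec.feed].smoothed)
            if rec.day in sm:
                xs.append(n[rec.sample_id])
                ys.append(sm[rec.day])
        if len(xs) >= 3 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
            rho, p = performance.spearman(xs, ys)
            report.record_counts[f"biomass_removal_rho_{stage.value}"] = round(rho, 4)
            report.record_counts[f"biomass_removal_p_{stage.value}"] = float(
                f"{p:.6g}"
            )

    report.failed_stage = None
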