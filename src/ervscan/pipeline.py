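"""End-to-end orchestration: annotate -> count -> FPKM -> DE -> severity -> age.

One cohort per run (cohorts are never pooled or cross-normalized). Inputs are
a RepeatMasker ``.out`` table, a gene GTF, a sample sheet, and either
per-sample SAM/BAM alignments (full route) or a ready-made count matrix
(short route). Every stage output is a TSV with a parameter-echo header
comment; a JSON manifest records inputs, checksums, parameters, and outputs
so a run can be re-executed from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotations import (
    filter_intergenic,
    group_by_subfamily,
    parse_gtf_features,
    parse_repeatmasker_out,
    select_erv_copies,
    summarize_subfamilies,
    write_bed,
    write_subfamily_summary_tsv,
    DEFAULT_ERV_CLASS_PREFIXES,
)
from .diffexpr import DEThresholds, call_differential, severity_comparison, write_de_table
from .age_analysis import compare_divergence, write_age_report, write_divergence_long_table
from .quantification import (
    CountingParams,
    ExpressionMatrix,
    compute_fpkm,
    count_fragments,
    feature_lengths_from_copies,
    load_fragments,
    read_sample_sheet,
)

logger = logging.getLogger("ervscan")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated run configuration; see :func:`PipelineConfig.from_yaml`."""

    rmsk_path: Path
    gtf_path: Path
    sample_sheet_path: Path
    out_dir: Path
    alignments: dict[str, Path] | None = None  # sample_id -> SAM/BAM
    counts_path: Path | None = None
    erv_class_prefixes: tuple[str, ...] = DEFAULT_ERV_CLASS_PREFIXES
    weighted_divergence: bool = False
    counting: CountingParams = field(default_factory=CountingParams)
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    age_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.rmsk_path = Path(self.rmsk_path)
        self.gtf_path = Path(self.gtf_path)
        self.sample_sheet_path = Path(self.sample_sheet_path)
        self.out_dir = Path(self.out_dir)
        if (self.alignments is None) == (self.counts_path is None):
            raise ValueError("give exactly one of alignments or counts_path")
        for p in [self.rmsk_path, self.gtf_path, self.sample_sheet_path]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.counts_path is not None and not Path(self.counts_path).exists():
            raise FileNotFoundError(self.counts_path)
        if self.alignments is not None:
            self.alignments = {s: Path(p) for s, p in self.alignments.items()}
            for p in self.alignments.values():
                if not p.exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.update(overrides)
        counting = CountingParams(**raw.pop("counting", {}))
        thresholds = DEThresholds(**raw.pop("thresholds", {}))
        alignments = raw.pop("alignments", None)
        if alignments is not None:
            alignments = {s: Path(p) for s, p in alignments.items()}
        return cls(alignments=alignments, counting=counting, thresholds=thresholds, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _echo(config: PipelineConfig) -> list[str]:
    return [
        f"ervscan {__version__}",
        f"counting: min_mapq={config.counting.min_mapq} strandedness={config.counting.strandedness}",
        f"thresholds: alpha={config.thresholds.alpha} min_fc={config.thresholds.min_fold_change} "
        f"pseudocount={config.thresholds.pseudocount_fpkm} adjust={config.thresholds.adjust}",
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {},
        "parameters": {
            "erv_class_prefixes": list(config.erv_class_prefixes),
            "weighted_divergence": config.weighted_divergence,
            "counting": asdict(config.counting),
            "thresholds": asdict(config.thresholds),
            "age_alpha": config.age_alpha,
            "seed": config.seed,
        },
        "outputs": {},
    }
    for key, p in (
        ("rmsk", config.rmsk_path),
        ("gtf", config.gtf_path),
        ("sample_sheet", config.sample_sheet_path),
        ("counts", config.counts_path),
    ):
        if p is not None:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}
    if config.alignments:
        manifest["inputs"]["alignments"] = {
            s: {"path": str(p), "sha256": _sha256(p)} for s, p in config.alignments.items()
        }

    samples = read_sample_sheet(config.sample_sheet_path)
    if not samples:
        raise ValueError("empty sample sheet: nothing to analyze")
    conditions = {s.sample_id: s.condition for s in samples}
    if "covid" not in conditions.values() or "control" not in conditions.values():
        raise ValueError("sample sheet must contain both control and covid samples")

    # ---- annotate -------------------------------------------------------
    logger.info("stage annotate: %s", config.rmsk_path)
    with open(config.rmsk_path) as fh:
        repeats = parse_repeatmasker_out(fh)
    with open(config.gtf_path) as fh:
        genes = parse_gtf_features(fh)
    ervs = select_erv_copies(repeats, config.erv_class_prefixes)
    intergenic = filter_intergenic(ervs, genes)
    summaries = summarize_subfamilies(intergenic, ervs, config.weighted_divergence)
    usable = [s for s in summaries if s.usable_for_expression]
    for s in summaries:
        if not s.usable_for_expression:
            logger.info("subfamily %s has no intergenic copies; excluded", s.subfamily)
    bed_path = out / "intergenic_copies.bed"
    with open(bed_path, "w") as fh:
        write_bed(intergenic, fh)
    summary_path = out / "subfamily_summary.tsv"
    with open(summary_path, "w") as fh:
        write_subfamily_summary_tsv(summaries, fh)
    manifest["outputs"]["annotate"] = [str(bed_path), str(summary_path)]

    grouped = group_by_subfamily(intergenic)
    by_sub = {s.subfamily: grouped[s.subfamily] for s in usable}
    lengths = feature_lengths_from_copies(by_sub)

    # ---- count / load counts -------------------------------------------
    if config.alignments is not None:
        logger.info("stage count: %d samples", len(config.alignments))
        cols: dict[str, pd.Series] = {}
        totals: dict[str, int] = {}
        assign_rows = []
        feature_order = sorted(by_sub)
        for s in samples:
            if s.sample_id not in config.alignments:
                raise ValueError(f"no alignment file for sample {s.sample_id}")
            frags = load_fragments(config.alignments[s.sample_id], config.counting)
            res = count_fragments(frags, by_sub, config.counting)
            cols[s.sample_id] = res.as_series(feature_order)
            totals[s.sample_id] = res.assigned_total
            assign_rows.append(
                (s.sample_id, len(frags), res.assigned_total, res.n_ambiguous, res.n_no_feature)
            )
        counts_df = pd.DataFrame(cols)
        assign_path = out / "assignment_summary.tsv"
        with open(assign_path, "w") as fh:
            fh.write("sample_id\tn_fragments\tassigned\tambiguous\tno_feature\n")
            for row in assign_rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        counts_path = out / "counts.tsv"
        with open(counts_path, "w") as fh:
            ExpressionMatrix(counts_df, "count").to_tsv(fh, _echo(config))
        manifest["outputs"]["count"] = [str(counts_path), str(assign_path)]
    else:
        logger.info("stage count: loading matrix %s", config.counts_path)
        counts_df = ExpressionMatrix.from_tsv(config.counts_path, "count").values
        counts_df = counts_df.loc[sorted(f for f in counts_df.index if f in by_sub)]
        totals = counts_df.sum(axis=0).to_dict()

    missing = set(counts_df.columns).symmetric_difference(conditions)
    if missing:
        raise ValueError(f"sample sheet and counts disagree on samples: {sorted(missing)}")

    # ---- fpkm -----------------------------------------------------------
    fpkm = compute_fpkm(counts_df, lengths, totals)
    fpkm_path = out / "fpkm.tsv"
    with open(fpkm_path, "w") as fh:
        fpkm.to_tsv(fh, _echo(config))
    manifest["outputs"]["fpkm"] = [str(fpkm_path)]

    # ---- differential expression ---------------------------------------
    de = call_differential(fpkm, conditions, config.thresholds)
    de_path = out / "de.tsv"
    with open(de_path, "w") as fh:
        write_de_table(de, fh, _echo(config))
    manifest["outputs"]["de"] = [str(de_path)]

    # ---- severity (when both groups are represented) --------------------
    severities = {s.sample_id: s.severity for s in samples}
    n_non_icu = sum(v == "non_icu" for v in severities.values())
    n_icu = sum(v == "icu" for v in severities.values())
    if n_non_icu >= 2 and n_icu >= 2:
        sev = severity_comparison(fpkm, severities)
        sev_path = out / "severity.tsv"
        with open(sev_path, "w") as fh:
            write_de_table(sev, fh, _echo(config))
        manifest["outputs"]["severity"] = [str(sev_path)]
    else:
        logger.info("severity contrast skipped (non_icu=%d, icu=%d)", n_non_icu, n_icu)

    # ---- age ------------------------------------------------------------
    age = compare_divergence(de, usable, alpha=config.age_alpha)
    age_path = out / "age.tsv"
    with open(age_path, "w") as fh:
        write_age_report(age, fh, _echo(config))
    long_path = out / "divergence_long.tsv"
    with open(long_path, "w") as fh:
        write_divergence_long_table(de, usable, fh)
    manifest["outputs"]["age"] = [str(age_path), str(long_path)]

    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
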