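"""End-to-end orchestration: simulate -> annotate -> count -> score ->
compare -> timescan, with a machine-readable run manifest.

A run either consumes real inputs (message corpus, report table, lexicon,
terminology) or generates a synthetic study from a ``SimConfig``; every
output table is written under the run's output directory and listed in
``manifest.json`` together with the configuration hash, seed and library
versions, so a run is re-derivable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__, annotate, dispro, evalcmp, pairs, synthetic, timescan
from .months import month_index, month_str

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one comparative signal-detection run.

    Exactly one of (*corpus_path* + *reports_path* + *lexicon_path* +
    *terminology_path*) or *sim* must be provided.
    """

    sim: synthetic.SimConfig | None = None
    corpus_path: str | None = None
    reports_path: str | None = None
    lexicon_path: str | None = None
    terminology_path: str | None = None
    decoy_fraction: float = 0.1
    misspelling_prob: float = 0.15
    as_of: str | None = None
    min_count: int = 1
    roc_score: str = "EBGM"  # forum metric swept for the ROC curve
    roc_label: str = "ebgm4"  # reference definition providing labels
    run_timescan: bool = True
    prior_mode: str = "refit"
    seed: int = 0
    outdir: str = "sdrwatch-run"

    def __post_init__(self):
        paths = (self.corpus_path, self.reports_path, self.lexicon_path, self.terminology_path)
        have_paths = any(p is not None for p in paths)
        if have_paths and self.sim is not None:
            raise ValueError("give either input paths or a SimConfig, not both")
        if have_paths and not all(p is not None for p in paths):
            raise ValueError("corpus, reports, lexicon and terminology paths all required")
        if not have_paths and self.sim is None:
            raise ValueError("either input paths or a SimConfig is required")


def _config_dict(config: RunConfig) -> dict:
    doc = dataclasses.asdict(config)
    if config.sim is not None:
        doc["sim"] = dataclasses.asdict(config.sim)
    return doc


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def demo_config(seed: int = 7, outdir: str = "sdrwatch-demo") -> RunConfig:
    """The packaged synthetic study: 2000 pairs, 50 planted signals.

    40 drugs x 50 events over three years, baseline giving ~3 units per
    pair, relative reporting rate 10 with a 6-month forum lead, so every
    stage of the pipeline has signal to find at desk scale.
    """
    sim = synthetic.SimConfig(
        n_study_drugs=3,
        n_background_drugs=37,
        n_events=50,
        start_month="2012-01",
        end_month="2014-12",
        baseline_rate=3.0 / 36.0,
        messages_per_report_ratio=1.0,
        seed=seed,
    )
    sim = synthetic.plant_signals(
        sim, n_signals=50, relative_rate=10.0, onset_month="2013-01", forum_lead_months=-6
    )
    return RunConfig(sim=sim, seed=seed, outdir=outdir)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full comparative study; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    summary: dict = {}

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, **kw)
        outputs[name.removesuffix(".csv")] = str(path)

    # -- stage: inputs -----------------------------------------------------
    if config.sim is not None:
        sim = config.sim
        stream, truth = synthetic.generate_streams(sim)
        lexicon, form_types = synthetic.build_lexicon(sim.drug_ids)
        terminology = synthetic.build_terminology(sim.pt_codes)
        render = synthetic.RenderConfig(
            decoy_fraction=config.decoy_fraction,
            misspelling_prob=config.misspelling_prob,
            seed=config.seed,
        )
        messages, truth_table = synthetic.render_forum_corpus(
            stream, lexicon, terminology, render
        )
        synthetic.write_corpus_jsonl(messages, outdir / "corpus.jsonl")
        synthetic.write_reports_csv(stream, terminology, outdir / "reports.csv")
        synthetic.write_truth_csv(truth_table, outdir / "truth.csv")
        lexicon.to_csv(outdir / "lexicon.csv", form_types)
        terminology.to_csv(outdir / "terminology.csv")
        outputs.update(
            corpus=str(outdir / "corpus.jsonl"),
            reports=str(outdir / "reports.csv"),
            truth=str(outdir / "truth.csv"),
            lexicon=str(outdir / "lexicon.csv"),
            terminology=str(outdir / "terminology.csv"),
        )
        reference_occ = synthetic.stream_to_occurrences(stream, terminology)
        reference_occ = reference_occ[reference_occ["source"] == synthetic.REFERENCE]
        ground_truth = truth
    else:
        for stage, path in (
            ("corpus", config.corpus_path),
            ("reports", config.reports_path),
            ("lexicon", config.lexicon_path),
            ("terminology", config.terminology_path),
        ):
            if not Path(path).exists():
                raise PipelineError("inputs", f"missing {stage} file: {path}")
        lexicon = annotate.DrugLexicon.from_csv(config.lexicon_path)
        terminology = annotate.Terminology.from_csv(config.terminology_path)
        messages = annotate.read_corpus_jsonl(config.corpus_path)
        reference_occ = annotate.read_reports_csv(config.reports_path, terminology)
        ground_truth = None

    # -- stage: annotate ---------------------------------------------------
    try:
        forum_occ, funnel = annotate.annotate_corpus(messages, lexicon, terminology)
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc
    logger.info("funnel: %s", funnel.as_dict())

    occurrences = pd.concat([forum_occ, reference_occ], ignore_index=True)
    save(occurrences.assign(month=occurrences["month"].map(month_str)),
         "occurrences.csv", index=False)

    # -- stage: count + score ----------------------------------------------
    as_of = month_index(config.as_of) if config.as_of else None
    try:
        forum_table = pairs.count_pairs(occurrences, as_of, source="forum")
        ref_table = pairs.count_pairs(occurrences, as_of, source="reference")
        scored_forum = dispro.score_source(forum_table)
        scored_ref = dispro.score_source(ref_table)
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc
    save(scored_forum, "panel_forum.csv")
    save(scored_ref, "panel_reference.csv")

    # -- stage: compare ----------------------------------------------------
    universe = pairs.overlap_pairs(forum_table, ref_table, config.min_count)
    summary["n_pairs_forum"] = len(forum_table)
    summary["n_pairs_reference"] = len(ref_table)
    summary["n_overlap"] = len(universe)
    if universe:
        perf = evalcmp.compare_definitions(scored_forum, scored_ref, universe)
        save(perf, "performance.csv")
        try:
            roc_res = evalcmp.roc(
                scored_forum[config.roc_score],
                scored_ref[config.roc_label],
                universe,
            )
            save(roc_res.to_frame(), "roc.csv", index=False)
            summary["auc"] = roc_res.auc
        except ValueError as exc:
            logger.warning("ROC skipped: %s", exc)
            summary["auc"] = None

    if ground_truth is not None and len(forum_table):
        gt_universe = forum_table.pairs
        labels = ground_truth.labels(gt_universe)
        if labels.any() and not labels.all():
            roc_gt = evalcmp.roc(scored_forum[config.roc_score], labels, gt_universe)
            summary["auc_vs_ground_truth"] = roc_gt.auc

    # -- stage: timescan ---------------------------------------------------
    if config.run_timescan:
        try:
            det_forum = timescan.detection_dates(
                occurrences, "forum", prior_mode=config.prior_mode
            )
            det_ref = timescan.detection_dates(
                occurrences, "reference", prior_mode=config.prior_mode
            )
            deltas = timescan.delta_records(det_forum, det_ref)
            delta_table = timescan.tabulate_delta(deltas)
        except Exception as exc:
            raise PipelineError("timescan", str(exc)) from exc
        save(det_forum, "detection_forum.csv")
        save(det_ref, "detection_reference.csv")
        save(delta_table, "delta_time.csv")
        if len(deltas):
            summary["median_delta_time"] = float(deltas["delta"].median())

    manifest = {
        "package": "sdrwatch",
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "config_hash": _config_hash(config),
        "versions": _library_versions(),
        "funnel": funnel.as_dict(),
        "outputs": dict(sorted(outputs.items())),
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    return manifest


def _library_versions() -> dict[str, str]:
    import numpy
    import scipy
    import sklearn

    return {
        "sdrwatch": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
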