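"""End-to-end orchestration: synthesis/ingest -> powerline removal ->
quality gating -> index extraction -> stability statistics -> feature
selection -> coarse-tree classification.

Every stage writes comma-delimited tables into the output directory with the
run-config hash echoed as a ``#`` header line, so tables from different runs
cannot be silently mixed. A single global seed determines every stochastic
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import selection as sel
from . import stability as stab
from .indices import SegmentIndexExtractor
from .io import read_recordings, write_cohort
from .preprocess import PreprocConfig, remove_powerline
from .quality import QualityCriteria, discard_summary, quality_vectors
from .synthetic import (
    SITES,
    ArtifactSchedule,
    DriftSpec,
    LossSpec,
    Recording,
    generate_cfae,
    generate_cohort,
    inject_artifacts,
    PRESETS,
)

log = logging.getLogger("cfaekit")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    input_mode: str = "synthetic"  # or "files"
    manifest: str | None = None
    n_par: int = 2
    n_per: int = 2
    sites: tuple[str, ...] = SITES
    seed: int = 17
    mains_freq: float = 50.0
    windows: tuple[int, ...] = (1, 2, 4)
    quality: QualityCriteria = field(default_factory=QualityCriteria)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    selection: sel.SelectionConfig = field(default_factory=sel.SelectionConfig)
    embedding_sample: int | None = 60
    max_subset_features: int = 8

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "files"):
            raise ValueError("input_mode must be 'synthetic' or 'files'")
        if self.input_mode == "files" and not self.manifest:
            raise ValueError("file mode requires a manifest path")
        for w in self.windows:
            if w not in (1, 2, 4):
                raise ValueError("windows must be drawn from {1, 2, 4}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def load_inputs(cfg: RunConfig) -> list[Recording]:
    if cfg.input_mode == "files":
        recs, problems = read_recordings(Path(cfg.manifest))
        for p in problems:
            log.warning("manifest line %d rejected: %s", p["line"], p["error"])
        if not recs:
            raise RuntimeError("no readable recordings in manifest")
        return recs
    return generate_cohort(cfg.n_par, cfg.n_per, cfg.sites, cfg.seed)


def run_pipeline(cfg: RunConfig, outdir: Path) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns a dict of the in-memory tables (quality/discards, per-segment and
    per-recording indices, stability, tests, correlation, ranking, subset and
    single-feature accuracies).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    (outdir / "run_config.json").write_text(
        json.dumps(asdict(cfg), indent=2, default=str) + "\n"
    )

    recordings = load_inputs(cfg)
    log.info("loaded %d recordings", len(recordings))

    clean = [remove_powerline(r, cfg.preproc) for r in recordings]

    qvecs = {f"{r.patient_id}/{r.site}": quality_vectors(r, cfg.quality) for r in clean}
    q1map = {k: v[1] for k, v in qvecs.items()}
    disc = discard_summary(q1map, clean)
    _write(disc, outdir / "discard_summary.csv", h)
    qrows = [
        {"recording": k, "w": w, "bits": " ".join(map(str, qv.bits))}
        for k, by_w in qvecs.items()
        for w, qv in by_w.items()
    ]
    _write(pd.DataFrame(qrows), outdir / "quality_vectors.csv", h)

    extractor = SegmentIndexExtractor(
        windows=cfg.windows, embedding_sample=cfg.embedding_sample, random_state=cfg.seed
    ).fit(clean)
    seg_table = extractor.transform(clean, qvecs)
    rec_table = extractor.recording_table(clean)
    _write(seg_table, outdir / "segment_indices.csv", h)
    _write(rec_table, outdir / "recording_indices.csv", h)

    stability = stab.stability_report(seg_table, cfg.windows)
    _write(stability, outdir / "stability_report.csv", h)
    tests = pd.concat(
        [
            stab.per_patient_tests(seg_table, index, w)
            for index in ("SE", "DET")
            for w in cfg.windows
        ],
        ignore_index=True,
    )
    _write(tests, outdir / "site_tests.csv", h)
    mw = stab.mann_whitney_sites(seg_table, rec_table, cfg.windows)
    _write(mw, outdir / "mann_whitney.csv", h)

    fms = {
        w: sel.build_feature_matrix(seg_table, rec_table, w, cfg.sites) for w in cfg.windows
    }
    corr = sel.averaged_correlation_matrix([fm.drop(columns="TYPE") for fm in fms.values()])
    _write(corr.reset_index().rename(columns={"index": "feature"}), outdir / "correlation_matrix.csv", h)

    results = {
        "discards": disc,
        "segment_indices": seg_table,
        "recording_indices": rec_table,
        "stability": stability,
        "site_tests": tests,
        "mann_whitney": mw,
        "correlation": corr,
        "feature_matrices": fms,
    }

    rankings, subsets, singles, best = [], [], [], {}
    retained = sel.correlation_filter(corr, cfg.selection)
    for w, fm in fms.items():
        y = fm["TYPE"].to_numpy()
        X = fm.drop(columns="TYPE")
        ranker = sel.GiniImportanceRanker(
            n_trees=cfg.selection.n_trees,
            importance_cutoff=cfg.selection.importance_cutoff,
            random_state=cfg.seed,
        ).fit(X[retained].fillna(X[retained].mean()), y)
        rank = ranker.ranking_table()
        rank.insert(0, "w", w)
        rankings.append(rank)
        chosen = list(rank.loc[rank["score"] > cfg.selection.importance_cutoff, "feature"])
        chosen = chosen[: cfg.max_subset_features]
        if chosen:
            Xs = X[chosen].fillna(X[chosen].mean())
            res, table = sel.subset_search(Xs, y, fm.index.to_numpy(), cfg.seed)
            table.insert(0, "w", w)
            subsets.append(table)
            best[w] = res
        # single-feature accuracies always run on the unfiltered feature set
        Xall = X.fillna(X.mean())
        single = sel.single_feature_accuracies(Xall, y, fm.index.to_numpy(), cfg.seed)
        single.insert(0, "w", w)
        singles.append(single)
    _write(pd.concat(rankings, ignore_index=True), outdir / "rf_ranking.csv", h)
    if subsets:
        _write(pd.concat(subsets, ignore_index=True), outdir / "subset_accuracies.csv", h)
    _write(pd.concat(singles, ignore_index=True), outdir / "single_feature_accuracies.csv", h)
    with open(outdir / "best_models.txt", "w") as fh:
        fh.write(f"# config_hash={h}\n")
        for w, res in best.items():
            fh.write(f"[w={w}s] features={'+'.join(res.features)} accuracy={res.accuracy:.1f}%\n")
            fh.write(res.tree_description + "\n")
    results.update({"rankings": rankings, "best_models": best, "retained": retained})
    log.info("pipeline complete: %s", outdir)
    return results


# ---------------------------------------------------------------------------
# fixtures


def drift_scenario_recording(seed: int = 0) -> Recording:
    """Drift artifact confined to the sixth second (q1(6) scenario)."""
    rec = generate_cfae(replace(PRESETS["ParAF"], seed=seed))
    sched = ArtifactSchedule(drift_intervals=(DriftSpec(start=5.0, end=6.0),))
    return inject_artifacts(rec, sched)


def loss_scenario_recording(seed: int = 0) -> Recording:
    """Signal loss over seconds 6-8 (q1(6..8) scenario)."""
    rec = generate_cfae(replace(PRESETS["ParAF"], seed=seed))
    sched = ArtifactSchedule(loss_intervals=(LossSpec(start=5.0, end=8.0),))
    return inject_artifacts(rec, sched)


def make_fixtures(seed: int, outdir: Path) -> Path:
    """Write the two worked artifact scenarios plus a 4-patient two-class
    mini-cohort; returns the mini-cohort manifest path."""
    outdir = Path(outdir)
    write_cohort([drift_scenario_recording(seed)], outdir / "drift_scenario")
    write_cohort([loss_scenario_recording(seed)], outdir / "loss_scenario")
    cohort = generate_cohort(2, 2, SITES, seed)
    return write_cohort(cohort, outdir / "mini_cohort")
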