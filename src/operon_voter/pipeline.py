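"""End-to-end pipeline: simulate -> features -> train -> predict -> vote ->
chain -> evaluate, with stage caching and a run manifest.

Each stage is keyed by a hash of its parameters and input files; a rerun
skips stages whose outputs exist under an unchanged key unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .estimators import (
    DEFAULT_SEED,
    load_suite,
    predict_suite,
    save_suite,
    train_suite,
)
from .evaluation import METRICS, bootstrap_ci, confusion_metrics, roc_auc
from .features import features_for_track
from .io import (
    read_coverage,
    read_feature_table,
    read_gff3_genes,
    read_pair_labels,
    read_predictions,
    split_pair_id,
    write_feature_table,
    write_predictions,
)
from .simulate import SimulationConfig, simulate_coverage, simulate_genome, write_simulation
from .voting import (
    DEFAULT_VOTE_THRESHOLD,
    chains_to_frame,
    replicate_consensus,
    string_operons,
    tally_votes,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "train", "predict", "vote", "chain", "evaluate")


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run.

    Defaults follow the method's stated operating point: 50-bp windows,
    mean-coverage-10 expression filter, vote threshold 3, 100-iteration 10%
    bootstrap, 10-fold CV with 10 optimization iterations.
    """

    outdir: str = "run"
    seed: int = DEFAULT_SEED
    window: int = 50
    window_offset: int = 0
    min_mean: float = 10.0
    same_strand_only: bool = False
    vote_threshold: int = DEFAULT_VOTE_THRESHOLD
    min_replicates: int = 2
    consensus: str = "unanimous"
    use_consensus: bool = False
    optimize: bool = False
    n_boot: int = 100
    bootstrap_fraction: float = 0.10
    simulation: Dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(params: dict, inputs: List[Path]) -> str:
    payload = {
        "params": params,
        "inputs": {str(p): _file_hash(p) for p in inputs if p.exists()},
        "version": __version__,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = (
            json.loads(path.read_text()) if path.exists() else {"stages": {}}
        )

    def fresh(self, stage: str, key: str, outputs: List[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        return (
            rec is not None
            and rec.get("key") == key
            and all(p.exists() for p in outputs)
        )

    def record(self, stage: str, key: str, outputs: List[Path], extra: dict) -> None:
        self.data["stages"][stage] = {
            "key": key,
            "outputs": [str(p) for p in outputs],
            **extra,
        }
        self.data["version"] = __version__
        self.path.write_text(json.dumps(self.data, indent=2) + "\n")


def run_pipeline(config: RunConfig, force: bool = False) -> Path:
    """Execute all stages in order; returns the output directory.

    Stages whose outputs exist under an unchanged key are skipped unless
    ``force``. Any stage error aborts with the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    simdir = out / "sim"
    features_path = out / "features.tsv"
    model_dir = out / "model"
    preds_path = out / "predictions.tsv"
    calls_path = out / "calls.tsv"
    operons_path = out / "operons.tsv"
    report_path = out / "report.json"

    sim_cfg = SimulationConfig(**config.simulation)
    sim_cfg.seed = config.seed

    def run_stage(stage, params, inputs, outputs, fn):
        key = _stage_key(params, inputs)
        if not force and manifest.fresh(stage, key, outputs):
            logger.info("stage %s: up to date, skipped", stage)
            return
        logger.info("stage %s: running", stage)
        try:
            extra = fn() or {}
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed on inputs {[str(i) for i in inputs]}: {exc}"
            ) from exc
        manifest.record(stage, key, outputs, extra)

    # -- simulate ----------------------------------------------------------
    cov_paths = [
        simdir / f"coverage_rep{r + 1}.txt" for r in range(sim_cfg.n_replicates)
    ]
    gff_path, labels_path = simdir / "genes.gff3", simdir / "labels.tsv"

    def do_simulate():
        truth = simulate_genome(sim_cfg)
        tracks = simulate_coverage(truth, sim_cfg)
        simdir.mkdir(parents=True, exist_ok=True)
        from .io import write_coverage, write_gff3_genes, write_pair_labels

        write_gff3_genes(truth.genes, gff_path)
        for track, p in zip(tracks, cov_paths):
            write_coverage(track, p)
        write_pair_labels(truth.labels, labels_path)
        return {"n_genes": len(truth.genes)}

    run_stage(
        "simulate",
        dataclasses.asdict(sim_cfg),
        [],
        [gff_path, labels_path, *cov_paths],
        do_simulate,
    )

    # -- features ----------------------------------------------------------
    def do_features():
        genes = read_gff3_genes(gff_path)
        lmap = {
            (l.geneA_id, l.geneB_id): l.label for l in read_pair_labels(labels_path)
        }
        frames = []
        for i, p in enumerate(cov_paths):
            track = read_coverage(p, f"rep{i + 1}")
            frames.append(
                features_for_track(
                    genes,
                    track,
                    min_mean=config.min_mean,
                    same_strand_only=config.same_strand_only,
                    window=config.window,
                    offset=config.window_offset,
                    labels=lmap,
                )
            )
        df = pd.concat(frames, ignore_index=True)
        write_feature_table(df, features_path)
        return {"n_rows": len(df)}

    feat_params = {
        k: getattr(config, k)
        for k in ("window", "window_offset", "min_mean", "same_strand_only")
    }
    run_stage(
        "features",
        feat_params,
        [gff_path, labels_path, *cov_paths],
        [features_path],
        do_features,
    )

    # -- train -------------------------------------------------------------
    def do_train():
        df = read_feature_table(features_path)
        suite = train_suite(df, optimize=config.optimize, seed=config.seed)
        save_suite(suite, model_dir)

    run_stage(
        "train",
        {"optimize": config.optimize, "seed": config.seed},
        [features_path],
        [model_dir / "suite.json"],
        do_train,
    )

    # -- predict -----------------------------------------------------------
    def do_predict():
        suite = load_suite(model_dir)
        df = read_feature_table(features_path)
        preds = predict_suite(suite, df)
        write_predictions(preds, preds_path)

    run_stage(
        "predict",
        {},
        [features_path, model_dir / "suite.json"],
        [preds_path],
        do_predict,
    )

    # -- vote --------------------------------------------------------------
    def do_vote():
        preds = read_predictions(preds_path)
        if config.use_consensus:
            calls = replicate_consensus(
                preds, min_replicates=config.min_replicates, mode=config.consensus
            )
        else:
            calls = tally_votes(preds)
        calls.to_csv(calls_path, sep="\t", index=False, lineterminator="\n")

    vote_params = {
        k: getattr(config, k)
        for k in ("use_consensus", "min_replicates", "consensus")
    }
    run_stage("vote", vote_params, [preds_path], [calls_path], do_vote)

    # -- chain -------------------------------------------------------------
    def do_chain():
        calls = pd.read_csv(calls_path, sep="\t", dtype={"pair_id": str})
        genes = read_gff3_genes(gff_path)
        chains = string_operons(calls, genes, threshold=config.vote_threshold)
        chains_to_frame(chains).to_csv(
            operons_path, sep="\t", index=False, lineterminator="\n"
        )

    run_stage(
        "chain",
        {"vote_threshold": config.vote_threshold},
        [calls_path, gff_path],
        [operons_path],
        do_chain,
    )

    # -- evaluate ----------------------------------------------------------
    def do_evaluate():
        calls = pd.read_csv(calls_path, sep="\t", dtype={"pair_id": str})
        lmap = {}
        from .io import pair_id as make_pid

        for l in read_pair_labels(labels_path):
            lmap[make_pid(l.geneA_id, l.geneB_id)] = l.label
            lmap[make_pid(l.geneB_id, l.geneA_id)] = l.label
        # score per (pair, sample) row; each row inherits its pair's label
        scored = calls[calls["pair_id"].isin(lmap)].reset_index(drop=True)
        keys = [
            f"{pid}#{i}" for i, pid in enumerate(scored["pair_id"])
        ]
        ensemble = dict(zip(keys, scored[f"call_at_{config.vote_threshold}"]))
        row_labels = {k: lmap[p] for k, p in zip(keys, scored["pair_id"])}
        report_ens = confusion_metrics(ensemble, row_labels)
        boot = {
            name: bootstrap_ci(
                METRICS[name],
                ensemble,
                row_labels,
                n_boot=config.n_boot,
                fraction=config.bootstrap_fraction,
                seed=config.seed,
            )
            for name in ("recall", "specificity")
        }
        votes = scored["votes"].to_numpy(float)
        y = scored["pair_id"].map(lmap).to_numpy(int)
        _points, auc_votes = roc_auc(votes, y)
        report = {
            "vote_threshold": config.vote_threshold,
            "n_pairs": report_ens.n_pairs,
            "recall": report_ens.recall,
            "specificity": report_ens.specificity,
            "bootstrap": boot,
            "auc_votes": auc_votes,
        }
        report_path.write_text(json.dumps(report, indent=2) + "\n")

    eval_params = {
        k: getattr(config, k)
        for k in ("vote_threshold", "n_boot", "bootstrap_fraction")
    }
    run_stage(
        "evaluate", eval_params, [calls_path, labels_path], [report_path], do_evaluate
    )
    return out
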