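"""Multi-seed benchmark orchestration: replicate runs -> mean +- sd ->
pairwise significance tests -> leaderboard files.

For every (model, seed) the flow is: seeded split -> seeded build -> train
-> evaluate on the held-out test part.  Replicates are aggregated per model
and metric, and each model pair is compared with the two-sample t-test on
the task's headline metric.  Every artifact carries the config hash and
seed list for provenance, and a failing model never blocks the others.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Record, TaskSpec, TrainConfig, make_split
from .evaluation import compare_methods, compute_metrics, primary_metric
from .training import predict, train
from .zoo import ModelConfig, build_model, default_config
from .zoo.embedding import EmbeddingProvider

DEFAULT_SEEDS = (0, 1, 2)


@dataclass
class RunConfig:
    """One benchmark run: a task, its records, the competing models, and
    the replicate seeds (distinct by contract)."""

    task_spec: TaskSpec
    architectures: Sequence[str]
    seeds: Sequence[int] = DEFAULT_SEEDS
    train_config: Optional[TrainConfig] = None
    model_configs: Dict[str, ModelConfig] = field(default_factory=dict)
    split_ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    alpha: float = 0.05
    out_dir: Optional[str] = None
    provider: Optional[EmbeddingProvider] = None

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be distinct")

    def config_hash(self) -> str:
        payload = {
            "task": self.task_spec.name,
            "archs": list(self.architectures),
            "seeds": list(self.seeds),
            "ratios": list(self.split_ratios),
            "alpha": self.alpha,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class BenchmarkResult:
    leaderboard: pd.DataFrame
    comparisons: pd.DataFrame
    per_seed: pd.DataFrame
    failures: Dict[str, str]


def run_single(architecture: str, records: Sequence[Record],
               run_config: RunConfig, seed: int) -> Dict[str, float]:
    """Train one architecture with one seed and score the test part."""
    ts = run_config.task_spec
    split = make_split(records, run_config.split_ratios, seed=seed)
    cfg = run_config.model_configs.get(architecture,
                                       default_config(architecture))
    model = build_model(architecture, ts, cfg, seed=seed,
                        provider=run_config.provider)
    tc = run_config.train_config or TrainConfig(
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs)
    tc = TrainConfig(learning_rate=tc.learning_rate, batch_size=tc.batch_size,
                     max_epochs=tc.max_epochs, seed=seed, dropout=tc.dropout)
    model, history = train(model, split, ts, tc)
    preds = predict(model, split.test, ts, batch_size=tc.batch_size)
    report = compute_metrics(ts, preds, split.test)
    out = dict(report.values)
    out["final_train_loss"] = history.train_loss[-1] if len(history) else float("nan")
    return out


def run_benchmark(records: Sequence[Record], run_config: RunConfig) -> BenchmarkResult:
    """Execute the full replicate protocol; deterministic given the seeds."""
    ts = run_config.task_spec
    metric = primary_metric(ts)
    rows: List[dict] = []
    failures: Dict[str, str] = {}
    chash = run_config.config_hash()
    for arch in run_config.architectures:
        for seed in run_config.seeds:
            try:
                values = run_single(arch, records, run_config, seed)
            except Exception:  # noqa: BLE001 - isolation contract
                failures[arch] = traceback.format_exc()
                break
            rows.append({"model": arch, "seed": seed, "config_hash": chash,
                         **values})
    per_seed = pd.DataFrame(rows)
    lb_rows = []
    for arch in run_config.architectures:
        sub = per_seed[per_seed["model"] == arch] if len(per_seed) else per_seed
        if len(per_seed) == 0 or len(sub) == 0:
            continue
        entry = {"model": arch, "n_seeds": len(sub), "config_hash": chash}
        for col in sub.columns:
            if col in ("model", "seed", "config_hash"):
                continue
            entry[f"{col}_mean"] = float(sub[col].mean())
            entry[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
        lb_rows.append(entry)
    leaderboard = pd.DataFrame(lb_rows)
    if len(leaderboard):
        ranks = leaderboard[f"{metric}_mean"].rank(
            ascending=metric in ("mse", "mae"), method="min").astype(int)
        leaderboard.insert(1, "rank", ranks)
        leaderboard = leaderboard.sort_values("rank", kind="mergesort") \
            .reset_index(drop=True)
    cmp_rows = []
    ok_models = list(leaderboard["model"]) if len(leaderboard) else []
    for i, a in enumerate(ok_models):
        for b in ok_models[i + 1:]:
            va = per_seed.loc[per_seed["model"] == a, metric].tolist()
            vb = per_seed.loc[per_seed["model"] == b, metric].tolist()
            if len(va) < 2 or len(vb) < 2:
                continue
            res = compare_methods(va, vb, alpha=run_config.alpha,
                                  name_a=a, name_b=b)
            cmp_rows.append({"model_a": a, "model_b": b, "metric": metric,
                             "t_statistic": res.t_statistic,
                             "p_value": res.p_value, "alpha": res.alpha,
                             "verdict": res.verdict, "config_hash": chash})
    comparisons = pd.DataFrame(cmp_rows)
    if run_config.out_dir:
        out = Path(run_config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        leaderboard.to_csv(out / "leaderboard.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        per_seed.to_csv(out / "per_seed.csv", index=False)
        if failures:
            (out / "failures.json").write_text(json.dumps(failures, indent=2))
    return BenchmarkResult(leaderboard, comparisons, per_seed, failures)
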