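"""Simulation protocols: trial/block orchestration and run aggregation.

Four experiments probe the models' valence prediction:

* capacity: error vs. number of stored patterns under full cues,
* partial cue: completion and prediction when 1-7 of 8 cue cells are
  silenced,
* thresholds: interplay of the exteroceptive (e) and valence (v) novelty
  thresholds when valences change after training,
* reversal: the 12-pattern cue/context discrimination-reversal task.

Each experiment runs independent replicates (default 20) from named RNG
substreams of one master seed, returns tidy per-run/per-block records as a
:class:`pandas.DataFrame`, and per-condition means carry symmetric 95%
t-based confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import StandardAutoassociativeModel, simple_hetero_model
from .hippocampus import HippocampalModel, ModelConfig, TrialRecord
from .patterns import (
    BinaryPattern,
    StimulusPair,
    degrade_cue,
    generate_reversal_task,
    generate_stimulus_set,
    make_valence,
)

__all__ = [
    "MODEL_KINDS",
    "make_model",
    "BlockResult",
    "Summary",
    "run_block",
    "capacity_experiment",
    "partial_cue_experiment",
    "threshold_experiment",
    "reversal_experiment",
    "summarize_ci",
    "summarize",
]

MODEL_KINDS = ("standard", "simple_hetero", "proposed")


def make_model(kind: str, config: ModelConfig | None = None, **kwargs):
    """Instantiate a model by kind: standard / simple_hetero / proposed."""
    if config is None:
        config = ModelConfig(**kwargs)
    if kind == "standard":
        return StandardAutoassociativeModel(config)
    if kind == "simple_hetero":
        return simple_hetero_model(config)
    if kind == "proposed":
        return HippocampalModel(config)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


@dataclass(frozen=True)
class BlockResult:
    """Aggregated outcome of one pass through a stimulus set."""

    block: int
    records: tuple[TrialRecord, ...]
    error_pct: float
    completion_error_pct: float
    mean_completion_hd: float
    interference_count: int
    groups_in_use: int


@dataclass(frozen=True)
class Summary:
    """Mean with symmetric 95% confidence interval over simulation runs."""

    mean: float
    ci95_low: float
    ci95_high: float
    n_runs: int


def summarize_ci(values: Iterable[float], confidence: float = 0.95) -> Summary:
    """t-based confidence interval; a single value yields a point interval."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty set of values")
    mean = float(vals.mean())
    if vals.size == 1:
        return Summary(mean, mean, mean, 1)
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size))
    half = float(stats.t.ppf(0.5 + confidence / 2, vals.size - 1) * sem)
    return Summary(mean, mean - half, mean + half, int(vals.size))


def summarize(
    df: pd.DataFrame, by: Sequence[str], value: str, confidence: float = 0.95
) -> pd.DataFrame:
    """Per-condition mean and CI of one tidy column, over runs."""

    def agg(group: pd.Series) -> pd.Series:
        s = summarize_ci(group, confidence)
        return pd.Series(
            {
                "mean": s.mean,
                "ci95_low": s.ci95_low,
                "ci95_high": s.ci95_high,
                "n_runs": s.n_runs,
            }
        )

    out = df.groupby(list(by))[value].apply(agg).unstack().reset_index()
    out["n_runs"] = out["n_runs"].astype(int)
    return out


def _aggregate(
    block: int, records: Sequence[TrialRecord], model
) -> BlockResult:
    n = len(records)
    return BlockResult(
        block=block,
        records=tuple(records),
        error_pct=100.0 * sum(r.prediction_error for r in records) / n,
        completion_error_pct=100.0 * sum(r.completion_error for r in records) / n,
        mean_completion_hd=sum(r.completion_hd for r in records) / n,
        interference_count=sum(r.interference_detected for r in records),
        groups_in_use=model.groups_in_use(),
    )


def run_block(
    model,
    stimuli: Sequence[StimulusPair],
    rng: np.random.Generator | None = None,
    learning_enabled: bool = True,
    cues: Sequence[BinaryPattern] | None = None,
    block: int = 0,
) -> BlockResult:
    """One pass through the stimuli, randomly reordered when an rng is given.

    ``cues``, aligned with ``stimuli``, substitutes degraded retrieval
    cues while errors stay measured against the intact patterns.
    """
    if not stimuli:
        raise ValueError("stimulus set must be non-empty")
    order = np.arange(len(stimuli))
    if rng is not None:
        order = rng.permutation(order)
    records = []
    for i in order:
        pair = stimuli[i]
        cue = cues[i] if cues is not None else None
        records.append(
            model.process_trial(
                pair.extero, pair.intero, learning_enabled=learning_enabled, cue=cue
            )
        )
    return _aggregate(block, records, model)


def _run_streams(seed: int, run: int, names: Sequence[str]):
    """Named substreams for one replicate, independent of model kind."""
    children = np.random.SeedSequence([int(seed), int(run)]).spawn(len(names))
    return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}


def _block_row(base: dict, phase: str, res: BlockResult) -> dict:
    return {
        **base,
        "phase": phase,
        "block": res.block,
        "error_pct": res.error_pct,
        "completion_error_pct": res.completion_error_pct,
        "mean_completion_hd": res.mean_completion_hd,
        "interference_count": res.interference_count,
        "groups_in_use": res.groups_in_use,
    }


def capacity_experiment(
    model_kinds: Sequence[str] = MODEL_KINDS,
    N_grid: Sequence[int] = tuple(range(10, 101, 10)),
    blocks: int = 1,
    runs: int = 20,
    seed: int = 0,
    n: int = 300,
    k: int = 8,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Valence prediction error vs. number of stored patterns (full cues).

    Per replicate and N: generate N stimuli, train for ``blocks`` passes,
    and measure a learning-disabled test block after every training pass.
    Rows carry phase "train" (errors scored on the training trials
    themselves) and "test".
    """
    cfg = config or ModelConfig(n=n)
    rows = []
    for run in range(runs):
        for N in N_grid:
            streams = _run_streams(seed, run, ["stimuli", "shuffle"])
            stimuli = generate_stimulus_set(N, cfg.n, k, streams["stimuli"])
            for kind in model_kinds:
                model = make_model(kind, cfg)
                base = {"run": run, "model": kind, "N": N, "seed": seed}
                for b in range(1, blocks + 1):
                    train = run_block(
                        model, stimuli, streams["shuffle"], True, block=b
                    )
                    rows.append(_block_row(base, "train", train))
                    test = run_block(model, stimuli, None, False, block=b)
                    rows.append(_block_row(base, "test", test))
    return pd.DataFrame(rows)


def partial_cue_experiment(
    model_kinds: Sequence[str] = MODEL_KINDS,
    N: int = 100,
    blocks: int = 1,
    deletion_levels: Sequence[int] = tuple(range(1, 8)),
    runs: int = 20,
    seed: int = 0,
    n: int = 300,
    k: int = 8,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Recall from degraded cues after training on ``N`` stimuli.

    For each deletion level d, every stored pattern is cued with d of its
    active cells silenced; completion and prediction errors are measured
    against the intact patterns, learning disabled.  The same degraded
    cues are shown to every model kind for a paired comparison.
    """
    cfg = config or ModelConfig(n=n)
    rows = []
    for run in range(runs):
        streams = _run_streams(seed, run, ["stimuli", "shuffle", "degrade"])
        stimuli = generate_stimulus_set(N, cfg.n, k, streams["stimuli"])
        cue_sets = {
            d: [degrade_cue(p.extero, d, streams["degrade"]) for p in stimuli]
            for d in deletion_levels
        }
        for kind in model_kinds:
            model = make_model(kind, cfg)
            for b in range(1, blocks + 1):
                run_block(model, stimuli, streams["shuffle"], True, block=b)
            base = {"run": run, "model": kind, "N": N, "seed": seed}
            for d in deletion_levels:
                res = run_block(
                    model, stimuli, None, False, cues=cue_sets[d], block=blocks
                )
                rows.append({**_block_row(base, "test", res), "deletions": d})
    return pd.DataFrame(rows)


def threshold_experiment(
    threshold_pairs: Sequence[tuple[int, int]] = ((0, 0), (2, 2), (2, 0)),
    N: int = 10,
    runs: int = 20,
    seed: int = 0,
    n: int = 300,
    k: int = 8,
    n_assoc_groups: int = 4,
) -> pd.DataFrame:
    """Novelty-threshold interplay when trained valences change.

    Per replicate: train the proposed model on ``N`` neutral stimuli, then
    reassign each stimulus a uniformly drawn valence (so about 1/3 keep
    neutral) and retrain one block under the configured (e, v) thresholds;
    finally test.  Alongside error percentages, the recall-phase Hamming
    mismatches are recorded separately for exteroception and valence and
    overall, before and after the change.
    """
    rows = []
    for run in range(runs):
        streams = _run_streams(seed, run, ["stimuli", "valences", "shuffle"])
        extero = [
            p.extero
            for p in generate_stimulus_set(N, n, k, streams["stimuli"])
        ]
        new_labels = [
            ("positive", "negative", "neutral")[streams["valences"].integers(0, 3)]
            for _ in range(N)
        ]
        neutral = [StimulusPair.make(e, "neutral") for e in extero]
        changed = [
            StimulusPair.make(e, lab) for e, lab in zip(extero, new_labels)
        ]
        for e_thr, v_thr in threshold_pairs:
            cfg = ModelConfig(
                n=n, n_assoc_groups=n_assoc_groups, e=e_thr, v=v_thr
            )
            model = HippocampalModel(cfg)
            base = {"run": run, "e": e_thr, "v": v_thr, "seed": seed}
            run_block(model, neutral, streams["shuffle"], True, block=1)
            pre = run_block(model, neutral, None, False, block=1)
            retrain = run_block(model, changed, streams["shuffle"], True, block=2)
            post = run_block(model, changed, None, False, block=2)
            for phase, res in [
                ("pre_change_test", pre),
                ("retrain", retrain),
                ("post_change_test", post),
            ]:
                recs = res.records
                rows.append(
                    {
                        **_block_row(base, phase, res),
                        "mean_hd_extero": np.mean(
                            [r.completion_hd for r in recs]
                        ),
                        "mean_hd_valence": np.mean(
                            [r.prediction_hd for r in recs]
                        ),
                        "mean_hd_overall": np.mean(
                            [r.completion_hd + r.prediction_hd for r in recs]
                        ),
                    }
                )
    return pd.DataFrame(rows)


def reversal_experiment(
    model_kinds: Sequence[str] = MODEL_KINDS,
    acquisition_blocks: int = 4,
    reversal_blocks: int = 4,
    runs: int = 20,
    seed: int = 0,
    n: int = 300,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """The cue/context discrimination-reversal task.

    Phase 1 (acquisition): four shuffled passes over the four original
    stimuli.  Phase 2 (retention and reversal): four shuffled passes over
    all 12 stimuli; errors are additionally split into old (original) and
    new (reversed) patterns.  Errors are scored on the training trials
    themselves, as the task is a continual-learning protocol.
    """
    cfg = config or ModelConfig(n=n)
    rows = []
    for run in range(runs):
        streams = _run_streams(seed, run, ["task", "shuffle"])
        task = generate_reversal_task(cfg.n, streams["task"])
        old = set(id(p) for p in task.old_patterns)
        for kind in model_kinds:
            model = make_model(kind, cfg)
            base = {"run": run, "model": kind, "seed": seed}
            for b in range(1, acquisition_blocks + 1):
                res = run_block(
                    model, task.group1, streams["shuffle"], True, block=b
                )
                rows.append(
                    {**_block_row(base, "acquisition", res), "subset": "all"}
                )
            for b in range(1, reversal_blocks + 1):
                stimuli = list(task.all_patterns)
                order = streams["shuffle"].permutation(len(stimuli))
                records, subsets = [], []
                for i in order:
                    pair = stimuli[i]
                    records.append(
                        model.process_trial(pair.extero, pair.intero, True)
                    )
                    subsets.append("old" if id(pair) in old else "new")
                res = _aggregate(b, records, model)
                rows.append(
                    {**_block_row(base, "reversal", res), "subset": "all"}
                )
                for name in ("old", "new"):
                    sub = [
                        r for r, s in zip(records, subsets) if s == name
                    ]
                    rows.append(
                        {
                            **_block_row(base, "reversal", _aggregate(b, sub, model)),
                            "subset": name,
                        }
                    )
    return pd.DataFrame(rows)
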