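"""End-to-end orchestration: simulate -> segment -> balance -> split ->
train -> predict -> evaluate, as reproducible in-memory runs or staged
on-disk artifacts.

The experiment protocol mirrors validation practice for animal-borne
detectors: individuals (never windows) are split into train/validation/test
groups; both detectors are trained on the training individuals and
evaluated on per-dive counts of the held-out test individuals, including
individuals with zero annotated captures.  The split/train/evaluate cycle
is repeated with fresh random splits and the split with the best count
regression (slope and fit closest to 1 for both models) is retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dives import Dive, DiveConfig, detect_dives, dive_table, flag_foraging
from .evaluate import EvalConfig, EvalReport, evaluate_predictions
from .features import (BalanceConfig, balance_summary, balancing_mask,
                       normalize_axes, pitch_deg, static_acceleration)
from .io import SyncedSeries, merge_streams, read_accel, read_labels, read_tdr
from .models import (CnnConfig, TrainedModel, VnetConfig, config_hash,
                     predict_points, train_cnn, train_vnet)
from .sampling import (SamplerConfig, SplitResult, WindowBatch,
                       segment_cnn_windows, split_individuals, split_manifest)
from .simulate import Cohort, SimConfig, SimTrip, simulate_cohort, write_trip

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "train_cnn", "train_vnet", "predict",
          "evaluate")
_UPSTREAM = {"simulate": None, "segment": "simulate",
             "train_cnn": "segment", "train_vnet": "segment",
             "predict": "train_vnet", "evaluate": "predict"}


@dataclass
class RunConfig:
    """Composite configuration of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    dive: DiveConfig = field(default_factory=DiveConfig)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    vnet: VnetConfig = field(default_factory=VnetConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    run_id: str = "run0"
    output_dir: str = "runs"
    seed: int = 0

    def hash(self) -> str:
        return config_hash(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        sub = {"sim": SimConfig, "dive": DiveConfig, "balance": BalanceConfig,
               "sampler": SamplerConfig, "cnn": CnnConfig, "vnet": VnetConfig,
               "eval": EvalConfig}
        for key, val in raw.items():
            if key in sub:
                val = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in (val or {}).items()}
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class ProcessedIndividual:
    """One individual's series with everything the detectors need."""

    individual_id: str
    series: SyncedSeries
    dives: list[Dive]
    mask: np.ndarray
    norm: np.ndarray
    pce_count: int
    truth_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def prepare_individual(series: SyncedSeries, cfg: RunConfig,
                       truth_indices: np.ndarray | None = None
                       ) -> ProcessedIndividual:
    """Segment dives, compute the balancing mask and normalized axes."""
    dives = detect_dives(series, cfg.dive)
    labels = series.label if series.label is not None \
        else np.zeros(len(series), dtype=np.uint8)
    for d in dives:
        d.foraging = flag_foraging(d, labels)
    xs, ys, zs = static_acceleration(series, cfg.balance.smoothing_window_s)
    pitch = pitch_deg(xs, ys, zs)
    mask = balancing_mask(series, dives, cfg.balance, pitch=pitch)
    return ProcessedIndividual(
        individual_id=series.individual_id,
        series=series,
        dives=dives,
        mask=mask,
        norm=normalize_axes(series),
        pce_count=int(labels.sum()) // 8,
        truth_indices=(np.empty(0, dtype=int) if truth_indices is None
                       else np.asarray(truth_indices, dtype=int)),
    )


def prepare_cohort(cohort: Cohort, cfg: RunConfig) -> list[ProcessedIndividual]:
    out = []
    for trip in cohort:
        truth = np.array([e.sample_index for e in trip.events], dtype=int)
        out.append(prepare_individual(trip.series, cfg, truth_indices=truth))
    return out


@dataclass
class ExperimentResult:
    split: SplitResult
    cnn: TrainedModel
    vnet: TrainedModel
    reports: dict[str, EvalReport]
    balance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"split": {
            "train": self.split.train_ids, "val": self.split.val_ids,
            "test": self.split.test_ids, "zero_pce": self.split.zero_pce_ids,
            "shares": list(self.split.shares)}}
        for kind, rep in self.reports.items():
            out[kind] = {**rep.regression, **{
                k: rep.dive_metrics.get(k)
                for k in ("accuracy", "sensitivity", "false_positive_rate")}}
        out["balance"] = self.balance
        return out


def _pool(inds: list[ProcessedIndividual]) -> list[tuple[str, np.ndarray, np.ndarray]]:
    return [(p.individual_id, p.norm,
             p.series.label if p.series.label is not None
             else np.zeros(len(p.series), dtype=np.uint8)) for p in inds]


def _cnn_windows(inds: list[ProcessedIndividual],
                 cfg: RunConfig) -> WindowBatch:
    parts = [segment_cnn_windows(
        p.norm, p.series.label, p.mask, p.dives, cfg.sampler,
        individual_id=p.individual_id) for p in inds]
    parts = [b for b in parts if len(b)]
    if not parts:
        return WindowBatch(data=np.empty((0, cfg.sampler.w_cnn, 3)),
                           labels=np.empty(0, dtype=np.int64))
    return WindowBatch(
        data=np.concatenate([b.data for b in parts]),
        labels=np.concatenate([b.labels for b in parts]),
        provenance=[pv for b in parts for pv in b.provenance])


def run_experiment(processed: list[ProcessedIndividual], cfg: RunConfig,
                   split_seed: int, model_seed: int) -> ExperimentResult:
    """One split/train/predict/evaluate cycle over a processed cohort."""
    counts = {p.individual_id: p.pce_count for p in processed}
    split = split_individuals(
        counts, cfg.sampler, np.random.default_rng(
            np.random.SeedSequence([split_seed & 0x7FFFFFFF, 21])))
    by_id = {p.individual_id: p for p in processed}
    train_inds = [by_id[i] for i in split.train_ids]
    val_inds = [by_id[i] for i in split.val_ids]
    test_inds = [by_id[i] for i in split.test_ids + split.zero_pce_ids]

    mask_all = np.concatenate([p.mask for p in train_inds + val_inds])
    label_all = np.concatenate([p.series.label for p in train_inds + val_inds])
    balance = balance_summary(mask_all, label_all)
    logger.info("balancing filter: retention %.3f, reduction %.3f",
                balance["retention"], balance["reduction"])

    cnn = train_cnn(_cnn_windows(train_inds, cfg),
                    _cnn_windows(val_inds, cfg), cfg.cnn, seed=model_seed)
    vnet = train_vnet(_pool(train_inds), _pool(val_inds), cfg.vnet,
                      cfg.sampler, seed=model_seed)

    reports = {}
    for kind, model in (("cnn", cnn), ("vnet", vnet)):
        per_ind = []
        for p in test_inds:
            pred = predict_points(model, p.norm, p.series.depth, p.dives,
                                  cfg.sampler, cfg.dive.dive_threshold_m)
            per_ind.append({
                "individual_id": p.individual_id,
                "labels": p.series.label,
                "pred": pred,
                "dives": p.dives,
                "depth": p.series.depth,
                "truth_indices": p.truth_indices,
            })
        reports[kind] = evaluate_predictions(kind, per_ind)
    return ExperimentResult(split=split, cnn=cnn, vnet=vnet, reports=reports,
                            balance=balance)


@dataclass
class RepeatOutcome:
    best: ExperimentResult | None
    best_index: int | None
    summaries: list[dict]


def repeat_experiment(processed: list[ProcessedIndividual], cfg: RunConfig,
                      n_repeats: int = 10) -> RepeatOutcome:
    """Repeat the random split + training cycle and keep the best split.

    Best = the repeat minimizing |slope - 1| summed over both detectors,
    ties broken by the higher mean R^2.  A repeat that fails is recorded
    and the remaining repeats continue.  Fixed master seed -> identical
    selection.
    """
    results: list[tuple[int, ExperimentResult, float, float]] = []
    summaries: list[dict] = []
    for r in range(n_repeats):
        try:
            res = run_experiment(processed, cfg,
                                 split_seed=cfg.seed + 1000 + r,
                                 model_seed=cfg.seed + 2000 + r)
            # a degenerate regression (e.g. a model predicting nothing, so
            # R^2 is undefined) scores as badly as possible, not as NaN
            score = float(np.nan_to_num(
                abs(res.reports["cnn"].regression.get("slope", np.inf) - 1)
                + abs(res.reports["vnet"].regression.get("slope", np.inf) - 1),
                nan=np.inf))
            mean_r2 = float(np.nan_to_num(np.mean(
                [res.reports[k].regression.get("r_squared", 0.0)
                 for k in ("cnn", "vnet")]), nan=0.0))
            results.append((r, res, float(score), float(mean_r2)))
            summaries.append({"repeat": r, "score": float(score),
                              "mean_r_squared": float(mean_r2),
                              **res.summary()})
        except Exception as exc:  # keep going: one bad split must not kill the run
            logger.warning("repeat %d failed: %s", r, exc)
            summaries.append({"repeat": r, "error": str(exc)})
    if not results:
        return RepeatOutcome(best=None, best_index=None, summaries=summaries)
    best = min(results, key=lambda t: (round(t[2], 12), -round(t[3], 12)))
    return RepeatOutcome(best=best[1], best_index=best[0], summaries=summaries)


def reference_config(seed: int = 0) -> RunConfig:
    """The package's reference experiment: a 24-individual synthetic cohort
    of 20-minute trips (roughly 11 train / 4 validation / 7 test individuals
    after the event-share split, plus non-foragers), with V-Net epochs of
    8000 training / 2400 validation windows.  Sized to train both detectors
    end-to-end in a few minutes on one CPU while leaving dozens of test
    dives for the count regression.
    """
    seed = int(seed) & 0x7FFFFFFF
    return RunConfig(
        sim=SimConfig(n_individuals=24, trip_duration_s=1200.0, seed=seed),
        sampler=SamplerConfig(epoch_windows_train=8000,
                              epoch_windows_val=2400),
        run_id=f"reference-{seed}",
        seed=seed,
    )


# --------------------------------------------------------------------------
# Staged on-disk execution


class StageError(RuntimeError):
    pass


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    return Path(cfg.output_dir) / cfg.run_id / stage


def _manifest_path(cfg: RunConfig, stage: str) -> Path:
    return _stage_dir(cfg, stage) / "manifest.json"


def _write_manifest(cfg: RunConfig, stage: str, artifacts: list[str]) -> None:
    _manifest_path(cfg, stage).write_text(json.dumps({
        "stage": stage, "run_id": cfg.run_id, "config_hash": cfg.hash(),
        "artifacts": artifacts}, indent=2))


def _check_upstream(cfg: RunConfig, stage: str) -> None:
    up = _UPSTREAM[stage]
    if up is None:
        return
    mp = _manifest_path(cfg, up)
    if not mp.exists():
        raise StageError(
            f"stage {stage!r} needs artifacts of stage {up!r}; "
            f"run {up!r} first")
    manifest = json.loads(mp.read_text())
    if manifest.get("config_hash") != cfg.hash():
        raise StageError(
            f"config hash mismatch for upstream stage {up!r}: artifacts were "
            "produced with a different configuration; refusing to continue")


def run_stage(stage: str, cfg: RunConfig) -> Path:
    """Execute one pipeline stage idempotently.

    A completed stage (manifest present with a matching config hash) is a
    no-op; a manifest with a different hash triggers a refusal; a missing
    upstream stage raises naming the stage to run first.
    """
    if stage not in STAGES:
        raise StageError(f"unknown stage {stage!r}; stages: {STAGES}")
    sdir = _stage_dir(cfg, stage)
    mp = _manifest_path(cfg, stage)
    if mp.exists():
        manifest = json.loads(mp.read_text())
        if manifest.get("config_hash") == cfg.hash():
            logger.info("stage %s already complete; skipping", stage)
            return sdir
        raise StageError(
            f"stage {stage!r} has artifacts from a different configuration "
            f"(hash {manifest.get('config_hash')} != {cfg.hash()}); "
            "remove them or change run_id")
    _check_upstream(cfg, stage)
    sdir.mkdir(parents=True, exist_ok=True)
    artifacts = _STAGE_FNS[stage](cfg, sdir)
    _write_manifest(cfg, stage, artifacts)
    return sdir


def _load_cohort_from_stage(cfg: RunConfig) -> list[ProcessedIndividual]:
    sim_dir = _stage_dir(cfg, "simulate")
    processed = []
    for accel_path in sorted(sim_dir.glob("*_accel.csv")):
        ind = accel_path.name.replace("_accel.csv", "")
        accel = read_accel(accel_path, individual_id=ind)
        tdr = read_tdr(sim_dir / f"{ind}_tdr.csv", individual_id=ind)
        labels = read_labels(sim_dir / f"{ind}_labels.csv")
        truth = pd.read_csv(sim_dir / f"{ind}_truth.csv") \
            if (sim_dir / f"{ind}_truth.csv").exists() else None
        series = merge_streams(accel, tdr, label=labels)
        idx = truth["sample_index"].to_numpy() if truth is not None and \
            len(truth) else None
        processed.append(prepare_individual(series, cfg, truth_indices=idx))
    return processed


def _stage_simulate(cfg: RunConfig, sdir: Path) -> list[str]:
    cohort = simulate_cohort(cfg.sim)
    arts = []
    for trip in cohort:
        for p in write_trip(trip, sdir).values():
            arts.append(p.name)
    return arts


def _stage_segment(cfg: RunConfig, sdir: Path) -> list[str]:
    processed = _load_cohort_from_stage(cfg)
    tables = [dive_table(p.dives, p.series.rate_hz) for p in processed]
    df = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    df.to_csv(sdir / "dives.csv", index=False)
    return ["dives.csv"]


def _train_stage(kind: str):
    def fn(cfg: RunConfig, sdir: Path) -> list[str]:
        processed = _load_cohort_from_stage(cfg)
        counts = {p.individual_id: p.pce_count for p in processed}
        split = split_individuals(counts, cfg.sampler, np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 21])))
        by_id = {p.individual_id: p for p in processed}
        train_inds = [by_id[i] for i in split.train_ids]
        val_inds = [by_id[i] for i in split.val_ids]
        if kind == "cnn":
            trained = train_cnn(_cnn_windows(train_inds, cfg),
                                _cnn_windows(val_inds, cfg), cfg.cnn,
                                seed=cfg.seed)
        else:
            trained = train_vnet(_pool(train_inds), _pool(val_inds), cfg.vnet,
                                 cfg.sampler, seed=cfg.seed)
        trained.save(sdir / kind)
        split_manifest(split, counts).to_csv(sdir / "split.csv", index=False)
        return [f"{kind}/weights.npz", f"{kind}/meta.json", "split.csv"]
    return fn


def _stage_predict(cfg: RunConfig, sdir: Path) -> list[str]:
    processed = _load_cohort_from_stage(cfg)
    arts = []
    for kind in ("cnn", "vnet"):
        mdir = _stage_dir(cfg, f"train_{kind}") / kind
        if not mdir.exists():
            raise StageError(f"stage 'predict' needs artifacts of stage "
                             f"'train_{kind}'; run 'train_{kind}' first")
        trained = TrainedModel.load(mdir)
        rows = []
        for p in processed:
            pred = predict_points(trained, p.norm, p.series.depth, p.dives,
                                  cfg.sampler, cfg.dive.dive_threshold_m)
            hits = np.flatnonzero(pred)
            rows.append(pd.DataFrame({
                "individual_id": p.individual_id, "sample_index": hits,
                "prediction": 1}))
        name = f"predictions_{kind}.csv"
        pd.concat(rows, ignore_index=True).to_csv(sdir / name, index=False)
        arts.append(name)
    return arts


def _stage_evaluate(cfg: RunConfig, sdir: Path) -> list[str]:
    processed = _load_cohort_from_stage(cfg)
    pdir = _stage_dir(cfg, "predict")
    arts = []
    for kind in ("cnn", "vnet"):
        preds = pd.read_csv(pdir / f"predictions_{kind}.csv")
        per_ind = []
        for p in processed:
            vec = np.zeros(len(p.series), dtype=np.uint8)
            mine = preds[preds.individual_id == p.individual_id]
            vec[mine.sample_index.to_numpy()] = 1
            per_ind.append({"individual_id": p.individual_id,
                            "labels": p.series.label, "pred": vec,
                            "dives": p.dives, "depth": p.series.depth,
                            "truth_indices": p.truth_indices})
        rep = evaluate_predictions(kind, per_ind)
        rep.to_json(sdir / f"report_{kind}.json")
        rep.to_csv(sdir / f"per_dive_{kind}.csv")
        arts += [f"report_{kind}.json", f"per_dive_{kind}.csv"]
    return arts


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "train_cnn": _train_stage("cnn"),
    "train_vnet": _train_stage("vnet"),
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
}
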