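"""Per-dive count evaluation of point-wise capture predictions.

A single capture is annotated as 8 labelled samples, so the number of
events in a dive is the number of labelled (or predicted) samples divided
by eight.  Counts are compared by ordinary least squares of predicted on
observed per dive (slope, intercept, R^2), by dive-level classification
into foraging / non-foraging dives, and by point-wise metrics after
collapsing both label vectors to 1 s bins (any-positive within a bin),
since sub-second timing cannot be matched exactly.

Metric definitions follow the bio-logging validation convention used for
penguin capture detection: accuracy is the proportion of correct
predictions; "sensitivity" is TP / (TP + FP) — which is what is
conventionally called precision, and conventional recall TP / (TP + FN) is
additionally reported as ``recall_conventional`` to avoid ambiguity; the
false-positive rate is FP divided by the total number of observed
positives.  Division-by-zero cases are reported as None rather than NaN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dives import Dive, phase_of_sample

logger = logging.getLogger(__name__)

PHASES = ("surface", "descent", "bottom", "ascent")


@dataclass
class EvalConfig:
    points_per_pce: int = 8
    smoothing_s: float = 1.0
    dive_threshold_m: float = 0.4
    rate_hz: float = 25.0

    def __post_init__(self) -> None:
        if min(self.points_per_pce, self.smoothing_s,
               self.dive_threshold_m, self.rate_hz) <= 0:
            raise ValueError("EvalConfig fields must be positive")


def dive_counts(pred: np.ndarray, labels: np.ndarray, dives: list[Dive],
                depth: np.ndarray, cfg: EvalConfig | None = None,
                individual_id: str = "") -> pd.DataFrame:
    """Observed and predicted capture counts per dive.

    Counts are (number of positive samples in the dive) / points_per_pce,
    reported both as real values and nearest integers.  Samples at depth <=
    threshold contribute to neither count, mirroring the exclusion of
    surface captures from the analysis.
    """
    cfg = cfg or EvalConfig()
    rows = []
    under = depth > cfg.dive_threshold_m
    for d in dives:
        sl = slice(d.start_idx, d.end_idx)
        obs_pts = int((np.asarray(labels[sl], bool) & under[sl]).sum())
        prd_pts = int((np.asarray(pred[sl], bool) & under[sl]).sum())
        rows.append({
            "individual_id": individual_id or d.individual_id,
            "dive_id": d.dive_id,
            "kind": d.kind,
            "observed_points": obs_pts,
            "predicted_points": prd_pts,
            "observed": obs_pts / cfg.points_per_pce,
            "predicted": prd_pts / cfg.points_per_pce,
            "observed_int": int(round(obs_pts / cfg.points_per_pce)),
            "predicted_int": int(round(prd_pts / cfg.points_per_pce)),
        })
    return pd.DataFrame(rows, columns=[
        "individual_id", "dive_id", "kind", "observed_points",
        "predicted_points", "observed", "predicted", "observed_int",
        "predicted_int"])


def regress_counts(per_dive: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of predicted on observed counts: (slope, intercept, R^2).

    R^2 is the squared correlation.  Raises if fewer than two dives or if
    the observed counts have zero variance.
    """
    obs = per_dive["observed"].to_numpy(dtype=float)
    prd = per_dive["predicted"].to_numpy(dtype=float)
    if len(obs) < 2:
        raise ValueError("need at least 2 dives to regress counts")
    if np.var(obs) == 0:
        raise ValueError("observed counts have zero variance; "
                         "regression undefined")
    res = stats.linregress(obs, prd)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def _safe_div(a: float, b: float) -> float | None:
    return a / b if b else None


def dive_level_metrics(per_dive: pd.DataFrame) -> dict:
    """Foraging-dive classification metrics from integerized counts.

    A dive is observed-foraging iff it holds at least one labelled sample;
    predicted-foraging iff its rounded predicted count is >= 1.
    """
    obs = per_dive["observed_points"].to_numpy() > 0
    prd = per_dive["predicted_int"].to_numpy() >= 1
    tp = int((obs & prd).sum())
    fp = int((~obs & prd).sum())
    fn = int((obs & ~prd).sum())
    tn = int((~obs & ~prd).sum())
    return {
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "sensitivity": _safe_div(tp, tp + fp),  # the field's usage: precision
        "false_positive_rate": _safe_div(fp, tp + fn),
        "recall_conventional": _safe_div(tp, tp + fn),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def _binned(vec: np.ndarray, dive: Dive, bin_samples: int) -> np.ndarray:
    """Any-positive 1 s bins anchored at the dive start (last bin partial)."""
    seg = np.asarray(vec[dive.start_idx:dive.end_idx], dtype=bool)
    n_bins = int(np.ceil(len(seg) / bin_samples))
    out = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        out[b] = seg[b * bin_samples:(b + 1) * bin_samples].any()
    return out


def pointwise_metrics(labels: np.ndarray, pred: np.ndarray,
                      dives: list[Dive], cfg: EvalConfig | None = None) -> dict:
    """Point-wise metrics after collapsing to 1 s bins over in-dive samples."""
    cfg = cfg or EvalConfig()
    bin_samples = int(round(cfg.smoothing_s * cfg.rate_hz))
    obs_bins, prd_bins = [], []
    for d in dives:
        obs_bins.append(_binned(labels, d, bin_samples))
        prd_bins.append(_binned(pred, d, bin_samples))
    if not obs_bins:
        return {"accuracy": None, "sensitivity": None,
                "false_positive_rate": None, "recall_conventional": None}
    obs = np.concatenate(obs_bins)
    prd = np.concatenate(prd_bins)
    tp = int((obs & prd).sum())
    fp = int((~obs & prd).sum())
    fn = int((obs & ~prd).sum())
    tn = int((~obs & ~prd).sum())
    return {
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "sensitivity": _safe_div(tp, tp + fp),
        "false_positive_rate": _safe_div(fp, tp + fn),
        "recall_conventional": _safe_div(tp, tp + fn),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def phase_distribution(sample_indices: np.ndarray | list[int],
                       dives: list[Dive]) -> dict:
    """Fractions of events per dive phase.

    Each event is assigned the phase containing its centre sample: surface
    (outside any dive, or inside an unsplit surface dive), descent, bottom
    or ascent.  Fractions sum to 1 when any events exist; an empty event
    list yields all zeros with ``empty=True``.
    """
    idx = np.asarray(sample_indices, dtype=np.int64)
    out = {p: 0.0 for p in PHASES}
    if idx.size == 0:
        out["empty"] = True
        return out
    # sorted dive starts for a binary-search lookup
    starts = np.array([d.start_idx for d in dives])
    order = np.argsort(starts)
    sdives = [dives[i] for i in order]
    sstarts = starts[order]
    counts = dict.fromkeys(PHASES, 0)
    for s in idx:
        j = int(np.searchsorted(sstarts, s, side="right")) - 1
        phase = sdives[j].phase_of(int(s)) if j >= 0 else "surface"
        counts[phase] += 1
    for p in PHASES:
        out[p] = counts[p] / idx.size
    out["empty"] = False
    return out


def predicted_event_centers(pred: np.ndarray) -> np.ndarray:
    """Centre sample of each contiguous run of predicted-positive samples."""
    v = np.asarray(pred, dtype=np.int8)
    edges = np.diff(np.r_[0, v, 0])
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return ((starts + ends - 1) // 2).astype(np.int64)


@dataclass
class EvalReport:
    """Evaluation bundle for one detector over a set of test individuals."""

    model_kind: str
    per_dive: pd.DataFrame
    regression: dict = field(default_factory=dict)
    dive_metrics: dict = field(default_factory=dict)
    point_metrics: dict = field(default_factory=dict)
    phase_observed: dict = field(default_factory=dict)
    phase_predicted: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model_kind": self.model_kind,
            "regression": self.regression,
            "dive_metrics": self.dive_metrics,
            "point_metrics": self.point_metrics,
            "phase_observed": self.phase_observed,
            "phase_predicted": self.phase_predicted,
            "n_dives": int(len(self.per_dive)),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        self.per_dive.to_csv(path, index=False)


def evaluate_predictions(model_kind: str,
                         per_individual: list[dict]) -> EvalReport:
    """Pool per-individual prediction results into one report.

    ``per_individual`` entries carry: individual_id, labels, pred, dives,
    depth (numpy arrays / Dive lists), truth_indices (optional centre
    samples of annotated events).
    """
    cfg = EvalConfig()
    tables, obs_phase_idx, prd_phase_idx = [], [], []
    all_dives_by_ind = {}
    for item in per_individual:
        t = dive_counts(item["pred"], item["labels"], item["dives"],
                        item["depth"], cfg, individual_id=item["individual_id"])
        tables.append(t)
        all_dives_by_ind[item["individual_id"]] = item["dives"]
    per_dive = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()

    report = EvalReport(model_kind=model_kind, per_dive=per_dive)
    try:
        slope, intercept, r2 = regress_counts(per_dive)
        report.regression = {"slope": slope, "intercept": intercept,
                             "r_squared": r2}
    except ValueError as exc:
        logger.warning("count regression unavailable: %s", exc)
        report.regression = {"error": str(exc)}
    report.dive_metrics = dive_level_metrics(per_dive)

    tp = fp = fn = tn = 0
    for item in per_individual:
        m = pointwise_metrics(item["labels"], item["pred"], item["dives"], cfg)
        tp, fp = tp + m["tp"], fp + m["fp"]
        fn, tn = fn + m["fn"], tn + m["tn"]
    report.point_metrics = {
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "sensitivity": _safe_div(tp, tp + fp),
        "false_positive_rate": _safe_div(fp, tp + fn),
        "recall_conventional": _safe_div(tp, tp + fn),
    }

    for item in per_individual:
        if "truth_indices" in item:
            report.phase_observed = _merge_phase(
                report.phase_observed,
                phase_distribution(item["truth_indices"], item["dives"]),
                len(item["truth_indices"]))
        centers = predicted_event_centers(item["pred"])
        report.phase_predicted = _merge_phase(
            report.phase_predicted,
            phase_distribution(centers, item["dives"]), len(centers))
    return report


def _merge_phase(acc: dict, part: dict, n: int) -> dict:
    """Weighted running merge of phase-fraction dicts."""
    if not acc:
        acc = {p: 0.0 for p in PHASES}
        acc["_n"] = 0
    total = acc["_n"] + n
    if total == 0:
        return acc
    for p in PHASES:
        acc[p] = (acc[p] * acc["_n"] + part.get(p, 0.0) * n) / total
    acc["_n"] = total
    return acc
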