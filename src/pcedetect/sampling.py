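"""Training-input construction: windows, the biased generator, and splits.

Two detectors consume different window shapes:

* the windowed CNN classifies overlapping 8-sample segments (step 4, i.e.
  50% overlap) cut from the balanced ("most likely foraging") regions of
  each dive separately, each segment carrying a single binary label;
* the 1D V-Net labels every sample of 128-sample windows (5.12 s) drawn by
  a global generator that mixes uniform draws (10%) with draws positioned
  uniformly at random among the placements containing a randomly chosen
  labelled prey-capture sample (90%), which over-represents the rare
  positive class during training.

Individuals — not windows — are assigned to the train/validation/test
groups so that evaluation is always on unseen animals; assignments are
rejection-sampled until each group holds its target share of the annotated
prey-capture events.  Individuals with zero events are excluded from the
assignment and returned separately for test-time prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Window and split parameters.

    ``epoch_windows_train``/``epoch_windows_val`` are the number of
    generator draws per V-Net training epoch and the size of its fixed
    validation set.  ``cnn_label_min_overlap`` is the number of labelled
    samples an 8-sample segment must contain to be labelled positive: 6 of
    8 guarantees every annotated capture yields at least one positive
    window at step 4 while keeping the divide-by-eight count conversion
    near-unbiased at prediction time.
    """

    w_cnn: int = 8
    cnn_overlap: float = 0.5
    cnn_label_min_overlap: int = 6
    w_vnet: int = 128
    vnet_bias: float = 0.9
    epoch_windows_train: int = 20000
    epoch_windows_val: int = 16000
    split_fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    n_split_repeats: int = 10
    split_tolerance: float = 0.05
    max_split_attempts: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.cnn_overlap < 1:
            raise ValueError("cnn_overlap must lie in (0, 1)")
        if not 0 <= self.vnet_bias <= 1:
            raise ValueError("vnet_bias must lie in [0, 1]")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if not 1 <= self.cnn_label_min_overlap <= self.w_cnn:
            raise ValueError("cnn_label_min_overlap must lie in [1, w_cnn]")

    @property
    def cnn_step(self) -> int:
        return max(1, int(round(self.w_cnn * (1.0 - self.cnn_overlap))))


@dataclass
class WindowBatch:
    """A stack of fixed-length windows with labels and provenance.

    ``data`` has shape (n, w, 3) — normalized X, Y, Z.  ``labels`` is (n,)
    for segment classification or (n, w) for per-sample labelling.
    ``provenance`` records (individual_id, start index) per window.
    """

    data: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = np.setdiff1d(np.unique(self.labels), [0, 1])
        if bad.size:
            raise ValueError(f"window labels must be binary, found {bad.tolist()}")

    def __len__(self) -> int:
        return len(self.data)


def masked_runs(mask: np.ndarray, start: int, end: int) -> list[tuple[int, int]]:
    """Maximal True-runs of ``mask`` restricted to [start, end), half-open."""
    m = np.asarray(mask[start:end], dtype=np.int8)
    if m.size == 0:
        return []
    edges = np.diff(m)
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, len(m)]
    return [(start + int(s), start + int(e)) for s, e in zip(starts, ends)]


def n_windows(run_len: int, w: int, step: int) -> int:
    """Closed-form window count for one run: floor((n - w)/step) + 1."""
    if run_len < w:
        return 0
    return (run_len - w) // step + 1


def segment_cnn_windows(data: np.ndarray, labels: np.ndarray,
                        mask: np.ndarray, dives: list, cfg: SamplerConfig,
                        individual_id: str = "") -> WindowBatch:
    """Cut 8-sample, step-4 windows from each dive's masked region.

    Windows never cross dive boundaries (each dive is segmented
    separately); masked runs shorter than one window are skipped and
    counted in the log.  A window is labelled 1 iff at least
    ``cnn_label_min_overlap`` of its samples carry the capture label.
    """
    w, step = cfg.w_cnn, cfg.cnn_step
    out_data, out_labels, prov = [], [], []
    skipped = 0
    for d in dives:
        for rs, re in masked_runs(mask, d.start_idx, d.end_idx):
            if re - rs < w:
                skipped += 1
                continue
            for k in range(n_windows(re - rs, w, step)):
                s = rs + k * step
                out_data.append(data[s:s + w])
                out_labels.append(
                    1 if int(labels[s:s + w].sum()) >= cfg.cnn_label_min_overlap
                    else 0)
                prov.append((individual_id, s))
    if skipped:
        logger.info("%s: %d masked runs shorter than w_cnn=%d skipped",
                    individual_id or "series", skipped, w)
    if not out_data:
        return WindowBatch(data=np.empty((0, w, data.shape[1])),
                           labels=np.empty(0, dtype=np.int64), provenance=[])
    return WindowBatch(data=np.stack(out_data),
                       labels=np.asarray(out_labels, dtype=np.int64),
                       provenance=prov)


def vnet_global_generator(pool: list[tuple[str, np.ndarray, np.ndarray]],
                          cfg: SamplerConfig, n_draws: int,
                          rng: np.random.Generator) -> WindowBatch:
    """Draw ``n_draws`` biased 128-sample windows from a multi-individual pool.

    ``pool`` holds (individual_id, normalized (n, 3) data, per-sample binary
    labels) triples.  Each draw: with probability ``1 - vnet_bias`` a
    uniformly random window from a uniformly random individual; otherwise a
    window positioned uniformly at random among the placements that contain
    a uniformly chosen labelled capture sample.  Windows may include
    surface and descent samples.  Falls back to uniform draws (with a
    warning) when the pool holds no labelled sample.
    """
    if not pool:
        raise ValueError("empty training pool")
    w = cfg.w_vnet
    ids = [ind for ind, d, _ in pool if len(d) >= w]
    datas = [np.asarray(d) for _, d, _ in pool if len(d) >= w]
    labs = [np.asarray(l) for _, d, l in pool if len(d) >= w]
    if not ids:
        raise ValueError(f"no individual in the pool is >= w_vnet={w} samples")

    # flat (individual, sample) index of every labelled sample
    pos_ind = np.concatenate(
        [np.full(int(l.sum()), i) for i, l in enumerate(labs)]
    ) if any(l.any() for l in labs) else np.empty(0, dtype=int)
    pos_idx = np.concatenate(
        [np.flatnonzero(l) for l in labs]
    ) if pos_ind.size else np.empty(0, dtype=int)
    bias = cfg.vnet_bias
    if bias > 0 and pos_idx.size == 0:
        logger.warning("biased draws requested but the pool holds no "
                       "labelled capture sample; falling back to uniform")
        bias = 0.0

    data = np.empty((n_draws, w, datas[0].shape[1]))
    labels = np.empty((n_draws, w), dtype=np.int64)
    prov: list[tuple[str, int]] = []
    biased = rng.random(n_draws) < bias
    for j in range(n_draws):
        if biased[j]:
            k = int(rng.integers(len(pos_idx)))
            i = int(pos_ind[k])
            s_hit = int(pos_idx[k])
            lo = max(0, s_hit - w + 1)
            hi = min(len(datas[i]) - w, s_hit)
            start = int(rng.integers(lo, hi + 1))
        else:
            i = int(rng.integers(len(ids)))
            start = int(rng.integers(0, len(datas[i]) - w + 1))
        data[j] = datas[i][start:start + w]
        labels[j] = labs[i][start:start + w]
        prov.append((ids[i], start))
    return WindowBatch(data=data, labels=labels, provenance=prov)


@dataclass
class SplitResult:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    zero_pce_ids: list[str]
    shares: tuple[float, float, float]
    attempts: int
    within_tolerance: bool

    def group_of(self, individual_id: str) -> str:
        if individual_id in self.train_ids:
            return "train"
        if individual_id in self.val_ids:
            return "val"
        if individual_id in self.test_ids:
            return "test"
        return "zero_pce"


def split_individuals(pce_counts: dict[str, int], cfg: SamplerConfig,
                      rng: np.random.Generator | None = None) -> SplitResult:
    """Assign individuals to train/val/test holding the target event shares.

    Individuals with zero annotated captures are excluded from the
    assignment (there is nothing for a model to learn from or validate
    against) and returned in ``zero_pce_ids`` for test-time prediction.
    Assignments are rejection-sampled: each attempt places every individual
    independently with probabilities equal to ``split_fractions``, requires
    non-empty groups, and accepts when each group's share of total events
    is within ``split_tolerance`` of its target.  If no attempt within
    ``max_split_attempts`` succeeds the best-found split is returned with a
    warning.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ids = sorted(pce_counts)
    zero = [i for i in ids if pce_counts[i] == 0]
    active = [i for i in ids if pce_counts[i] > 0]
    if len(active) < 3:
        raise ValueError("need at least 3 individuals with nonzero events "
                         f"to form three groups (got {len(active)})")
    counts = np.array([pce_counts[i] for i in active], dtype=float)
    total = counts.sum()
    targets = np.asarray(cfg.split_fractions)

    best = None
    best_dev = np.inf
    attempts = 0
    for attempt in range(1, cfg.max_split_attempts + 1):
        attempts = attempt
        groups = rng.choice(3, size=len(active), p=targets)
        if len(np.unique(groups)) < 3:
            continue
        shares = np.array([counts[groups == g].sum() / total for g in range(3)])
        dev = float(np.abs(shares - targets).max())
        if dev < best_dev:
            best_dev, best = dev, (groups, shares)
        if dev <= cfg.split_tolerance:
            break
    groups, shares = best
    ok = best_dev <= cfg.split_tolerance
    if not ok:
        logger.warning(
            "no split within tolerance %.3f after %d attempts; best "
            "deviation %.3f returned", cfg.split_tolerance, attempts, best_dev)
    return SplitResult(
        train_ids=[i for i, g in zip(active, groups) if g == 0],
        val_ids=[i for i, g in zip(active, groups) if g == 1],
        test_ids=[i for i, g in zip(active, groups) if g == 2],
        zero_pce_ids=zero,
        shares=tuple(float(s) for s in shares),
        attempts=attempts,
        within_tolerance=ok,
    )


def split_manifest(split: SplitResult, pce_counts: dict[str, int]):
    """Split manifest table: individual_id, group, pce_count."""
    import pandas as pd

    rows = []
    for ind in sorted(pce_counts):
        rows.append({"individual_id": ind, "group": split.group_of(ind),
                     "pce_count": pce_counts[ind]})
    return pd.DataFrame(rows)
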