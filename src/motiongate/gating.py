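"""Artifact-frame removal by percentile and relative-maximum gating.

Frames whose dissimilarity score stands out are rejected:

* the **percentile gate** keeps the lowest-scoring ``P`` percent of frames
  (nearest-rank percentile; a cutoff of 60 keeps the best-matching 60 %
  and rejects the top 40 %);
* the **n-neighbor (relative-maximum) filter** partitions the sequence into
  consecutive non-overlapping groups of ``n`` frames and removes, within
  each group, exactly the frame with the highest score;
* **double filtering** applies the same filter a second time to the
  retained sequence — the only way a relative-maximum pass can catch two
  consecutive distorted frames, at the price of removing one frame per
  group even from clean footage.

All selections are expressed in *origin indices* so downstream
timestamping survives frame removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .scoring import ReferencePolicy, ScoreSeries, score_stack
from .stack_io import FrameStack


@dataclass(frozen=True)
class GateConfig:
    """Which gates to run and how.

    At least one of ``percentile_cutoff`` / ``neighbor_group`` must be set.
    ``rescore_between_passes=None`` resolves to True under a rolling
    reference policy (removed artifacts contaminate rolling references,
    which must be rebuilt) and False under a single reference.
    """

    percentile_cutoff: float | None = None
    neighbor_group: int | None = None
    passes: int = 1
    rescore_between_passes: bool | None = None

    def __post_init__(self) -> None:
        if self.percentile_cutoff is None and self.neighbor_group is None:
            raise ConfigurationError(
                "GateConfig needs percentile_cutoff and/or neighbor_group"
            )
        if self.percentile_cutoff is not None and not 0 < self.percentile_cutoff <= 100:
            raise ConfigurationError(
                f"percentile_cutoff must be in (0, 100]; got {self.percentile_cutoff}"
            )
        if self.neighbor_group is not None:
            n = self.neighbor_group
            if n < 3 or n % 2 == 0:
                raise ConfigurationError(
                    f"neighbor_group must be an odd integer >= 3; got {n}"
                )
        if self.passes not in (1, 2):
            raise ConfigurationError(f"passes must be 1 or 2; got {self.passes}")


@dataclass(frozen=True)
class FrameSelection:
    """Partition of origin indices into kept and removed frames.

    ``reasons`` maps each removed origin index to ``(filter_name, pass_no)``.
    """

    kept: np.ndarray
    removed: np.ndarray
    reasons: dict[int, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kept = np.asarray(sorted(self.kept), dtype=np.int64)
        removed = np.asarray(sorted(self.removed), dtype=np.int64)
        if np.intersect1d(kept, removed).size:
            raise ConsistencyError("kept and removed origin indices overlap")
        missing = set(removed.tolist()) - set(self.reasons)
        if missing:
            raise ConsistencyError(f"removed frames without a reason: {sorted(missing)}")
        object.__setattr__(self, "kept", kept)
        object.__setattr__(self, "removed", removed)

    @property
    def all_indices(self) -> np.ndarray:
        return np.union1d(self.kept, self.removed)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: origin_index, status, reason, pass."""
        rows = [
            {"origin_index": int(i), "status": "kept", "reason": "", "pass": 0}
            for i in self.kept
        ] + [
            {
                "origin_index": int(i),
                "status": "removed",
                "reason": self.reasons[int(i)][0],
                "pass": self.reasons[int(i)][1],
            }
            for i in self.removed
        ]
        return (
            pd.DataFrame(rows)
            .sort_values("origin_index")
            .reset_index(drop=True)
        )


def nearest_rank_threshold(scores: np.ndarray, P: float) -> float:
    """Nearest-rank P-th percentile: the value at rank ``ceil(P/100 * T)``
    of the ascending sort (1-based)."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ConfigurationError("percentile of an empty score series")
    rank = math.ceil(P / 100.0 * scores.size)
    return float(np.sort(scores)[rank - 1])


def percentile_gate(series: ScoreSeries, P: float, *, pass_no: int = 1) -> FrameSelection:
    """Keep frames scoring at or below the nearest-rank P-th percentile."""
    if not 0 < P <= 100:
        raise ConfigurationError(f"percentile must be in (0, 100]; got {P}")
    if len(series) == 0:
        raise ConfigurationError("cannot gate an empty score series")
    threshold = nearest_rank_threshold(series.scores, P)
    keep_mask = series.scores <= threshold
    kept = series.origin_indices[keep_mask]
    removed = series.origin_indices[~keep_mask]
    reasons = {int(i): ("percentile", pass_no) for i in removed}
    return FrameSelection(kept=kept, removed=removed, reasons=reasons)


def neighbor_max_filter(series: ScoreSeries, n: int, *, pass_no: int = 1) -> FrameSelection:
    """Remove the highest-scoring frame in each consecutive group of ``n``.

    The trailing partial group is still filtered when it holds at least two
    frames; a lone trailing singleton is kept.  Ties remove the earliest
    frame of the group.
    """
    T = len(series)
    if n % 2 == 0 or not 3 <= n <= T:
        raise ConfigurationError(f"group size must be odd with 3 <= n <= T={T}; got {n}")
    removed_pos: list[int] = []
    for start in range(0, T, n):
        group = series.scores[start : start + n]
        if group.size < 2:
            continue
        removed_pos.append(start + int(np.argmax(group)))
    mask = np.ones(T, dtype=bool)
    mask[removed_pos] = False
    kept = series.origin_indices[mask]
    removed = series.origin_indices[~mask]
    reasons = {int(i): ("neighbor_max", pass_no) for i in removed}
    return FrameSelection(kept=kept, removed=removed, reasons=reasons)


def _restrict(series: ScoreSeries, kept: np.ndarray) -> ScoreSeries:
    mask = np.isin(series.origin_indices, kept)
    return ScoreSeries(
        scores=series.scores[mask],
        origin_indices=series.origin_indices[mask],
        policy=series.policy,
        channel=series.channel,
    )


def _merge(first: FrameSelection, second: FrameSelection) -> FrameSelection:
    reasons = dict(first.reasons)
    reasons.update(second.reasons)
    removed = np.union1d(first.removed, second.removed)
    kept = np.setdiff1d(first.kept, second.removed)
    return FrameSelection(kept=kept, removed=removed, reasons=reasons)


def gate_stack(
    stack: FrameStack,
    channel: str,
    policy: ReferencePolicy,
    config: GateConfig,
) -> tuple[FrameSelection, ScoreSeries]:
    """Run the configured gates on a stack; returns the selection and the
    pass-1 score series.

    Within a pass the percentile gate runs first and the neighbor filter
    second, on the survivors, reusing that pass's scores.  With
    ``passes=2`` the same gates are re-applied to the retained sequence;
    scores are recomputed between passes when ``rescore_between_passes``
    resolves to True, else pass-1 scores are reused restricted to the
    retained frames.
    """
    series = score_stack(stack, channel, policy)
    selection = _gate_pass(series, config, pass_no=1)
    if config.passes == 2:
        rescore = config.rescore_between_passes
        if rescore is None:
            rescore = policy.mode == "rfg"
        retained = apply_selection(stack, selection)
        if rescore:
            series2 = score_stack(retained, channel, policy)
        else:
            series2 = _restrict(series, selection.kept)
        selection = _merge(selection, _gate_pass(series2, config, pass_no=2))
    return selection, series


def _gate_pass(series: ScoreSeries, config: GateConfig, pass_no: int) -> FrameSelection:
    selection = FrameSelection(
        kept=series.origin_indices, removed=np.array([], dtype=np.int64)
    )
    current = series
    if config.percentile_cutoff is not None:
        sel = percentile_gate(current, config.percentile_cutoff, pass_no=pass_no)
        selection = _merge(selection, sel)
        current = _restrict(current, selection.kept)
    if config.neighbor_group is not None and len(current) >= config.neighbor_group:
        sel = neighbor_max_filter(current, config.neighbor_group, pass_no=pass_no)
        selection = _merge(selection, sel)
    return selection


def double_filter(
    stack: FrameStack,
    channel: str,
    policy: ReferencePolicy,
    config: GateConfig,
) -> FrameSelection:
    """Two-pass gating (``config.passes`` must be 2); catches consecutive
    distorted frames that a single relative-maximum pass provably misses."""
    if config.passes != 2:
        raise ConfigurationError("double_filter requires config.passes == 2")
    selection, _ = gate_stack(stack, channel, policy, config)
    return selection


def apply_selection(stack: FrameStack, selection: FrameSelection) -> FrameStack:
    """New stack holding the kept frames in order, origin indices preserved.

    Selection indices absent from the stack are tolerated (those frames were
    already removed), which makes re-applying a selection a no-op; a stack
    frame unknown to the selection is a consistency error.
    """
    covered = set(selection.all_indices.tolist())
    unknown = [int(i) for i in stack.origin_indices if int(i) not in covered]
    if unknown:
        raise ConsistencyError(
            f"stack holds origin indices unknown to the selection: {unknown}"
        )
    mask = np.isin(stack.origin_indices, selection.kept)
    return FrameStack(
        frames=stack.frames[mask].copy(),
        channel_names=stack.channel_names,
        origin_indices=stack.origin_indices[mask],
    )


def evaluate_gating(selection: FrameSelection, truth) -> dict[str, float]:
    """Score a selection against planted ground-truth labels.

    Returns artifact_rate_before (#minor+major over T),
    residual_artifact_rate (#artifact frames kept over #kept),
    recall (artifacts removed over artifacts) and false_positive_rate
    (good frames removed over good frames).  Empty denominators yield 0.0
    for rates and 1.0 for recall (nothing to catch).
    """
    labels = truth.labels_by_index()
    all_idx = selection.all_indices
    if set(labels) != set(int(i) for i in all_idx):
        raise ConsistencyError("ground truth does not cover the selected frames")
    artifact = {i for i, lab in labels.items() if lab in ("minor", "major")}
    good = set(labels) - artifact
    kept = set(int(i) for i in selection.kept)
    removed = set(int(i) for i in selection.removed)
    T = len(labels)
    kept_artifacts = len(kept & artifact)
    return {
        "n_frames": float(T),
        "n_kept": float(len(kept)),
        "artifact_rate_before": len(artifact) / T,
        "residual_artifact_rate": kept_artifacts / len(kept) if kept else 0.0,
        "recall": len(removed & artifact) / len(artifact) if artifact else 1.0,
        "false_positive_rate": len(removed & good) / len(good) if good else 0.0,
    }
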