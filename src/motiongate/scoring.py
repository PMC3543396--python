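"""Per-frame dissimilarity scoring against single or rolling reference frames.

A frame's dissimilarity score is the mean squared pixel difference (square
difference, SSD normalised per pixel) between the frame and a reference
image, computed on a single designated *reference channel* — in vivo this is
the channel holding a temporally stable structure such as blood vessels.

Two reference policies exist:

``single``
    one user-chosen frame serves as reference for the whole sequence.
``rfg`` (reference frame generation)
    each frame is scored against the average-intensity projection of the
    window of ``n`` adjacent frames centred on it (``n`` odd, truncated at
    the stack boundaries, the scored frame included).  Rolling references
    keep the score baseline flat in long recordings where drift makes a
    single reference progressively stale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .stack_io import FrameStack

DEFAULT_RFG_WINDOW = 15  # frames; midpoint of the useful 5-30 range


@dataclass(frozen=True)
class ReferencePolicy:
    """How the reference image for each frame is obtained."""

    mode: str = "rfg"
    single_index: int | None = None
    window: int = DEFAULT_RFG_WINDOW

    def __post_init__(self) -> None:
        if self.mode not in ("single", "rfg"):
            raise ConfigurationError(f"mode must be 'single' or 'rfg'; got {self.mode!r}")
        if self.mode == "single" and self.single_index is None:
            raise ConfigurationError("mode='single' requires single_index")
        if self.mode == "rfg":
            if self.window % 2 == 0:
                raise ConfigurationError(
                    f"rfg window must be odd; got {self.window}"
                )
            if self.window < 3:
                raise ConfigurationError(f"rfg window must be >= 3; got {self.window}")

    def validate_for(self, T: int) -> None:
        if self.mode == "single" and not 0 <= int(self.single_index) < T:
            raise ConfigurationError(
                f"single_index {self.single_index} out of range for T={T}"
            )
        if self.mode == "rfg" and self.window > T:
            raise ConfigurationError(
                f"rfg window {self.window} exceeds stack length T={T}"
            )


@dataclass(frozen=True)
class ScoreSeries:
    """Dissimilarity scores aligned to a stack's origin indices."""

    scores: np.ndarray            # (T,) float64, >= 0
    origin_indices: np.ndarray    # (T,) int64
    policy: ReferencePolicy
    channel: str

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        origin = np.asarray(self.origin_indices, dtype=np.int64)
        if scores.shape != origin.shape or scores.ndim != 1:
            raise ConfigurationError("scores and origin_indices must be equal-length 1-D")
        if np.any(scores < 0):
            raise ConfigurationError("dissimilarity scores must be non-negative")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "origin_indices", origin)

    def __len__(self) -> int:
        return len(self.scores)


def ssd_score(frame: np.ndarray, reference: np.ndarray) -> float:
    """Mean over pixels of the squared difference between frame and
    reference, in real arithmetic (no 8-bit saturation)."""
    frame = np.asarray(frame)
    reference = np.asarray(reference)
    if frame.shape != reference.shape or frame.ndim != 2:
        raise ConfigurationError(
            f"frame {frame.shape} and reference {reference.shape} must be "
            "identically shaped single-channel images"
        )
    diff = frame.astype(np.float64) - reference.astype(np.float64)
    return float(np.mean(diff * diff))


def build_reference(
    stack: FrameStack | np.ndarray, policy: ReferencePolicy, t: int
) -> np.ndarray:
    """Reference image (float64, H x W) for scoring frame ``t``.

    mode='single': the designated frame.  mode='rfg': arithmetic mean of
    the frames in the odd window centred on ``t`` (truncated at the
    boundaries, frame ``t`` included).
    """
    frames = _channel_planes(stack)
    T = frames.shape[0]
    if not 0 <= t < T:
        raise ConfigurationError(f"frame index {t} out of range for T={T}")
    policy.validate_for(T)
    if policy.mode == "single":
        return frames[int(policy.single_index)].astype(np.float64)
    half = policy.window // 2
    lo, hi = max(0, t - half), min(T, t + half + 1)
    return frames[lo:hi].mean(axis=0, dtype=np.float64)


def _channel_planes(stack: FrameStack | np.ndarray) -> np.ndarray:
    if isinstance(stack, FrameStack):
        if stack.C != 1:
            raise ConfigurationError(
                "build_reference expects a single-channel stack; use "
                "score_stack(stack, channel, ...) for multi-channel input"
            )
        return stack.frames[..., 0]
    arr = np.asarray(stack)
    if arr.ndim != 3:
        raise ConfigurationError(f"expected (T, H, W) planes; got {arr.shape}")
    return arr


def score_stack(
    stack: FrameStack, channel: str, policy: ReferencePolicy
) -> ScoreSeries:
    """Score every frame of ``stack`` on the named reference channel."""
    planes = stack.channel(channel)
    policy.validate_for(stack.T)
    scores = np.empty(stack.T, dtype=np.float64)
    if policy.mode == "single":
        ref = planes[int(policy.single_index)].astype(np.float64)
        for t in range(stack.T):
            scores[t] = ssd_score(planes[t], ref)
    else:
        half = policy.window // 2
        for t in range(stack.T):
            lo, hi = max(0, t - half), min(stack.T, t + half + 1)
            ref = planes[lo:hi].mean(axis=0, dtype=np.float64)
            scores[t] = ssd_score(planes[t], ref)
    return ScoreSeries(
        scores=scores,
        origin_indices=stack.origin_indices,
        policy=policy,
        channel=channel,
    )


def score_report(
    series: ScoreSeries, bins: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score trace and binned relative-frequency distribution.

    Returns ``(trace, histogram)``: the trace has columns
    ``origin_index, score``; the histogram has ``bin_left, bin_right,
    relative_frequency`` with frequencies summing to 1.
    """
    if len(series) == 0:
        raise ConfigurationError("cannot report on an empty score series")
    trace = pd.DataFrame(
        {"origin_index": series.origin_indices, "score": series.scores}
    )
    counts, edges = np.histogram(series.scores, bins=bins)
    hist = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "relative_frequency": counts / counts.sum(),
        }
    )
    return trace, hist
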