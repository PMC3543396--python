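"""Frame-to-frame x-y registration and artifactual-displacement measurement.

Four transform families are supported, each mapping a moving frame onto its
(already aligned) predecessor: pure translation, rigid body (translation +
rotation), scaled rotation (adds isotropic scale) and full affine (adds
shear/skew).  Translation is estimated by subpixel phase correlation; the
richer models by intensity-based least squares (Gauss-Newton with analytic
Jacobians, initialised from the phase-correlation translation) — feature
matching on vessel-like imagery suffers the aperture problem along tubes,
whereas whole-image least squares uses every informative pixel.

Alignment proceeds by propagation: frame 0 anchors the sequence, every later
frame is registered onto its aligned predecessor and the resulting model
(already expressed in anchor coordinates) is applied to all channels.

``displacement_series`` quantifies residual motion by tracking a small
intensity patch around a user-chosen marker from frame to frame and summing
the per-frame displacement magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp

from .errors import ConfigurationError, DegenerateFrameError
from .stack_io import FrameStack

logger = logging.getLogger(__name__)

TRANSFORM_KINDS = ("translation", "rigid", "scaled_rotation", "affine")


@dataclass(frozen=True)
class TransformModel:
    """A 2-D geometric model mapping moving-frame coordinates onto
    fixed-frame coordinates, stored as a 3x3 homogeneous matrix."""

    kind: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ConfigurationError(
                f"kind must be one of {TRANSFORM_KINDS}; got {self.kind!r}"
            )
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ConfigurationError(f"matrix must be 3x3; got {m.shape}")
        object.__setattr__(self, "matrix", m)

    # -- constructors ----------------------------------------------------
    @classmethod
    def identity(cls, kind: str = "translation") -> "TransformModel":
        return cls(kind=kind, matrix=np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "TransformModel":
        return cls("translation", AffineTransform(translation=(dx, dy)).params)

    @classmethod
    def from_skimage(cls, kind: str, tform) -> "TransformModel":
        return cls(kind, np.asarray(tform.params))

    # -- parameter accessors (x right, y down; angle in radians) ---------
    @property
    def dx(self) -> float:
        return float(self.matrix[0, 2])

    @property
    def dy(self) -> float:
        return float(self.matrix[1, 2])

    @property
    def rotation(self) -> float:
        return float(np.arctan2(self.matrix[1, 0], self.matrix[0, 0]))

    @property
    def scale(self) -> float:
        return float(np.hypot(self.matrix[0, 0], self.matrix[1, 0]))

    def as_skimage(self) -> AffineTransform:
        return AffineTransform(matrix=self.matrix)

    def compose(self, inner: "TransformModel") -> "TransformModel":
        """Model applying ``inner`` first, then this model.  The composite
        kind is the broader of the two (affine closure)."""
        order = {k: i for i, k in enumerate(TRANSFORM_KINDS)}
        kind = self.kind if order[self.kind] >= order[inner.kind] else inner.kind
        return TransformModel(kind, self.matrix @ inner.matrix)

    def inverse(self) -> "TransformModel":
        det = np.linalg.det(self.matrix[:2, :2])
        if abs(det) < 1e-12:
            raise ConfigurationError("transform is not invertible")
        return TransformModel(self.kind, np.linalg.inv(self.matrix))

    def max_displacement(self, shape: tuple[int, int]) -> float:
        """Largest corner displacement (px) the model induces on a frame."""
        H, W = shape
        corners = np.array([[0, 0], [W - 1, 0], [0, H - 1], [W - 1, H - 1]], float)
        moved = self.as_skimage()(corners)
        return float(np.max(np.hypot(*(moved - corners).T)))


def _as_float_plane(frame: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim != 2:
        raise ConfigurationError(f"{name} must be a single-channel 2-D image")
    if arr.std() == 0:
        raise DegenerateFrameError(f"{name} has zero variance; cannot register")
    return arr


def estimate_transform(
    moving: np.ndarray,
    fixed: np.ndarray,
    kind: str = "translation",
    *,
    presmooth: float = 1.0,
    margin_frac: float = 0.08,
    max_iter: int = 80,
) -> TransformModel:
    """Estimate the model of the requested kind mapping ``moving`` onto
    ``fixed``.

    Translation uses whole-frame phase correlation with subpixel
    refinement (1/20 px).  The richer kinds minimise the sum of squared
    intensity differences over the interior of the field by Gauss-Newton
    with analytic Jacobians, starting from the phase-correlation
    translation; a fit that diverges falls back to translation-only with
    a logged warning.
    """
    if kind not in TRANSFORM_KINDS:
        raise ConfigurationError(f"unknown transform kind {kind!r}")
    mov = _as_float_plane(moving, "moving")
    fix = _as_float_plane(fixed, "fixed")
    if mov.shape != fix.shape:
        raise ConfigurationError(
            f"moving {mov.shape} and fixed {fix.shape} differ in size"
        )

    shift, _, _ = phase_cross_correlation(
        fix, mov, upsample_factor=20, normalization=None
    )
    translation = TransformModel.translation(dx=float(shift[1]), dy=float(shift[0]))
    if kind == "translation":
        return translation

    matrix = _gauss_newton_fit(
        mov, fix, kind, init_shift=shift,
        presmooth=presmooth, margin_frac=margin_frac, max_iter=max_iter,
    )
    if matrix is None:
        logger.warning(
            "least-squares fit diverged for kind=%s; falling back to translation",
            kind,
        )
        return TransformModel(kind, translation.matrix)
    return TransformModel(kind, matrix)


def _gauss_newton_fit(
    mov: np.ndarray,
    fix: np.ndarray,
    kind: str,
    init_shift: np.ndarray,
    presmooth: float,
    margin_frac: float,
    max_iter: int,
) -> np.ndarray | None:
    """Fit the inverse map (fixed -> moving, row/col convention) by
    Gauss-Newton on intensity residuals; return the forward 3x3 matrix
    in x/y convention, or None when the fit diverges."""
    H, W = fix.shape
    movf = ndimage.gaussian_filter(mov, presmooth) if presmooth else mov
    fixf = ndimage.gaussian_filter(fix, presmooth) if presmooth else fix
    grad_r, grad_c = np.gradient(movf)
    my, mx = max(2, int(H * margin_frac)), max(2, int(W * margin_frac))
    rows, cols = np.mgrid[my : H - my, mx : W - mx]
    q = np.stack([rows.ravel(), cols.ravel()]).astype(np.float64)
    f = fixf[my : H - my, mx : W - mx].ravel()

    # parameter vector of the inverse map
    if kind == "affine":
        p = np.array([1.0, 0.0, -init_shift[0], 0.0, 1.0, -init_shift[1]])
    elif kind == "scaled_rotation":
        p = np.array([-init_shift[0], -init_shift[1], 0.0, 1.0])
    else:  # rigid
        p = np.array([-init_shift[0], -init_shift[1], 0.0])

    def inverse_rc(p: np.ndarray) -> np.ndarray:
        """2x3 row/col matrix of the inverse map."""
        if kind == "affine":
            return np.array([[p[0], p[1], p[2]], [p[3], p[4], p[5]]])
        theta = p[2]
        s = p[3] if kind == "scaled_rotation" else 1.0
        c, si = s * np.cos(theta), s * np.sin(theta)
        return np.array([[c, -si, p[0]], [si, c, p[1]]])

    for _ in range(max_iter):
        B = inverse_rc(p)
        mapped = B[:, :2] @ q + B[:, 2:3]
        inside = (
            (mapped[0] >= 2) & (mapped[0] <= H - 3)
            & (mapped[1] >= 2) & (mapped[1] <= W - 3)
        )
        if inside.sum() < 16 * len(p):
            return None
        coords = mapped[:, inside]
        r = ndimage.map_coordinates(movf, coords, order=3) - f[inside]
        g_r = ndimage.map_coordinates(grad_r, coords, order=3)
        g_c = ndimage.map_coordinates(grad_c, coords, order=3)
        qr, qc = q[0, inside], q[1, inside]
        if kind == "affine":
            J = np.stack([g_r * qr, g_r * qc, g_r, g_c * qr, g_c * qc, g_c], axis=1)
        else:
            theta = p[2]
            s = p[3] if kind == "scaled_rotation" else 1.0
            c, si = np.cos(theta), np.sin(theta)
            dr_dth = s * (-si * qr - c * qc)
            dc_dth = s * (c * qr - si * qc)
            cols_j = [g_r, g_c, g_r * dr_dth + g_c * dc_dth]
            if kind == "scaled_rotation":
                dr_ds = c * qr - si * qc
                dc_ds = si * qr + c * qc
                cols_j.append(g_r * dr_ds + g_c * dc_ds)
            J = np.stack(cols_j, axis=1)
        JtJ = J.T @ J
        try:
            dp = np.linalg.solve(
                JtJ + 1e-10 * np.trace(JtJ) * np.eye(len(p)), J.T @ r
            )
        except np.linalg.LinAlgError:
            return None
        p = p - dp
        if not np.all(np.isfinite(p)):
            return None
        if np.max(np.abs(dp)) < 1e-8:
            break

    B = inverse_rc(p)
    # convert the row/col inverse map into an x/y forward matrix
    inv_xy = np.eye(3)
    inv_xy[0, 0], inv_xy[0, 1], inv_xy[0, 2] = B[1, 1], B[1, 0], B[1, 2]
    inv_xy[1, 0], inv_xy[1, 1], inv_xy[1, 2] = B[0, 1], B[0, 0], B[0, 2]
    if abs(np.linalg.det(inv_xy[:2, :2])) < 1e-8:
        return None
    forward = np.linalg.inv(inv_xy)
    # reject wild solutions (the field of view is the natural scale)
    if TransformModel(kind, forward).max_displacement((H, W)) > max(H, W):
        return None
    return forward


def apply_transform(stack: FrameStack, t: int, model: TransformModel) -> FrameStack:
    """Resample frame ``t`` (all channels) under the model with bilinear
    interpolation; out-of-field pixels are zero-filled and the result is
    re-quantised to 8 bits by round-half-up."""
    if not 0 <= t < stack.T:
        raise ConfigurationError(f"frame index {t} out of range for T={stack.T}")
    inverse = model.inverse().as_skimage()
    frames = stack.frames.copy()
    frames[t] = _warp_uint8(stack.frames[t], inverse)
    return stack.with_frames(frames)


def _warp_uint8(frame: np.ndarray, inverse_map) -> np.ndarray:
    out = np.empty_like(frame)
    for c in range(frame.shape[-1]):
        warped = warp(
            frame[..., c].astype(np.float64),
            inverse_map,
            order=1,
            cval=0.0,
            preserve_range=True,
        )
        out[..., c] = np.clip(np.floor(warped + 0.5), 0, 255).astype(np.uint8)
    return out


def align_stack(
    stack: FrameStack, channel: str, kind: str = "translation"
) -> tuple[FrameStack, list[TransformModel]]:
    """Propagated alignment: frame 0 anchors; each later frame is
    registered onto its already-aligned predecessor on the named channel
    and the cumulative model applied to all channels.

    Returns the aligned stack and the per-frame cumulative models (the
    anchor's model is the identity).  A degenerate frame mid-sequence
    reuses the previous cumulative model with a logged warning.
    """
    if stack.T < 2:
        raise ConfigurationError("alignment needs at least two frames")
    c = stack.channel_names.index(channel) if channel in stack.channel_names else None
    if c is None:
        raise ConfigurationError(
            f"unknown channel {channel!r}; stack has {stack.channel_names}"
        )
    planes = stack.frames[..., c]
    aligned = stack.frames.copy()
    models: list[TransformModel] = [TransformModel.identity(kind)]
    prev_aligned_plane = planes[0].astype(np.float64)
    for t in range(1, stack.T):
        try:
            model = estimate_transform(planes[t], prev_aligned_plane, kind)
        except DegenerateFrameError:
            logger.warning(
                "degenerate frame at position %d; propagating previous model", t
            )
            model = models[-1]
        models.append(model)
        aligned[t] = _warp_uint8(stack.frames[t], model.inverse().as_skimage())
        prev_aligned_plane = aligned[t, ..., c].astype(np.float64)
    return stack.with_frames(aligned), models


def transforms_to_frame(
    models: list[TransformModel], origin_indices: np.ndarray
) -> pd.DataFrame:
    """Tabular export of per-frame cumulative models."""
    rows = []
    for origin, m in zip(origin_indices, models):
        rows.append({
            "origin_index": int(origin),
            "kind": m.kind,
            "dx": m.dx,
            "dy": m.dy,
            "rotation_rad": m.rotation,
            "scale": m.scale,
            **{f"m{i}{j}": m.matrix[i, j] for i in range(2) for j in range(3)},
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marker displacement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisplacementResult:
    """Marker track and per-frame displacement magnitudes.

    ``positions`` are (x, y) per retained frame; ``displacements_px[t]``
    is the distance moved between frames ``t-1`` and ``t`` (length T-1);
    ``total_px`` is their sum — the total artifactual displacement of the
    tracked object.  Micrometre columns are present when the pixel size
    is known.  ``truncated`` flags a track that left the usable field.
    """

    positions: np.ndarray
    displacements_px: np.ndarray
    total_px: float
    displacements_um: np.ndarray | None = None
    total_um: float | None = None
    truncated: bool = False

    def to_frame(self, origin_indices: np.ndarray) -> pd.DataFrame:
        n = len(self.positions)
        data = {
            "origin_index": np.asarray(origin_indices)[:n],
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "displacement_px": np.concatenate([[0.0], self.displacements_px]),
        }
        if self.displacements_um is not None:
            data["displacement_um"] = np.concatenate([[0.0], self.displacements_um])
        return pd.DataFrame(data)


def _quadratic_peak_offset(values: np.ndarray, idx: int) -> float:
    """Subpixel offset of a 1-D correlation peak by parabola fit."""
    if idx <= 0 or idx >= len(values) - 1:
        return 0.0
    left, centre, right = values[idx - 1], values[idx], values[idx + 1]
    denom = left - 2 * centre + right
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))


def displacement_series(
    stack: FrameStack,
    marker: tuple[float, float],
    channel: str,
    *,
    search_radius: int = 15,
    patch_radius: int = 5,
    pixel_size: float | None = None,
) -> DisplacementResult:
    """Track the intensity patch around ``marker`` (x, y) frame to frame by
    normalised cross-correlation within ``search_radius`` pixels, and sum
    the per-frame displacement magnitudes."""
    planes = stack.channel(channel).astype(np.float64)
    T, H, W = planes.shape
    x0, y0 = marker
    r, s = patch_radius, search_radius
    if not (r <= x0 < W - r and r <= y0 < H - r):
        raise ConfigurationError(f"marker {marker} (patch radius {r}) outside field")

    positions = [np.array([float(x0), float(y0)])]
    truncated = False
    for t in range(1, T):
        px, py = positions[-1]
        row, col = int(round(py)), int(round(px))
        template = planes[t - 1, row - r : row + r + 1, col - r : col + r + 1]
        top, left = row - r - s, col - r - s
        window = planes[t, max(0, top) : row + r + s + 1, max(0, left) : col + r + s + 1]
        if (
            template.shape != (2 * r + 1, 2 * r + 1)
            or window.shape[0] < template.shape[0]
            or window.shape[1] < template.shape[1]
            or template.std() == 0
        ):
            truncated = True
            break
        corr = match_template(window, template)
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        dy_sub = _quadratic_peak_offset(corr[:, peak[1]], peak[0])
        dx_sub = _quadratic_peak_offset(corr[peak[0], :], peak[1])
        new_y = max(0, top) + peak[0] + r + dy_sub
        new_x = max(0, left) + peak[1] + r + dx_sub
        if not (r <= new_x < W - r and r <= new_y < H - r):
            truncated = True
            break
        positions.append(np.array([new_x, new_y]))

    positions_arr = np.asarray(positions)
    steps = np.diff(positions_arr, axis=0)
    disp = np.hypot(steps[:, 0], steps[:, 1]) if len(steps) else np.empty(0)
    total = float(disp.sum())
    disp_um = total_um = None
    if pixel_size is not None:
        disp_um = disp * pixel_size
        total_um = total * pixel_size
    return DisplacementResult(
        positions=positions_arr,
        displacements_px=disp,
        total_px=total,
        displacements_um=disp_um,
        total_um=total_um,
        truncated=truncated,
    )
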