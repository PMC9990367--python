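"""Raw movie -> clean whole-frame ratio trace.

Four stages, mirroring standard practice for ratiometric biosensor
time-lapse data: (1) xy drift registration by frequency-domain
cross-correlation, (2) automatic tissue masking by Li's minimum
cross-entropy threshold on the time-averaged channel-sum image,
(3) masked ratio extraction as the ratio of channel means, and
(4) centred moving-average temporal smoothing of the ratio trace.

The analysis is whole-frame: a single static tissue mask, one trace per
movie.  Offsets are estimated on the channel-sum image and applied to
both channels, so the ratio is insensitive to the common shift; the
ratio-of-means estimator suppresses the noise amplification a mean of
per-pixel ratios would suffer at dim pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .render import MovieStack

__all__ = [
    "DriftPath",
    "TissueMask",
    "RatioTrace",
    "estimate_drift",
    "register_stack",
    "temporal_smooth",
    "li_threshold",
    "build_mask",
    "extract_ratio_trace",
    "process_movie",
]


@dataclass(frozen=True)
class DriftPath:
    """Per-frame offsets (dy, dx) relative to the reference frame."""

    offsets: np.ndarray  # (T, 2) int
    scores: np.ndarray   # (T,) normalized peak correlation
    reference_index: int = 0
    low_confidence: np.ndarray | None = None  # (T,) bool

    def __post_init__(self) -> None:
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must be (T, 2)")
        if len(self.scores) != len(self.offsets):
            raise ValueError("scores and offsets must have equal length")
        if tuple(self.offsets[self.reference_index]) != (0, 0):
            raise ValueError("reference frame offset must be (0, 0)")

    @property
    def max_abs_offset(self) -> int:
        return int(np.abs(self.offsets).max()) if len(self.offsets) else 0


@dataclass(frozen=True)
class TissueMask:
    mask: np.ndarray       # bool (H, W)
    threshold: float
    fraction: float        # masked pixels / total pixels

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("mask must be nonempty")


@dataclass(frozen=True)
class RatioTrace:
    """Whole-frame mean ratio per frame, uniformly sampled."""

    t: np.ndarray          # s
    r: np.ndarray          # ratio
    frame_rate: float      # Hz
    smoothing_window: int  # frames
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.t) != len(self.r):
            raise ValueError("t and r must have equal length")
        if not np.all(np.isfinite(self.r)) or np.any(self.r <= 0):
            raise ValueError("ratios must be finite and > 0")

    def __len__(self) -> int:
        return len(self.t)


# ----------------------------------------------------------------------
# registration

def _wrap_offsets(idx: np.ndarray, size: int) -> np.ndarray:
    """Map circular-correlation lags into the centred range (-size/2, size/2]."""
    return (idx + size // 2) % size - size // 2


def estimate_drift(
    frame: np.ndarray,
    reference: np.ndarray,
    *,
    score_floor: float = 0.3,
) -> tuple[tuple[int, int], float, bool]:
    """Integer offset of ``frame`` relative to ``reference``.

    Maximises the circular cross-correlation of the zero-mean images,
    computed in the frequency domain.  The score is the normalised
    correlation at the peak (1.0 for an exact copy).  Ties are broken
    toward the smallest Euclidean offset, then row-major order.

    Returns ``((dy, dx), score, low_confidence)`` where the flag marks a
    peak score below ``score_floor``.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    f0 = frame - frame.mean()
    r0 = reference - reference.mean()
    norm = np.linalg.norm(f0) * np.linalg.norm(r0)
    if norm == 0:
        raise ValueError("no structure to register (constant image)")
    corr = np.fft.ifft2(np.fft.fft2(f0) * np.conj(np.fft.fft2(r0))).real / norm

    peak = corr.max()
    # tolerance for float ties between equivalent peaks
    cand = np.argwhere(corr >= peak - 1e-12)
    h, w = corr.shape
    dy = _wrap_offsets(cand[:, 0], h)
    dx = _wrap_offsets(cand[:, 1], w)
    order = np.lexsort((dx, dy, dy**2 + dx**2))
    best = order[0]
    return (int(dy[best]), int(dx[best])), float(peak), bool(peak < score_floor)


def _shift_with_fill(img: np.ndarray, dy: int, dx: int, fill: float) -> tuple[np.ndarray, np.ndarray]:
    """Translate by (dy, dx), filling vacated pixels; returns (image, valid)."""
    out = np.full_like(img, fill)
    valid = np.zeros(img.shape, dtype=bool)
    h, w = img.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = img[ys_src, xs_src]
    valid[ys, xs] = True
    return out, valid


def register_stack(
    movie: MovieStack,
    *,
    reference: int | str = 0,
    score_floor: float = 0.3,
) -> tuple[MovieStack, DriftPath]:
    """Align a movie to a reference frame; returns the registered stack.

    Offsets are estimated per frame on the channel-sum image and the
    inverse shift applied to both channels.  Vacated pixels are filled
    with the frame's background estimate (median intensity) and flagged
    invalid so masked statistics can exclude them.
    """
    if movie.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    sums = movie.channel_sum()
    if reference == "mean":
        ref_img = sums.mean(axis=0)
        ref_idx = 0
    else:
        ref_idx = int(reference)
        ref_img = sums[ref_idx]

    n = movie.n_frames
    offsets = np.zeros((n, 2), dtype=int)
    scores = np.ones(n)
    lowconf = np.zeros(n, dtype=bool)
    num = np.empty_like(movie.numerator)
    den = np.empty_like(movie.denominator)
    valid = np.ones((n, *movie.shape), dtype=bool)
    for i in range(n):
        (dy, dx), score, low = estimate_drift(sums[i], ref_img, score_floor=score_floor)
        offsets[i] = (dy, dx)
        scores[i] = score
        lowconf[i] = low
        if dy == 0 and dx == 0:
            num[i] = movie.numerator[i]
            den[i] = movie.denominator[i]
        else:
            num[i], v = _shift_with_fill(movie.numerator[i], -dy, -dx, float(np.median(movie.numerator[i])))
            den[i], _ = _shift_with_fill(movie.denominator[i], -dy, -dx, float(np.median(movie.denominator[i])))
            valid[i] = v
    if reference != "mean":
        offsets[ref_idx] = (0, 0)
    path = DriftPath(offsets=offsets, scores=scores, reference_index=ref_idx, low_confidence=lowconf)
    meta = dict(movie.metadata)
    meta["registered"] = True
    out = MovieStack(numerator=num, denominator=den, frame_rate=movie.frame_rate, metadata=meta, valid=valid)
    return out, path


# ----------------------------------------------------------------------
# smoothing

def temporal_smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with symmetrically shrinking edge windows.

    At index ``i`` the half-width is ``min(window // 2, i, n - 1 - i)``,
    so no padding values are invented.  Window 1 is the identity.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    n = len(x)
    if window > n:
        raise ValueError("window exceeds series length")
    if window == 1:
        return x.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = (csum[i + k + 1] - csum[i - k]) / (2 * k + 1)
    return out


# ----------------------------------------------------------------------
# masking

def li_threshold(image: np.ndarray, *, tol: float = 0.5, max_iter: int = 200) -> float:
    """Li's minimum cross-entropy threshold.

    Fixed-point iteration ``t <- (mu_b - mu_f) / (ln mu_b - ln mu_f)``
    where ``mu_b`` / ``mu_f`` are the mean intensities below/above the
    current threshold, started at the image mean and stopped when the
    update moves less than ``tol`` intensity units.  The log form needs
    positive means, so non-positive images are shifted up by
    ``1 - min`` and the threshold shifted back.
    """
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = img.min(), img.max()
    if lo == hi:
        raise ValueError("threshold undefined for a constant image")
    shift = 0.0
    if lo <= 0:
        shift = 1.0 - lo
        img = img + shift
    t = img.mean()
    for _ in range(max_iter):
        back = img[img <= t]
        fore = img[img > t]
        if len(back) == 0 or len(fore) == 0:
            break
        mu_b, mu_f = back.mean(), fore.mean()
        if mu_b == mu_f:
            break
        t_new = (mu_b - mu_f) / (np.log(mu_b) - np.log(mu_f))
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t - shift)


def cross_entropy(image: np.ndarray, threshold: float) -> float:
    """Li's cross-entropy objective at a candidate threshold.

    ``sum_b x (ln x - ln mu_b) + sum_f x (ln x - ln mu_f)`` over the
    background/foreground partitions; the Li fixed point minimises it.
    Used as the brute-force oracle for the iterative threshold.
    """
    img = np.asarray(image, dtype=float).ravel()
    lo = img.min()
    if lo <= 0:
        img = img + (1.0 - lo)
        threshold = threshold + (1.0 - lo)
    back = img[img <= threshold]
    fore = img[img > threshold]
    if len(back) == 0 or len(fore) == 0:
        return np.inf
    return float(
        np.sum(back * (np.log(back) - np.log(back.mean())))
        + np.sum(fore * (np.log(fore) - np.log(fore.mean())))
    )


def build_mask(movie: MovieStack) -> TissueMask:
    """Static tissue mask from the time-averaged channel-sum image.

    The threshold is computed once on the temporal mean (pixels invalid
    in any frame are excluded) and applied globally, so the mask — and
    with it the trace — is stable over time.
    """
    mean_img = movie.channel_sum().mean(axis=0)
    always_valid = np.ones(movie.shape, dtype=bool) if movie.valid is None else movie.valid.all(axis=0)
    vals = mean_img[always_valid]
    if vals.size == 0 or vals.min() == vals.max():
        raise ValueError("no tissue detected (no contrast in the averaged image)")
    thr = li_threshold(vals)
    mask = (mean_img > thr) & always_valid
    if not mask.any():
        raise ValueError("no tissue detected (empty mask)")
    return TissueMask(mask=mask, threshold=thr, fraction=float(mask.sum()) / mask.size)


# ----------------------------------------------------------------------
# extraction

def extract_ratio_trace(
    movie: MovieStack,
    mask: TissueMask,
    window: int,
    *,
    meta: dict[str, Any] | None = None,
) -> RatioTrace:
    """Masked ratio-of-means trace, temporally smoothed.

    Per frame ``r = mean(numerator over mask) / mean(denominator over
    mask)``; pixels invalid that frame or with zero denominator are
    excluded from both means.  The trace is then smoothed with a
    centred moving average of ``window`` frames (11 for the lactate
    sensor, 5 for the glucose sensor by default upstream).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    n = movie.n_frames
    r = np.empty(n)
    n_pix = np.empty(n, dtype=int)
    for i in range(n):
        sel = mask.mask.copy()
        if movie.valid is not None:
            sel &= movie.valid[i]
        sel &= movie.denominator[i] > 0
        if not sel.any():
            raise ValueError(f"all masked denominator pixels zero or invalid in frame {i}")
        r[i] = movie.numerator[i][sel].mean() / movie.denominator[i][sel].mean()
        n_pix[i] = int(sel.sum())
    r_s = temporal_smooth(r, window)
    info = dict(movie.metadata)
    info.update(meta or {})
    info.update(mask_fraction=mask.fraction, n_masked_pixels=n_pix)
    return RatioTrace(
        t=movie.times,
        r=r_s,
        frame_rate=movie.frame_rate,
        smoothing_window=window,
        meta=info,
    )


def process_movie(
    movie: MovieStack,
    *,
    window: int,
    register: bool = True,
    reference: int | str = 0,
) -> tuple[RatioTrace, DriftPath | None, TissueMask]:
    """Register -> mask -> extract in one call."""
    path = None
    if register and movie.n_frames >= 2:
        movie, path = register_stack(movie, reference=reference)
    mask = build_mask(movie)
    trace = extract_ratio_trace(movie, mask, window)
    if path is not None:
        trace.meta["max_abs_offset"] = path.max_abs_offset
        trace.meta["min_registration_score"] = float(path.scores.min())
    return trace, path, mask
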