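"""Multi-scale Hessian descriptors and their weighted fusion.

At scale ``sigma`` the frame is convolved with sigma^2-normalized second
Gaussian derivatives; at each pixel the 2x2 Hessian has eigenvalues
ordered |lambda1| <= |lambda2|.  On a tubular structure |lambda1| ~ 0 and
|lambda2| is large, with sign depending on polarity (bright tube on dark
background: lambda2 < 0).

Two descriptors are combined:

* ``F1 = ln(lambda2^2 + 1)`` where ``lambda2 < -sqrt(2*pi)*sigma`` (else
  0) — a log-compressed response that avoids saturating wide intensity
  ranges, firing on bright tubes (negative lambda2);
* ``F2`` — a smooth rational response built from ``lambda2`` and a
  regularized surrogate ``lambda_r`` (the per-frame, per-scale maximum of
  the positive eigenvalue, optionally scaled by ``tau``), giving a
  uniform response at bends and bifurcations.  F2 uses the *positive*
  eigenvalue convention, so the pipeline feeds it the negated map.

The fused map is ``F = max_sigma(alpha1*F1_norm + alpha2*F2)``.  F1 is
unbounded while F2 lies in [0, 1], so F1 is min-max normalized across the
whole per-frame scale stack before the weighted sum — otherwise equal
weights would be meaningless.  Segmentation is a plain threshold on F
(scalar, or Otsu's method on the nonzero responses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    sigma_list: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0)
    alpha1: float = 0.5
    alpha2: float = 0.5
    tau: float = 1.0
    polarity: str = "bright_vessels"  # or "dark_vessels"
    threshold: float | str = "otsu"
    #: gray-level scale applied before Hessian analysis.  The F1 firing
    #: condition lambda2 < -sqrt(2 pi) sigma presumes 8-bit-like gray
    #: levels; on [0, 1] frames it would never trigger.
    intensity_scale: float = 255.0

    def validate(self) -> None:
        if len(self.sigma_list) == 0:
            raise FeatureError("sigma_list must not be empty")
        sig = np.asarray(self.sigma_list, dtype=float)
        if np.any(sig <= 0) or np.any(np.diff(sig) <= 0):
            raise FeatureError("sigma_list must be strictly increasing and positive")
        if not 0 < self.tau <= 1:
            raise FeatureError("tau must lie in (0, 1]")
        if self.polarity not in ("bright_vessels", "dark_vessels"):
            raise FeatureError(f"unknown polarity {self.polarity!r}")
        if not self.intensity_scale > 0:
            raise FeatureError("intensity_scale must be positive")
        if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-9:
            logger.info(
                "fusion weights alpha1 + alpha2 = %.3f != 1",
                self.alpha1 + self.alpha2,
            )


@dataclass
class HessianField:
    """Per-pixel scale-normalized Hessian and its eigen-decomposition."""

    sigma: float
    hxx: np.ndarray
    hxy: np.ndarray
    hyy: np.ndarray
    lambda1: np.ndarray  # |lambda1| <= |lambda2|
    lambda2: np.ndarray

    def eigenvectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit eigenvectors (v1 along the centerline, v2 normal).

        v2 belongs to lambda2; v1 is its orthogonal complement.  At
        isotropic pixels (hxy = 0, hxx = hyy) the axes are returned.
        """
        vx = self.hxy
        vy = self.lambda2 - self.hxx
        norm = np.hypot(vx, vy)
        degenerate = norm < 1e-12
        vx = np.where(degenerate, 1.0, vx)
        vy = np.where(degenerate, 0.0, vy)
        norm = np.where(degenerate, 1.0, norm)
        v2 = np.stack([vx / norm, vy / norm], axis=-1)
        v1 = np.stack([-v2[..., 1], v2[..., 0]], axis=-1)
        return v1, v2


def _gaussian_derivative_kernels(
    sigma: float, truncate: float = 4.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled Gaussian and its first/second derivative kernels.

    The second-derivative kernel is re-centred to exact zero sum so that
    a constant image has an exactly zero Hessian (the raw sampled kernel
    carries a small DC residual); the first-derivative kernel is odd and
    sums to zero by symmetry.
    """
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    g1 = -x / sigma**2 * g
    g2 = (x**2 - sigma**2) / sigma**4 * g
    g2 -= g2.mean()
    return g, g1, g2


def hessian_at_scale(
    frame: np.ndarray, sigma: float, truncate: float = 4.0
) -> HessianField:
    """sigma^2-normalized Gaussian-derivative Hessian of one frame.

    Kernels are truncated at ``truncate`` sigma with reflect boundary.
    Eigenvalues of the symmetric 2x2 matrix are computed in closed form
    and ordered by magnitude.
    """
    if not sigma > 0:
        raise FeatureError("sigma must be positive")
    frame = np.asarray(frame, dtype=np.float64)
    g, g1, g2 = _gaussian_derivative_kernels(sigma, truncate)

    def sep(kx, ky):
        out = ndimage.correlate1d(frame, kx, axis=1, mode="reflect")
        return ndimage.correlate1d(out, ky, axis=0, mode="reflect")

    norm = sigma**2
    hxx = norm * sep(g2, g)
    hyy = norm * sep(g, g2)
    hxy = norm * sep(g1, g1)
    # eigenvalues of [[hxx, hxy], [hxy, hyy]]
    mean = 0.5 * (hxx + hyy)
    radius = np.sqrt(0.25 * (hxx - hyy) ** 2 + hxy**2)
    ev_lo, ev_hi = mean - radius, mean + radius
    swap = np.abs(ev_lo) > np.abs(ev_hi)
    lambda1 = np.where(swap, ev_hi, ev_lo)
    lambda2 = np.where(swap, ev_lo, ev_hi)
    return HessianField(
        sigma=sigma, hxx=hxx, hxy=hxy, hyy=hyy, lambda1=lambda1, lambda2=lambda2
    )


def f1_descriptor(lambda2_map: np.ndarray, sigma: float) -> np.ndarray:
    """Log-compressed tube response: ln(lambda2^2 + 1) below -sqrt(2 pi) sigma."""
    lam = np.asarray(lambda2_map, dtype=np.float64)
    fire = lam < -SQRT_2PI * sigma
    return np.where(fire, np.log(lam**2 + 1.0), 0.0)


def lambda_r_field(lambda2_map: np.ndarray, tau: float = 1.0) -> np.ndarray:
    """Regularized eigenvalue surrogate.

    With ``m`` the per-map maximum of lambda2 and cutoff ``c = tau*m``:
    lambda_r = lambda2 where lambda2 > c, the cutoff where
    0 < lambda2 <= c, and 0 where lambda2 <= 0.  At tau = 1 the first
    case is empty and every positive pixel receives the shared maximum.
    """
    if not 0 < tau <= 1:
        raise FeatureError("tau must lie in (0, 1]")
    lam = np.asarray(lambda2_map, dtype=np.float64)
    out = np.zeros_like(lam)
    pos = lam > 0
    if not np.any(pos):
        return out
    cutoff = tau * float(lam.max())
    above = pos & (lam > cutoff)
    out[above] = lam[above]
    out[pos & ~above] = cutoff
    return out


def f2_descriptor(
    lambda2_map: np.ndarray, lambda_r_map: np.ndarray
) -> np.ndarray:
    """Uniform-response descriptor in [0, 1].

    0 where both eigen-quantities are non-positive; 1 where
    lambda2 >= lambda_r/2 > 0; else
    lambda2^2 (lambda_r - lambda2) (3/(lambda_r + lambda2))^3, clipped.
    The else-branch tends to 1 as lambda2 -> lambda_r/2, so the response
    is continuous across that boundary.
    """
    lam = np.asarray(lambda2_map, dtype=np.float64)
    lr = np.asarray(lambda_r_map, dtype=np.float64)
    if lam.shape != lr.shape:
        raise FeatureError("lambda2 and lambda_r maps must share a shape")
    zero_branch = (lam <= 0) & (lr <= 0)
    one_branch = (lam >= lr / 2.0) & (lr > 0)
    denom = lam + lr
    safe = np.abs(denom) > 1e-300
    body = np.zeros_like(lam)
    np.divide(3.0, denom, out=body, where=safe)
    body = lam**2 * (lr - lam) * body**3
    out = np.where(zero_branch, 0.0, np.where(one_branch, 1.0, body))
    return np.clip(out, 0.0, 1.0)


@dataclass
class FeatureMaps:
    """All intermediate per-scale maps plus the fused response."""

    sigmas: tuple[float, ...]
    f1: np.ndarray        # (S, h, w) raw log responses
    f1_norm: np.ndarray   # (S, h, w) min-max normalized over the stack
    f2: np.ndarray        # (S, h, w)
    lambda_r: np.ndarray  # (S, h, w)
    fused: np.ndarray     # (h, w)
    best_sigma: np.ndarray = field(default=None)  # argmax scale per pixel


def fuse_multiscale(frame: np.ndarray, config: FeatureConfig) -> FeatureMaps:
    """Fused multi-scale response of one enhanced frame.

    The frame is oriented so vessels are bright; lambda2 then goes
    directly into F1 (which fires on negative values) and negated into
    lambda_r / F2 (which use the positive convention).
    """
    config.validate()
    frame = np.asarray(frame, dtype=np.float64)
    work = -frame if config.polarity == "dark_vessels" else frame
    work = work * config.intensity_scale

    sigmas = tuple(float(s) for s in config.sigma_list)
    f1_stack, f2_stack, lr_stack = [], [], []
    for sigma in sigmas:
        hess = hessian_at_scale(work, sigma)
        f1_stack.append(f1_descriptor(hess.lambda2, sigma))
        lam_pos = -hess.lambda2
        # floor rounding noise so flat regions cannot saturate the
        # ratio-based branches of F2 (signal eigenvalues are O(1)-O(100))
        lam_pos[np.abs(lam_pos) < 1e-8] = 0.0
        lr = lambda_r_field(lam_pos, config.tau)
        lr_stack.append(lr)
        f2_stack.append(f2_descriptor(lam_pos, lr))
    f1 = np.stack(f1_stack)
    f2 = np.stack(f2_stack)
    lr = np.stack(lr_stack)

    lo, hi = float(f1.min()), float(f1.max())
    f1_norm = (f1 - lo) / (hi - lo) if hi > lo else np.zeros_like(f1)

    combined = config.alpha1 * f1_norm + config.alpha2 * f2
    fused = combined.max(axis=0)
    best = np.asarray(sigmas)[combined.argmax(axis=0)]
    return FeatureMaps(
        sigmas=sigmas,
        f1=f1,
        f1_norm=f1_norm,
        f2=f2,
        lambda_r=lr,
        fused=fused,
        best_sigma=best,
    )


def threshold_segment(
    F: np.ndarray, threshold: float | str = "otsu"
) -> np.ndarray:
    """Binary segmentation ``F >= t``.

    ``threshold='otsu'`` picks t by Otsu's method over the *nonzero*
    responses (the zero background would otherwise dominate the
    histogram).  A response map without positive values yields an empty
    mask.
    """
    F = np.asarray(F, dtype=np.float64)
    if not np.all(np.isfinite(F)):
        raise FeatureError("non-finite values in response map")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise FeatureError(f"unknown threshold rule {threshold!r}")
        nonzero = F[F > 0]
        if nonzero.size == 0:
            return np.zeros_like(F, dtype=bool)
        if np.unique(nonzero).size < 2:
            return F > 0
        t = float(threshold_otsu(nonzero))
    else:
        t = float(threshold)
    return F >= t
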