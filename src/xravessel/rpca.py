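"""Online low-rank + sparse decomposition of angiographic difference frames.

The difference sequence ``DI`` (top-hat filtered angiogram) is modelled per
frame as a quasi-static non-vascular component plus a sparse vascular
component.  Instead of batch nuclear-norm RPCA, the low-rank part is
factorized explicitly, ``B = Lr @ Ce.T``, so frames can be processed one at
a time:

* inter-frame pass — a single basis ``Lr`` (D x r) evolves across frames.
  For each frame the coefficients ``Ce`` and sparse part ``E`` are solved
  with the *previous* basis, then the basis is updated from accumulated
  sufficient statistics.  The coupling through ``Lr`` is the inter-frame
  constraint: quasi-static content is absorbed into the subspace, moving
  vessels remain in ``E``.

* intra-frame pass — each frame independently, with the basis fixed to an
  all-ones matrix.  Because the columns are identical, the "low-rank" part
  is a spatially constant offset per frame; the sparse residual ``V`` is
  the final enhanced vascular image over a flattened background.

Per frame both passes minimise the convex objective

    1/2 ||x - Lr Ce - E||^2  +  (lambda1/2) ||Ce||^2  +  lambda2 ||E||_1

by exact alternation: a ridge solve for ``Ce`` and elementwise soft
thresholding for ``E``; the objective is non-increasing across iterations.
The regularizers default to the empirical rule ``2.1 / max(M1, M2)`` with
``M1, M2`` the frame dimensions, and the rank bound defaults to r = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .sequence import ImageSequence


class RpcaError(ValueError):
    pass


@dataclass(frozen=True)
class RpcaConfig:
    """Regularization and solver settings for both decomposition passes.

    ``lambda*`` fields left as None are resolved to ``2.1 / max(M1, M2)``
    once the frame shape is known (see :meth:`resolved`).
    """

    rank_r: int = 5
    rank_r_prime: int = 5
    lambda1: float | None = None
    lambda2: float | None = None
    lambda1_prime: float | None = None
    lambda2_prime: float | None = None
    max_inner_iters: int = 100
    tol: float = 1e-6
    seed: int = 0
    clip_negative: bool = True  # applied by the pipeline, not by the solvers

    def validate(self) -> None:
        if self.rank_r < 1 or self.rank_r_prime < 1:
            raise RpcaError("rank bounds must be >= 1")
        for name in ("lambda1", "lambda2", "lambda1_prime", "lambda2_prime"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise RpcaError(f"{name} must be positive")
        if not self.tol > 0:
            raise RpcaError("tol must be positive")
        if self.max_inner_iters < 1:
            raise RpcaError("max_inner_iters must be >= 1")

    def resolved(self, frame_shape: tuple[int, int]) -> "RpcaConfig":
        """Fill unset regularizers from the frame size rule 2.1/max(M1, M2)."""
        self.validate()
        lam = 2.1 / float(max(frame_shape))
        return replace(
            self,
            lambda1=self.lambda1 if self.lambda1 is not None else lam,
            lambda2=self.lambda2 if self.lambda2 is not None else lam,
            lambda1_prime=self.lambda1_prime
            if self.lambda1_prime is not None
            else lam,
            lambda2_prime=self.lambda2_prime
            if self.lambda2_prime is not None
            else lam,
        )


def soft_threshold(x: np.ndarray | float, t: float) -> np.ndarray | float:
    """Proximal operator of t*||.||_1: sign(x) * max(|x| - t, 0)."""
    if t < 0:
        raise RpcaError("soft threshold must be non-negative")
    x = np.asarray(x, dtype=np.float64)
    out = np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
    return out if out.ndim else float(out)


def frame_objective(
    frame_vec: np.ndarray,
    Lr: np.ndarray,
    Ce: np.ndarray,
    E: np.ndarray,
    lambda1: float,
    lambda2: float,
) -> float:
    resid = frame_vec - Lr @ Ce - E
    return float(
        0.5 * resid @ resid
        + 0.5 * lambda1 * Ce @ Ce
        + lambda2 * np.abs(E).sum()
    )


def solve_frame(
    frame_vec: np.ndarray,
    Lr: np.ndarray,
    lambda1: float,
    lambda2: float,
    max_inner_iters: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and sparse part of one frame for a fixed basis.

    Alternates the exact block minimisers
    ``Ce = (Lr'Lr + lambda1 I)^-1 Lr' (x - E)`` and
    ``E = soft_threshold(x - Lr Ce, lambda2)`` until the relative change
    of (Ce, E) drops below ``tol`` or ``max_inner_iters`` is reached.
    """
    frame_vec = np.asarray(frame_vec, dtype=np.float64).ravel()
    Lr = np.asarray(Lr, dtype=np.float64)
    if frame_vec.shape[0] != Lr.shape[0]:
        raise RpcaError(
            f"frame length {frame_vec.shape[0]} != basis rows {Lr.shape[0]}"
        )
    if not (np.all(np.isfinite(frame_vec)) and np.all(np.isfinite(Lr))):
        raise RpcaError("non-finite values in solver input")
    r = Lr.shape[1]
    gram = Lr.T @ Lr + lambda1 * np.eye(r)
    # gram is SPD for lambda1 > 0; factor once per frame
    chol = np.linalg.cholesky(gram)

    Ce = np.zeros(r)
    E = np.zeros_like(frame_vec)
    for _ in range(max_inner_iters):
        rhs = Lr.T @ (frame_vec - E)
        Ce_new = np.linalg.solve(chol.T, np.linalg.solve(chol, rhs))
        E_new = soft_threshold(frame_vec - Lr @ Ce_new, lambda2)
        num = np.linalg.norm(Ce_new - Ce) + np.linalg.norm(E_new - E)
        den = np.linalg.norm(Ce_new) + np.linalg.norm(E_new) + 1e-12
        Ce, E = Ce_new, E_new
        if num / den < tol:
            break
    return Ce, E


@dataclass
class BasisState:
    """Streaming state of the inter-frame pass.

    ``stat_A`` (r x r) accumulates coefficient outer products, ``stat_B``
    (D x r) accumulates residual-coefficient products; together they are
    the sufficient statistics of the quadratic surrogate the basis update
    minimises.
    """

    Lr: np.ndarray
    stat_A: np.ndarray
    stat_B: np.ndarray
    frames_seen: int = 0

    @classmethod
    def initialize(cls, D: int, r: int, seed: int = 0) -> "BasisState":
        """Random basis, entries N(0, 1/D); deterministic under the seed."""
        rng = np.random.default_rng(seed)
        Lr = rng.standard_normal((D, r)) / np.sqrt(D)
        return cls(
            Lr=Lr, stat_A=np.zeros((r, r)), stat_B=np.zeros((D, r)), frames_seen=0
        )

    @property
    def rank(self) -> int:
        return self.Lr.shape[1]

    def save(self, path: str | Path) -> None:
        """Checkpoint to a flat binary (.npz) plus a small text manifest."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            Lr=self.Lr,
            stat_A=self.stat_A,
            stat_B=self.stat_B,
            frames_seen=self.frames_seen,
        )
        path.with_suffix(".manifest.txt").write_text(
            f"D: {self.Lr.shape[0]}\nr: {self.Lr.shape[1]}\n"
            f"frames_seen: {self.frames_seen}\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "BasisState":
        data = np.load(Path(path).with_suffix(".npz"))
        return cls(
            Lr=data["Lr"],
            stat_A=data["stat_A"],
            stat_B=data["stat_B"],
            frames_seen=int(data["frames_seen"]),
        )


def surrogate_cost(state: BasisState, lambda1: float) -> float:
    """Quadratic surrogate the basis update minimises (up to a constant):
    1/2 tr(Lr' Lr (A + lambda1 I)) - tr(Lr' B)."""
    A = state.stat_A + lambda1 * np.eye(state.rank)
    return float(
        0.5 * np.trace(state.Lr.T @ state.Lr @ A)
        - np.trace(state.Lr.T @ state.stat_B)
    )


def update_basis(
    state: BasisState,
    frame_vec: np.ndarray,
    Ce: np.ndarray,
    E: np.ndarray,
    lambda1: float,
) -> BasisState:
    """Fold one frame into the statistics and refresh the basis.

    One pass of exact block-coordinate descent over basis columns on the
    ridge-regularized surrogate; the surrogate cost never increases.  If
    the statistics are still all zero (a frame carried no coefficient
    information), the basis is left untouched.
    """
    frame_vec = np.asarray(frame_vec, dtype=np.float64).ravel()
    if frame_vec.shape[0] != state.Lr.shape[0] or Ce.shape[0] != state.rank:
        raise RpcaError("shape mismatch between state and frame data")
    stat_A = state.stat_A + np.outer(Ce, Ce)
    stat_B = state.stat_B + np.outer(frame_vec - E, Ce)
    Lr = state.Lr.copy()
    if np.any(stat_A) or np.any(stat_B):
        A_bar = stat_A + lambda1 * np.eye(state.rank)
        for j in range(state.rank):
            # exact minimiser over column j of the surrogate
            Lr[:, j] += (stat_B[:, j] - Lr @ A_bar[:, j]) / A_bar[j, j]
    return BasisState(
        Lr=Lr, stat_A=stat_A, stat_B=stat_B, frames_seen=state.frames_seen + 1
    )


def inter_frame_rpca(
    DI: ImageSequence,
    config: RpcaConfig,
    state: BasisState | None = None,
) -> tuple[ImageSequence, ImageSequence, BasisState]:
    """Single streaming pass over the difference sequence.

    For each frame: solve the per-frame problem with the current basis,
    then update the basis once.  Returns the low-rank reconstruction
    ``B_i = Lr_i @ Ce_i``, the sparse vascular component ``E``, and the
    final basis state (so a stream can be resumed).  Deterministic given
    the config seed.
    """
    if len(DI) == 0:
        raise RpcaError("empty sequence")
    h, w = DI.frame_shape
    cfg = config.resolved((h, w))
    D = h * w
    if state is None:
        state = BasisState.initialize(D, cfg.rank_r, seed=cfg.seed)
    elif state.Lr.shape != (D, cfg.rank_r):
        raise RpcaError("resumed basis state does not match frame shape/rank")
    B_frames = np.empty_like(DI.frames)
    E_frames = np.empty_like(DI.frames)
    for i, frame in enumerate(DI.frames):
        x = frame.ravel()
        Ce, E = solve_frame(
            x, state.Lr, cfg.lambda1, cfg.lambda2, cfg.max_inner_iters, cfg.tol
        )
        state = update_basis(state, x, Ce, E, cfg.lambda1)
        B_frames[i] = (state.Lr @ Ce).reshape(h, w)
        E_frames[i] = E.reshape(h, w)
    return DI.copy_with(B_frames), DI.copy_with(E_frames), state


def intra_frame_rpca(DIprime: ImageSequence, config: RpcaConfig) -> ImageSequence:
    """Per-frame decomposition against a fixed all-ones basis.

    All basis columns are identical, so the low-rank term is a spatially
    constant offset per frame (the ridge makes the coefficient solve
    well-posed despite the rank-1 Gram matrix); the sparse residual is the
    final enhanced vascular frame over a flattened background.  No state
    crosses frames.
    """
    if len(DIprime) == 0:
        raise RpcaError("empty sequence")
    h, w = DIprime.frame_shape
    cfg = config.resolved((h, w))
    D = h * w
    ones = np.ones((D, cfg.rank_r_prime))
    V_frames = np.empty_like(DIprime.frames)
    for i, frame in enumerate(DIprime.frames):
        _, E = solve_frame(
            frame.ravel(),
            ones,
            cfg.lambda1_prime,
            cfg.lambda2_prime,
            cfg.max_inner_iters,
            cfg.tol,
        )
        V_frames[i] = E.reshape(h, w)
    return DIprime.copy_with(V_frames)
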