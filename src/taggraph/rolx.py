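"""Role discovery (RolX-style) by nonnegative matrix factorization.

The stacked, normalized node-time feature matrix V (rows = (tag, month)
pairs, columns = structural features) is factorized as V ≈ W·H with W, H
nonnegative: W holds the role relevance of every node-time for each of r
roles, H the definition of each role in feature space. The number of roles
is selected by a minimum-description-length score — bits for the quantized
factors plus bits for the residual under a Gaussian code — so the choice is
deterministic, not an elbow heuristic.

The factorization uses Frobenius multiplicative updates with a best-of
strategy over seeded random initializations plus one SVD-based nonnegative
initialization, and supports warm starts, which makes the best fit error
non-increasing in r when the search chains r -> r+1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refex import FeatureTensor

logger = logging.getLogger(__name__)

__all__ = [
    "RoleModel",
    "factorize",
    "select_num_roles",
    "select_rank",
    "role_relevance",
    "mdl_score",
    "MissingRowError",
]

MAX_ITER = 500
REL_TOL = 1e-6
_EPS = 1e-12

DEFAULT_R_MIN = 2
DEFAULT_R_MAX = 8
DEFAULT_RESTARTS = 3


class MissingRowError(KeyError):
    """A (tag, month) pair absent from the model (tag not in that snapshot)."""


@dataclass
class RoleModel:
    """Nonnegative factors of the node-time feature matrix.

    ``W`` is (n_rows, r) role relevance, ``H`` is (r, n_features) role
    definitions; ``rows`` aligns W's rows with (month, tag) pairs. Raw W
    feeds the correlation analysis; the row-normalized ``mixtures`` feed
    trajectory outputs.
    """

    r: int
    W: np.ndarray
    H: np.ndarray
    rows: pd.MultiIndex
    feature_names: list[str]
    months: list[str]
    fit_error: float
    seed: int = 0
    restarts: int = DEFAULT_RESTARTS

    def __post_init__(self) -> None:
        if self.W.min() < 0 or self.H.min() < 0:
            raise ValueError("factors must be nonnegative")
        if self.W.shape != (len(self.rows), self.r):
            raise ValueError("W shape inconsistent with rows/r")
        if self.H.shape != (self.r, len(self.feature_names)):
            raise ValueError("H shape inconsistent with r/features")

    @property
    def mixtures(self) -> np.ndarray:
        """W rows normalized to sum 1; all-zero rows stay all-zero."""
        sums = self.W.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mix = np.where(sums > 0, self.W / np.where(sums > 0, sums, 1.0), 0.0)
        return mix

    def row_position(self, tag: str, month: str) -> int:
        try:
            return self.rows.get_loc((month, tag))
        except KeyError:
            raise MissingRowError(f"tag {tag!r} absent in month {month}") from None

    def role_relevance(self, tag: str, role: int, month: str) -> float:
        """Raw W entry for (tag, month) and role; missing rows raise."""
        if not 0 <= role < self.r:
            raise ValueError(f"role {role} out of range [0, {self.r})")
        return float(self.W[self.row_position(tag, month), role])

    def mixture(self, tag: str, month: str) -> np.ndarray:
        return self.mixtures[self.row_position(tag, month)]

    def w_frame(self) -> pd.DataFrame:
        cols = [f"role_{k}" for k in range(self.r)]
        out = pd.DataFrame(self.W, index=self.rows, columns=cols).reset_index()
        return out[["tag", "month"] + cols]

    def h_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.H, columns=self.feature_names)
        out.insert(0, "role", range(self.r))
        return out


def _mu_fit(
    V: np.ndarray, W0: np.ndarray, H0: np.ndarray, max_iter: int = MAX_ITER, tol: float = REL_TOL
) -> tuple[np.ndarray, np.ndarray, float]:
    """Frobenius multiplicative updates from a given initialization.

    Zero entries of the initialization stay exactly zero (multiplicative
    fixed point), which warm starts rely on.
    """
    W, H = W0.copy(), H0.copy()
    err_prev = None
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(V - W @ H))
        if err_prev is not None and abs(err_prev - err) <= tol * max(err_prev, _EPS):
            err_prev = err
            break
        err_prev = err
    return W, H, float(np.linalg.norm(V - W @ H))


def _nndsvd_init(V: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray]:
    """SVD-based nonnegative initialization (NNDSVD with average fill)."""
    u, s, vt = np.linalg.svd(V, full_matrices=False)
    n, m = V.shape
    W = np.zeros((n, r))
    H = np.zeros((r, m))
    W[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    H[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for k in range(1, min(r, len(s))):
        x, y = u[:, k], vt[k]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        pos = np.linalg.norm(xp) * np.linalg.norm(yp)
        neg = np.linalg.norm(xn) * np.linalg.norm(yn)
        if pos >= neg and pos > 0:
            W[:, k] = np.sqrt(s[k] * pos) * xp / np.linalg.norm(xp)
            H[k] = np.sqrt(s[k] * pos) * yp / np.linalg.norm(yp)
        elif neg > 0:
            W[:, k] = np.sqrt(s[k] * neg) * xn / np.linalg.norm(xn)
            H[k] = np.sqrt(s[k] * neg) * yn / np.linalg.norm(yn)
    fill = V.mean() / max(r, 1)
    W[W == 0] = fill
    H[H == 0] = fill
    return W, H


def _factor_matrix(
    V: np.ndarray,
    r: int,
    seed: int,
    restarts: int,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of fit: `restarts` random inits, one NNDSVD init, optional warm start."""
    if np.isnan(V).any():
        raise ValueError("feature matrix contains NaN")
    n, m = V.shape
    if not 1 <= r <= min(n, m):
        raise ValueError(f"r={r} out of range [1, {min(n, m)}]")
    scale = np.sqrt(max(V.mean(), _EPS) / r)
    inits: list[tuple[np.ndarray, np.ndarray]] = []
    seeds = np.random.SeedSequence(seed).spawn(restarts)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        inits.append((scale * rng.random((n, r)), scale * rng.random((r, m))))
    inits.append(_nndsvd_init(V, r))
    if warm is not None:
        inits.append(warm)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for W0, H0 in inits:
        W, H, err = _mu_fit(V, W0, H0)
        if best is None or err < best[2]:
            best = (W, H, err)
    if warm is not None:
        # the warm point itself is admissible: guarantees the chained fit
        # error never exceeds the previous rank's error
        err_w = float(np.linalg.norm(V - warm[0] @ warm[1]))
        if err_w < best[2]:
            best = (warm[0].copy(), warm[1].copy(), err_w)
    assert best is not None
    return best


def factorize(
    tensor: FeatureTensor,
    r: int,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> RoleModel:
    """Fit an r-role model to a normalized feature tensor.

    Deterministic given (tensor, r, seed, restarts): the random restarts are
    seeded, the NNDSVD init is deterministic, and the best final Frobenius
    error wins.
    """
    if not tensor.normalized:
        raise ValueError("tensor must be normalized before factorization")
    V = tensor.values.to_numpy(dtype=float)
    W, H, err = _factor_matrix(V, r, seed, restarts, warm)
    return RoleModel(
        r=r,
        W=W,
        H=H,
        rows=tensor.values.index,
        feature_names=list(tensor.feature_names),
        months=list(tensor.months),
        fit_error=err,
        seed=seed,
        restarts=restarts,
    )


def role_relevance(model: RoleModel, tag: str, role: int, month: str) -> float:
    """Raw role relevance W[(tag, month), role]; absent rows raise
    :class:`MissingRowError` (the tag was not in that month's snapshot)."""
    return model.role_relevance(tag, role, month)


def mdl_score(V: np.ndarray, W: np.ndarray, H: np.ndarray, bins: int = 16) -> float:
    """Description length in bits: quantized factors plus Gaussian-coded residual.

    Model cost: log2(bins) bits per factor entry, with entries stored on
    log2-spaced bin centers. Error cost: the fit residual encoded with a
    Gaussian of matched variance, N/2 * log2(2*pi*e*sigma^2), floored to keep
    the log finite (the usual two-part-code approximation: the residual term
    uses the fitted factors, the quantizer prices their storage).
    """
    model_bits = np.log2(bins) * (W.size + H.size)
    resid = V - W @ H
    n = V.size
    sigma2 = max(float(np.mean(resid**2)), 1e-12)
    error_bits = 0.5 * n * np.log2(2.0 * np.pi * np.e * sigma2)
    return float(model_bits + error_bits)


def select_num_roles(
    tensor: FeatureTensor,
    r_min: int = DEFAULT_R_MIN,
    r_max: int = DEFAULT_R_MAX,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    return_scores: bool = False,
):
    """Pick the role count minimizing the MDL score over [r_min, r_max].

    Fits are warm-started along the chain r -> r+1 (previous best factors
    padded with a zero role), so the best fit error is non-increasing in r.
    Ties resolve to the smaller r. The full score table is logged.
    """
    V = tensor.values.to_numpy(dtype=float)
    return select_rank(V, r_min, r_max, seed=seed, restarts=restarts, return_scores=return_scores)


def select_rank(
    V: np.ndarray,
    r_min: int,
    r_max: int,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    return_scores: bool = False,
):
    """Matrix-level MDL rank selection (see :func:`select_num_roles`)."""
    if not 1 <= r_min <= r_max:
        raise ValueError(f"need 1 <= r_min <= r_max, got [{r_min}, {r_max}]")
    warm = None
    table: list[tuple[int, float, float]] = []
    best_r, best_score = r_min, np.inf
    for r in range(r_min, min(r_max, min(V.shape)) + 1):
        W, H, err = _factor_matrix(V, r, seed, restarts, warm)
        score = mdl_score(V, W, H)
        table.append((r, err, score))
        logger.info("role selection: r=%d fit_error=%.6g mdl_bits=%.6g", r, err, score)
        if score < best_score:
            best_r, best_score = r, score
        warm = (np.hstack([W, np.zeros((W.shape[0], 1))]), np.vstack([H, np.zeros((1, H.shape[1]))]))
    if return_scores:
        return best_r, table
    return best_r
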