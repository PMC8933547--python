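"""Non-negative matrix factorization of speckle frame stacks.

The flattened stack I (pixels x frames) is approximated as W @ H with
W >= 0 the per-emitter fingerprints and H >= 0 the per-frame illumination
weights, by minimising the squared Frobenius residual with multiplicative
updates (which guarantee a monotone objective).  The factorisation rank is
picked by scanning candidate ranks and locating the knee of the RMS
residual curve.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .simulate import FrameStack, GroundTruth

__all__ = [
    "FactorizationResult",
    "RankScan",
    "MatchResult",
    "flatten_stack",
    "unflatten_stack",
    "nmf_factorize",
    "estimate_rank",
    "match_to_truth",
]

_EPS = 1e-12


def flatten_stack(stack: FrameStack | np.ndarray) -> np.ndarray:
    """Flatten a (T, H, W) stack into the (H*W, T) data matrix.

    Column t is frame t raveled in row-major order, so pixel (i, j) of
    frame t lands at I[i * W + j, t].  The reshape is exactly invertible
    by :func:`unflatten_stack`.
    """
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    if frames.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    T = frames.shape[0]
    return frames.reshape(T, -1).T


def unflatten_stack(I: np.ndarray, frame_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`flatten_stack`: (H*W, T) back to (T, H, W)."""
    H, W = frame_shape
    if I.shape[0] != H * W:
        raise ValueError("matrix row count does not match frame_shape")
    return I.T.reshape(-1, H, W)


@dataclasses.dataclass(frozen=True)
class FactorizationResult:
    """NMF output.  Columns of ``fingerprints`` are normalised to unit
    maximum, with the scale absorbed into ``weights``; columns whose peak
    is below 1e-12 of the data maximum are flagged in ``dead``."""

    fingerprints: np.ndarray  # (r, rank) W
    weights: np.ndarray  # (rank, T) H
    final_residual: float  # Frobenius norm of I - WH
    objective_trace: np.ndarray  # squared Frobenius residual per iteration
    iterations_run: int
    converged: bool
    dead: np.ndarray  # (rank,) bool

    @property
    def rank(self) -> int:
        return self.fingerprints.shape[1]

    def live_fingerprints(self) -> np.ndarray:
        return self.fingerprints[:, ~self.dead]


@dataclasses.dataclass(frozen=True)
class RankScan:
    ranks: np.ndarray
    rms_residuals: np.ndarray  # ||I - WH||_F / sqrt(r * t) per rank
    chosen_rank: int
    criterion: str

    def __post_init__(self) -> None:
        if self.chosen_rank not in list(self.ranks):
            raise ValueError("chosen_rank must be one of the scanned ranks")


def _objective(I: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    R = I - W @ H
    return float(np.einsum("ij,ij->", R, R))


def nmf_factorize(
    I: np.ndarray,
    rank: int,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    dtype=np.float64,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> FactorizationResult:
    """Multiplicative-update NMF of the non-negative matrix ``I``.

    Random uniform initialisation scaled to the data norm (or an explicit
    non-negative ``init = (W0, H0)``); stops when the relative decrease of
    the squared Frobenius objective drops below ``tol`` (converged=True)
    or after ``max_iter`` iterations.
    """
    I = np.asarray(I, dtype=dtype)
    if I.ndim != 2:
        raise ValueError("I must be a matrix")
    if np.any(~np.isfinite(I)):
        raise ValueError("I contains non-finite entries")
    if np.any(I < 0):
        raise ValueError("I contains negative entries")
    r, t = I.shape
    if not 1 <= rank <= min(r, t):
        raise ValueError(f"rank must be in [1, {min(r, t)}]")

    if init is not None:
        W0, H0 = init
        if W0.shape != (r, rank) or H0.shape != (rank, t):
            raise ValueError("init factor shapes do not match")
        if np.any(W0 < 0) or np.any(H0 < 0):
            raise ValueError("init factors must be non-negative")
        W = np.asarray(W0, dtype=dtype).copy()
        H = np.asarray(H0, dtype=dtype).copy()
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
        scale = np.sqrt(max(I.mean(), _EPS) / rank)
        W = rng.uniform(0.0, 1.0, (r, rank)).astype(dtype) * scale
        H = rng.uniform(0.0, 1.0, (rank, t)).astype(dtype) * scale

    trace = np.empty(max_iter + 1)
    trace[0] = _objective(I, W, H)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # standard Lee-Seung multiplicative updates for the Frobenius loss
        H *= (W.T @ I) / (W.T @ W @ H + _EPS)
        W *= (I @ H.T) / (W @ (H @ H.T) + _EPS)
        trace[it] = _objective(I, W, H)
        prev = trace[it - 1]
        if prev > 0 and (prev - trace[it]) / prev < tol:
            converged = True
            break
    trace = trace[: it + 1]

    # gauge fixing: unit-max fingerprint columns, scale absorbed into H
    peak = W.max(axis=0)
    dead = peak < 1e-12 * max(I.max(), _EPS)
    safe = np.where(peak > 0, peak, 1.0)
    W = W / safe[None, :]
    H = H * safe[:, None]

    return FactorizationResult(
        fingerprints=np.ascontiguousarray(W, dtype=np.float64),
        weights=np.ascontiguousarray(H, dtype=np.float64),
        final_residual=float(np.sqrt(trace[-1])),
        objective_trace=trace,
        iterations_run=it,
        converged=converged,
        dead=dead,
    )


def estimate_rank(
    I: np.ndarray,
    rank_min: int = 1,
    rank_max: int = 12,
    restarts: int = 3,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    ranks: list[int] | None = None,
    criterion: str = "knee",
    knee_frac: float = 0.03,
    threshold_frac: float = 0.05,
    dtype=np.float32,
) -> RankScan:
    """Scan candidate ranks and choose one from the RMS residual curve.

    Each rank is fitted from ``restarts`` random initialisations plus a
    warm start built from the best previous-rank solution with one extra
    small random component, which keeps the residual curve monotone
    non-increasing in rank (nested model classes).  Because the raw
    residual is monotone, literal minimisation is degenerate; the
    ``knee`` criterion walks up the ranks while each step still improves
    the RMS residual by at least ``knee_frac`` (relative) and stops at
    the first step that does not.  The ``threshold`` criterion picks the
    smallest rank whose RMS drops below ``threshold_frac`` of the rank-1
    RMS.  The full scan is returned for inspection.
    """
    if ranks is None:
        if rank_max < rank_min:
            raise ValueError("rank_max must be >= rank_min")
        ranks = list(range(rank_min, rank_max + 1))
    ranks = sorted(set(int(k) for k in ranks))
    if len(ranks) == 0 or ranks[0] < 1:
        raise ValueError("ranks must be positive")
    I = np.asarray(I)
    r, t = I.shape
    norm = np.sqrt(r * t)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 203]))
    rms = np.empty(len(ranks))
    carry: tuple[np.ndarray, np.ndarray] | None = None  # best factors so far
    for i, k in enumerate(ranks):
        best = np.inf
        best_factors = None
        inits: list[tuple[np.ndarray, np.ndarray] | None] = [
            None for _ in range(max(restarts, 1))
        ]
        if carry is not None:
            Wp, Hp = carry
            extra = k - Wp.shape[1]
            if extra > 0:
                scale = 1e-3 * np.sqrt(max(I.mean(), _EPS) / k)
                W0 = np.hstack([Wp, scale * rng.random((r, extra))])
                H0 = np.vstack([Hp, scale * rng.random((extra, t))])
                inits.append((W0, H0))
        for s, init in enumerate(inits):
            res = nmf_factorize(
                I, k, max_iter=max_iter, tol=tol,
                seed=seed + 1000 * s, dtype=dtype, init=init,
            )
            if res.final_residual < best:
                best = res.final_residual
                best_factors = (res.fingerprints, res.weights)
        rms[i] = best / norm
        carry = best_factors

    chosen = _select_rank(np.array(ranks), rms, criterion, knee_frac, threshold_frac)
    return RankScan(
        ranks=np.array(ranks),
        rms_residuals=rms,
        chosen_rank=chosen,
        criterion=criterion,
    )


def _select_rank(
    ranks: np.ndarray,
    rms: np.ndarray,
    criterion: str,
    knee_frac: float,
    threshold_frac: float,
) -> int:
    if criterion == "threshold":
        below = np.nonzero(rms <= threshold_frac * max(rms[0], _EPS))[0]
        return int(ranks[below[0]]) if below.size else int(ranks[-1])
    if criterion != "knee":
        raise ValueError("criterion must be 'knee' or 'threshold'")
    if len(ranks) == 1:
        return int(ranks[0])
    # near-exact fit: stop at the first rank that explains the data
    floor = 1e-6 * max(rms[0], _EPS)
    exact = np.nonzero(rms <= floor)[0]
    if exact.size:
        return int(ranks[exact[0]])
    # walk up while each step still buys >= knee_frac improvement,
    # measured against the overall scale of the residual curve (the
    # rank-1 RMS) so the criterion is not fooled by relative changes of
    # an already tiny residual
    scale = max(rms[0], _EPS)
    chosen = ranks[0]
    for i in range(1, len(ranks)):
        if (rms[i - 1] - rms[i]) / scale < knee_frac:
            break
        chosen = ranks[i]
    return int(chosen)


@dataclasses.dataclass(frozen=True)
class MatchResult:
    """Greedy assignment of factor columns to ground-truth fingerprints."""

    permutation: np.ndarray  # (P,) index into W columns, -1 if truth unmatched
    scores: np.ndarray  # (P,) correlation of each truth fingerprint's match
    unmatched_columns: np.ndarray  # W columns not assigned to any truth

    @property
    def mean_score(self) -> float:
        valid = self.scores[self.permutation >= 0]
        return float(valid.mean()) if valid.size else 0.0


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns of A and columns of B."""
    A = A - A.mean(axis=0, keepdims=True)
    B = B - B.mean(axis=0, keepdims=True)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (A / na).T @ (B / nb)


def match_to_truth(
    result: FactorizationResult | np.ndarray,
    truth: GroundTruth | np.ndarray,
    score_threshold: float = 0.5,
) -> MatchResult:
    """Greedily match estimated fingerprint columns to true fingerprints
    by maximum Pearson correlation (one-to-one)."""
    W = result.fingerprints if isinstance(result, FactorizationResult) else result
    Wt = truth.fingerprints if isinstance(truth, GroundTruth) else truth
    C = _corr_matrix(Wt, W)  # (P, rank)
    P, rank = C.shape
    perm = np.full(P, -1, dtype=int)
    scores = np.zeros(P)
    avail_t = set(range(P))
    avail_c = set(range(rank))
    work = C.copy()
    for _ in range(min(P, rank)):
        ti, ci = np.unravel_index(np.argmax(work), work.shape)
        if work[ti, ci] < score_threshold:
            break
        perm[ti] = ci
        scores[ti] = C[ti, ci]
        avail_t.discard(int(ti))
        avail_c.discard(int(ci))
        work[ti, :] = -np.inf
        work[:, ci] = -np.inf
    return MatchResult(
        permutation=perm,
        scores=scores,
        unmatched_columns=np.array(sorted(avail_c), dtype=int),
    )
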