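"""Sammon non-linear mapping of a distance matrix into 2D/3D.

Sammon's stress weights each pair's squared distance error by the inverse
of its original distance,

    E = [1 / sum_{i<j} d*_ij] * sum_{i<j} (d*_ij - d_ij)^2 / d*_ij,

so the preservation of short distances is favored over long ones. The
minimizer is Sammon's diagonal second-order descent with a step ("magic")
factor alpha and step halving, run from multiple starts; axes of the
result are arbitrary (any rotation, reflection or translation leaves E
unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from seqspace.errors import ValidationError
from seqspace.seqio import DistanceMatrix

_EPS = 1e-12


@dataclass(frozen=True)
class EmbedConfig:
    """Settings for :func:`sammon_embed`.

    k: target dimension (2 or 3). seed: base seed for the random restarts.
    restarts: independent starts; the best final stress wins. alpha:
    Sammon's step factor. init: 'classical' seeds the first start with
    Torgerson metric MDS, 'random' reproduces the historical all-random
    behavior.
    """

    k: int = 3
    seed: int = 0
    restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-9
    alpha: float = 0.3
    init: str = "classical"

    def __post_init__(self) -> None:
        if self.k not in (2, 3):
            raise ValidationError("target dimension k must be 2 or 3")
        if self.restarts < 1:
            raise ValidationError("restarts must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError("alpha must be in (0, 1]")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.init not in ("classical", "random"):
            raise ValidationError(f"unknown init {self.init!r}")


@dataclass(frozen=True)
class EmbeddingResult:
    """A sequence-space map: coordinates, final stress and optimizer trace."""

    labels: tuple[str, ...]
    coords: np.ndarray
    stress: float
    n_iter: int
    converged: bool
    restart_stresses: tuple[float, ...]
    seed: int
    trace: tuple[float, ...] = field(default=(), repr=False)

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def coords_of(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]


def _stress_arrays(coords: np.ndarray, dstar: np.ndarray) -> float:
    iu = np.triu_indices(dstar.shape[0], 1)
    ds = dstar[iu]
    d = pdist(coords)
    c = ds.sum()
    return float(((ds - d) ** 2 / ds).sum() / c)


def sammon_stress(coords: np.ndarray, dm: DistanceMatrix | np.ndarray) -> float:
    """Sammon stress E of a configuration against original distances."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("non-finite coordinates")
    dstar = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    if coords.shape[0] != dstar.shape[0]:
        raise ValidationError("coordinate count does not match distance matrix")
    iu = np.triu_indices(dstar.shape[0], 1)
    if np.any(dstar[iu] <= 0):
        raise ValidationError(
            "zero off-diagonal distance; merge duplicate points first"
        )
    return _stress_arrays(coords, dstar)


def classical_mds(dstar: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric MDS: spectral embedding of the double-centered Gram."""
    n = dstar.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dstar**2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[order], 0.0, None)
    x = eigvec[:, order] * np.sqrt(lam)[None, :]
    if x.shape[1] < k:  # degenerate rank
        x = np.pad(x, ((0, 0), (0, k - x.shape[1])))
    return x


def _sammon_descent(
    x0: np.ndarray,
    dstar: np.ndarray,
    alpha: float,
    max_iter: int,
    tol: float,
    free_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float], bool]:
    """Sammon's diagonal-Newton descent with step halving.

    ``free_mask`` restricts updates to a subset of points (used when
    overlaying internal tree nodes onto frozen leaf coordinates). The
    returned stress trace is non-increasing.
    """
    x = x0.copy()
    n = x.shape[0]
    iu = np.triu_indices(n, 1)
    c = dstar[iu].sum()
    if free_mask is None:
        free_mask = np.ones(n, dtype=bool)

    def stress_of(xx: np.ndarray) -> float:
        return _stress_arrays(xx, dstar)

    trace = [stress_of(x)]
    converged = False
    for _ in range(max_iter):
        d = squareform(pdist(x))
        np.fill_diagonal(d, 1.0)
        d = np.maximum(d, _EPS)
        ds = dstar.copy()
        np.fill_diagonal(ds, 1.0)

        delta = ds - d
        w1 = delta / (d * ds)
        np.fill_diagonal(w1, 0.0)
        diff = x[:, None, :] - x[None, :, :]          # (n, n, k)
        grad = (-2.0 / c) * np.einsum("ij,ijq->iq", w1, diff)

        w2 = 1.0 / (d * ds)
        np.fill_diagonal(w2, 0.0)
        term = delta[:, :, None] - (diff**2 / d[:, :, None]) * (
            1.0 + delta[:, :, None] / d[:, :, None]
        )
        hess = (-2.0 / c) * np.einsum("ijq->iq", w2[:, :, None] * term)

        step = alpha * grad / np.maximum(np.abs(hess), _EPS)
        step[~free_mask] = 0.0

        prev = trace[-1]
        scale = 1.0
        accepted = None
        for _half in range(21):
            cand = x - scale * step
            s = stress_of(cand)
            if s <= prev:
                accepted = (cand, s)
                break
            scale /= 2.0
        if accepted is None:
            converged = True
            break
        x, s = accepted
        trace.append(s)
        if prev > 0 and (prev - s) / prev < tol:
            converged = True
            break
        if s < 1e-30:
            converged = True
            break
    return x, trace, converged


def _merge_duplicates(dm: DistanceMatrix) -> tuple[list[int], dict[int, int]]:
    """Group indices at zero mutual distance; return representatives and map."""
    n = dm.n
    rep_of: dict[int, int] = {}
    reps: list[int] = []
    for i in range(n):
        for r in reps:
            if dm.values[i, r] == 0.0:
                rep_of[i] = r
                break
        else:
            reps.append(i)
            rep_of[i] = i
    return reps, rep_of


def sammon_embed(dm: DistanceMatrix, cfg: EmbedConfig | None = None) -> EmbeddingResult:
    """Embed a distance matrix into k dimensions by Sammon mapping.

    Duplicate taxa (zero original distance) are merged into one point for
    the optimization — the 1/d* weight is undefined at 0 — and re-attached
    at their representative's coordinates afterward. Fully reproducible
    from the config seed; the best of ``restarts`` starts is returned.
    """
    cfg = cfg or EmbedConfig()
    reps, rep_of = _merge_duplicates(dm)
    sub = dm.values[np.ix_(reps, reps)]
    m = len(reps)
    if m <= cfg.k:
        if m < 2:
            raise ValidationError("need at least 2 distinct points to embed")
        # fewer distinct points than dimensions: still well-posed
    rng = np.random.default_rng(cfg.seed)
    scale = sub[np.triu_indices(m, 1)].mean() if m > 1 else 1.0

    best: tuple[float, np.ndarray, list[float], bool] | None = None
    restart_stresses: list[float] = []
    for r in range(cfg.restarts):
        if r == 0 and cfg.init == "classical":
            x0 = classical_mds(sub, cfg.k)
        else:
            x0 = rng.normal(scale=scale if scale > 0 else 1.0, size=(m, cfg.k))
        x, trace, conv = _sammon_descent(
            x0, sub, cfg.alpha, cfg.max_iter, cfg.tol
        )
        final = trace[-1]
        restart_stresses.append(final)
        if best is None or final < best[0]:
            best = (final, x, trace, conv)

    stress, x, trace, conv = best
    coords = np.zeros((dm.n, cfg.k))
    rep_index = {orig: pos for pos, orig in enumerate(reps)}
    for i in range(dm.n):
        coords[i] = x[rep_index[rep_of[i]]]
    coords.setflags(write=False)
    return EmbeddingResult(
        labels=dm.labels,
        coords=coords,
        stress=_stress_arrays(x, sub),
        n_iter=len(trace) - 1,
        converged=conv,
        restart_stresses=tuple(restart_stresses),
        seed=cfg.seed,
        trace=tuple(trace),
    )


def shepard_data(coords: np.ndarray, dm: DistanceMatrix) -> list[tuple[float, float]]:
    """(original, embedded) distance pairs for a Shepard diagnostic scatter."""
    coords = np.asarray(coords, dtype=float)
    iu = np.triu_indices(dm.n, 1)
    ds = dm.values[iu]
    d = pdist(coords)
    return list(zip(ds.tolist(), d.tolist()))
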