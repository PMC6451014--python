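"""Pairwise evolutionary distances between aligned protein sequences.

Three estimators are provided:

``p``
    observed difference fraction (no correction),
``poisson``
    -ln(1 - p), the equal-rates correction,
``dayhoff_ml``
    the maximum-likelihood divergence t under the Dayhoff model: the t
    maximizing sum_sites ln(pi_a P_ab(t)) over comparable columns, the
    quantity protdist computes in its Dayhoff-PAM mode.

Gaps and ``X`` are excluded column-wise (pairwise deletion by default).
Distances beyond ``D_MAX`` = 10 substitutions/site are capped and the pair
is flagged as saturated so downstream consumers stay total.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from seqspace.errors import ConvergenceError, ValidationError
from seqspace.models import AA_ORDER, SubstitutionModel, transition_matrix
from seqspace.seqio import DistanceMatrix, Msa

#: cap (expected substitutions/site) applied to saturated or ML distances
D_MAX = 10.0

#: p beyond this is treated as saturated for the Poisson correction
_P_SAT = 1.0 - 1e-9

_CODE = {aa: i for i, aa in enumerate(AA_ORDER)}
_MISSING = 255  # code for gap or X


@dataclass(frozen=True)
class PairSiteSummary:
    """Column bookkeeping for one aligned pair (pairwise deletion applied)."""

    n_compared: int
    n_diff: int

    @property
    def p(self) -> float:
        return self.n_diff / self.n_compared


def encode_row(row: str) -> np.ndarray:
    """Map a sequence string to integer codes; gap/X become a missing code."""
    out = np.full(len(row), _MISSING, dtype=np.uint8)
    for i, ch in enumerate(row):
        out[i] = _CODE.get(ch, _MISSING)
    return out


def p_distance(a: str, b: str, policy: str = "pairwise_deletion") -> PairSiteSummary:
    """Observed difference fraction between two aligned rows.

    Columns where either row has a gap or ``X`` are dropped. On an isolated
    pair the two deletion policies coincide; ``complete_deletion`` across a
    whole alignment is applied by :func:`distance_matrix`.
    """
    if len(a) != len(b):
        raise ValidationError("rows differ in length")
    if policy not in ("pairwise_deletion", "complete_deletion"):
        raise ValueError(f"unknown gap policy {policy!r}")
    ca, cb = encode_row(a.upper()), encode_row(b.upper())
    mask = (ca != _MISSING) & (cb != _MISSING)
    n_comp = int(mask.sum())
    if n_comp == 0:
        raise ValidationError("no comparable columns between the two rows")
    n_diff = int((ca[mask] != cb[mask]).sum())
    return PairSiteSummary(n_compared=n_comp, n_diff=n_diff)


def poisson_distance(p: float, d_max: float = D_MAX) -> float:
    """Poisson-corrected distance d = -ln(1 - p); saturates to ``d_max``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"difference fraction must be in [0, 1], got {p}")
    if p >= _P_SAT:
        return d_max
    return min(-math.log1p(-p), d_max)


def _pair_counts(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """20x20 counts of comparable aligned residue pairs."""
    mask = (ca != _MISSING) & (cb != _MISSING)
    if not mask.any():
        raise ValidationError("no comparable columns between the two rows")
    flat = ca[mask].astype(np.int64) * 20 + cb[mask]
    return np.bincount(flat, minlength=400).reshape(20, 20).astype(float)


def _pair_loglik(counts: np.ndarray, model: SubstitutionModel, t: float) -> float:
    p = transition_matrix(model, t)
    ai, bi = np.nonzero(counts)
    vals = model.pi[ai] * p[ai, bi]
    if np.any(vals <= 0):
        return -np.inf
    return float((counts[ai, bi] * np.log(vals)).sum())


def pam_ml_distance(
    a: str,
    b: str,
    model: SubstitutionModel,
    d_max: float = D_MAX,
    xatol: float = 1e-6,
    max_evals: int = 500,
) -> tuple[float, float]:
    """ML divergence of an aligned pair under a reversible model.

    Maximizes the site-product likelihood over t in [0, d_max] by bounded
    scalar optimization; the boundary values are checked explicitly so that
    identical pairs return exactly 0 and saturated ones exactly ``d_max``.
    Returns ``(t_hat, logL)``. The substitution-count matrix is
    canonicalized against its transpose (the model is reversible, so the
    likelihood is direction-symmetric), making the result exactly
    invariant to both argument order and column order.
    """
    ca, cb = encode_row(a.upper()), encode_row(b.upper())
    counts = _canonical_counts(_pair_counts(ca, cb))
    return _ml_from_counts(counts, model, d_max, xatol, max_evals)


def _canonical_counts(counts: np.ndarray) -> np.ndarray:
    flat, flat_t = counts.ravel(), counts.T.ravel()
    for x, y in zip(flat, flat_t):
        if x != y:
            return counts if x < y else counts.T.copy()
    return counts


def _ml_from_counts(
    counts: np.ndarray,
    model: SubstitutionModel,
    d_max: float,
    xatol: float = 1e-6,
    max_evals: int = 500,
) -> tuple[float, float]:
    def neg_ll(t: float) -> float:
        return -_pair_loglik(counts, model, t)

    res = minimize_scalar(
        neg_ll,
        bounds=(0.0, d_max),
        method="bounded",
        options={"xatol": xatol, "maxiter": max_evals},
    )
    if not res.success:
        raise ConvergenceError(
            f"ML distance optimizer did not converge (last t={res.x:g})"
        )
    candidates = [(float(res.x), -float(res.fun))]
    for t_edge in (0.0, d_max):
        candidates.append((t_edge, _pair_loglik(counts, model, t_edge)))
    t_hat, logl = max(candidates, key=lambda c: c[1])
    return t_hat, logl


def distance_matrix(
    msa: Msa,
    method: str = "dayhoff_ml",
    model: SubstitutionModel | None = None,
    gap_policy: str = "pairwise_deletion",
    d_max: float = D_MAX,
) -> DistanceMatrix:
    """All-pairs distance matrix for an alignment.

    Every pair is computed independently (deterministic, symmetric by
    construction); pairs at the cap are recorded in ``saturated``.
    """
    if msa.n_taxa < 2:
        raise ValidationError("need at least two taxa")
    if method not in ("dayhoff_ml", "poisson", "p"):
        raise ValueError(f"unknown distance method {method!r}")
    if method == "dayhoff_ml" and model is None:
        from seqspace.models import build_dayhoff_model

        model = build_dayhoff_model()

    codes = [encode_row(row) for row in msa.rows]
    if gap_policy == "complete_deletion":
        keep = np.ones(msa.n_sites, dtype=bool)
        for c in codes:
            keep &= c != _MISSING
        if not keep.any():
            raise ValidationError("complete deletion removed every column")
        codes = [c[keep] for c in codes]
    elif gap_policy != "pairwise_deletion":
        raise ValueError(f"unknown gap policy {gap_policy!r}")

    n = msa.n_taxa
    mat = np.zeros((n, n))
    saturated: set[frozenset[str]] = set()
    for i, j in itertools.combinations(range(n), 2):
        ca, cb = codes[i], codes[j]
        mask = (ca != _MISSING) & (cb != _MISSING)
        n_comp = int(mask.sum())
        if n_comp == 0:
            raise ValidationError(
                f"no comparable columns between {msa.taxa[i]!r} and {msa.taxa[j]!r}"
            )
        if method in ("p", "poisson"):
            p_obs = float((ca[mask] != cb[mask]).sum()) / n_comp
            if method == "p":
                d = p_obs
                sat = False
            else:
                d = poisson_distance(p_obs, d_max)
                sat = p_obs >= _P_SAT
        else:
            # canonical orientation: reversibility makes the likelihood
            # direction-symmetric, so this only pins down the fp rounding
            d, _ = _ml_from_counts(
                _canonical_counts(_pair_counts(ca, cb)), model, d_max
            )
            sat = d >= d_max
        mat[i, j] = mat[j, i] = d
        if sat:
            saturated.add(frozenset((msa.taxa[i], msa.taxa[j])))
    return DistanceMatrix(tuple(msa.taxa), mat, frozenset(saturated))
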