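"""Empirical amino-acid substitution model (Dayhoff/PAM).

The model is a time-reversible continuous-time Markov chain on the 20
amino acids. Its rate matrix is assembled from the classic Dayhoff (1978)
exchangeabilities S_ab and stationary frequencies pi, shipped as a text
resource in the PAML ``.dat`` layout (lower-triangle S, then pi, amino
acids in the order ARNDCQEGHILKMFPSTWYV):

    Q_ab = scale * S_ab * pi_b   (a != b),  Q_aa = -sum_{b != a} Q_ab

with ``scale`` chosen so the mean rate -sum_a pi_a Q_aa equals 1, i.e.
divergence t is measured in expected substitutions per site. PAM250
corresponds to the high-divergence regime of this same process; distances
are estimated per pair rather than read off a fixed score matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from seqspace.errors import ValidationError

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: sha256 of the shipped dayhoff.dat, guarding against resource corruption
_DAYHOFF_SHA256 = "e84f9ff0b675954c6d81f1f5bb80e94275c4b8b29cc59643f030d5a7f7b627dd"


@dataclass(frozen=True)
class SubstitutionModel:
    """Normalized reversible rate matrix Q with stationary frequencies pi."""

    q: np.ndarray
    pi: np.ndarray
    name: str
    scale: float
    # eigendecomposition of the pi-symmetrized rate matrix, cached for P(t)
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(
        repr=False, compare=False, default=None
    )

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if q.shape != (20, 20) or pi.shape != (20,):
            raise ValidationError("model must be 20x20 with 20 frequencies")
        if np.any(pi <= 0):
            raise ValidationError("stationary frequencies must be positive")
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValidationError("stationary frequencies must sum to 1")
        off = q[~np.eye(20, dtype=bool)]
        if np.any(off < 0):
            raise ValidationError("negative off-diagonal rate")
        if np.max(np.abs(q.sum(axis=1))) > 1e-10:
            raise ValidationError("rate-matrix rows must sum to 0")
        flux = pi[:, None] * q
        if np.max(np.abs(flux - flux.T)) > 1e-8:
            raise ValidationError("model is not time-reversible")
        if abs(-(pi * np.diag(q)).sum() - 1.0) > 1e-10:
            raise ValidationError("mean substitution rate must be 1")
        q.setflags(write=False)
        pi.setflags(write=False)
        # A = D^{1/2} Q D^{-1/2} is symmetric for reversible Q: exact
        # eigendecomposition gives a numerically stable P(t) at any t.
        sqrt_pi = np.sqrt(pi)
        a = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        a = (a + a.T) / 2.0
        eigval, eigvec = np.linalg.eigh(a)
        left = eigvec / sqrt_pi[:, None]       # D^{-1/2} V
        right = (eigvec * sqrt_pi[:, None]).T  # V^T D^{1/2}
        object.__setattr__(self, "_eig", (eigval, left, right))

    @property
    def n_states(self) -> int:
        return 20


def _load_dayhoff_dat() -> tuple[np.ndarray, np.ndarray]:
    raw = resources.files("seqspace.data").joinpath("dayhoff.dat").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _DAYHOFF_SHA256:
        raise ValidationError(
            "dayhoff.dat resource checksum mismatch; package data corrupted"
        )
    tokens = raw.decode().split()
    need = 190 + 20
    if len(tokens) != need:
        raise ValidationError("dayhoff.dat: unexpected token count")
    vals = np.array([float(t) for t in tokens])
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = vals[k]
            k += 1
    pi = vals[190:]
    pi = pi / pi.sum()
    return s, pi


def build_dayhoff_model() -> SubstitutionModel:
    """Construct the unit-mean-rate Dayhoff rate model."""
    s, pi = _load_dayhoff_dat()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(pi * np.diag(q)).sum()
    scale = 1.0 / mean_rate
    q = q * scale
    return SubstitutionModel(q=q, pi=pi, name="dayhoff", scale=scale)


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via the cached symmetric eigendecomposition.

    Rows sum to 1; tiny negative entries from round-off are clamped to 0.
    """
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"divergence must be finite and >= 0, got {t}")
    eigval, left, right = model._eig
    p = (left * np.exp(eigval * t)) @ right
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def transition_matrices(model: SubstitutionModel, ts: np.ndarray) -> np.ndarray:
    """P(t) for a vector of divergences, shape (len(ts), 20, 20)."""
    ts = np.asarray(ts, dtype=float)
    if np.any(~np.isfinite(ts)) or np.any(ts < 0):
        raise ValueError("divergences must be finite and >= 0")
    eigval, left, right = model._eig
    ew = np.exp(ts[:, None] * eigval[None, :])           # (T, 20)
    p = np.einsum("av,tv,vb->tab", left, ew, right, optimize=True)
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=2, keepdims=True)
    return p
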