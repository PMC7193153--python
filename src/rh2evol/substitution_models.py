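"""Empirical amino-acid substitution models (JTT, WAG, Dayhoff).

A model is a pair (S, pi): a symmetric 20x20 exchangeability matrix and a
stationary frequency vector, shipped as plain-text data files in the
de-facto interchange layout (19 lines of lower-triangle exchangeabilities
followed by the 20 frequencies).  ``build_rate_matrix`` turns a model into
a reversible rate matrix Q with Q[i,j] = S[i,j]*pi[j], rescaled so the mean
substitution rate at stationarity is exactly 1 — branch lengths are then in
expected substitutions per site.  ``transition_probabilities`` computes
P(t) = exp(Qt) through the symmetrized eigendecomposition that
reversibility affords.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .alphabet import AMINO_ACIDS, N_STATES

__all__ = [
    "EmpiricalModel",
    "RateMatrix",
    "available_models",
    "get_model",
    "build_rate_matrix",
    "transition_probabilities",
]

# md5 of the packaged data files; guards against silent corruption of the
# published constants.
_MODEL_FILES = {
    "JTT": ("jtt.dat", "411dc1660d66883bcc90488bc67a8efe"),
    "WAG": ("wag.dat", "424df387a5b7229ce07c1b1e204f051c"),
    "Dayhoff": ("dayhoff.dat", "74b254e820fbbfa8cecbe8ac4e98360c"),
}


@dataclass(frozen=True)
class EmpiricalModel:
    """A named reversible empirical model: exchangeabilities + frequencies."""

    name: str
    exchangeabilities: np.ndarray  # symmetric 20x20, zero diagonal
    frequencies: np.ndarray  # length-20 probability vector

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (N_STATES, N_STATES):
            raise ValueError(f"exchangeability matrix must be 20x20, got {S.shape}")
        if not np.allclose(S, S.T, rtol=0, atol=1e-12):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(np.diag(S) != 0):
            raise ValueError("exchangeability matrix must have a zero diagonal")
        if np.any(S < 0):
            raise ValueError("exchangeabilities must be nonnegative")
        _validate_frequencies(pi)
        object.__setattr__(self, "exchangeabilities", S)
        object.__setattr__(self, "frequencies", pi)


def _validate_frequencies(pi: np.ndarray) -> None:
    if pi.shape != (N_STATES,):
        raise ValueError(f"frequency vector must have length 20, got shape {pi.shape}")
    if np.min(pi) <= 0:
        bad = AMINO_ACIDS[int(np.argmin(pi))]
        raise ValueError(f"all frequencies must be positive (offending state: {bad})")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1, got {pi.sum():.8f}")


def available_models() -> list[str]:
    return list(_MODEL_FILES)


def _parse_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    values = [float(tok) for tok in text.split()]
    if len(values) != 190 + 20:
        raise ValueError(f"expected 190 exchangeabilities + 20 frequencies, got {len(values)} numbers")
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.array(values[190:])
    pi = pi / pi.sum()  # printed frequencies carry rounding; renormalize
    return S, pi


def get_model(name: str) -> EmpiricalModel:
    """Load one of the shipped models ('JTT', 'WAG', 'Dayhoff')."""
    key = {m.lower(): m for m in _MODEL_FILES}.get(name.lower())
    if key is None:
        raise KeyError(f"unknown model {name!r}; available: {', '.join(_MODEL_FILES)}")
    fname, md5 = _MODEL_FILES[key]
    data = resources.files("rh2evol.data").joinpath(fname).read_bytes()
    digest = hashlib.md5(data).hexdigest()
    if digest != md5:
        raise RuntimeError(f"model file {fname} failed its checksum ({digest} != {md5})")
    S, pi = _parse_dat(data.decode())
    return EmpiricalModel(name=key, exchangeabilities=S, frequencies=pi)


@dataclass
class RateMatrix:
    """Normalized reversible rate matrix with cached eigendecomposition.

    ``Q`` has rows summing to zero and mean rate -sum(pi_i Q_ii) == 1, so a
    branch length t is the expected number of substitutions per site.
    """

    Q: np.ndarray
    pi: np.ndarray
    scale: float = 1.0
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def eig(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, left factor, right factor) of the symmetrized Q.

        With D = diag(sqrt(pi)), B = D Q D^-1 is symmetric; B = U L U^T and
        P(t) = D^-1 U exp(Lt) U^T D.  Returns (L, D^-1 U, U^T D).
        """
        if self._eig is None:
            sq = np.sqrt(self.pi)
            B = (self.Q * sq[:, None]) / sq[None, :]
            B = 0.5 * (B + B.T)  # kill round-off asymmetry
            lam, U = np.linalg.eigh(B)
            left = U / sq[:, None]
            right = U.T * sq[None, :]
            self._eig = (lam, left, right)
        return self._eig


def build_rate_matrix(
    model: EmpiricalModel, frequencies_override: np.ndarray | None = None
) -> RateMatrix:
    """Construct the mean-rate-one rate matrix for a model.

    If ``frequencies_override`` is given (e.g. alignment-empirical "+F"
    frequencies) it replaces the model's published frequencies.
    """
    if frequencies_override is not None:
        pi = np.asarray(frequencies_override, dtype=float)
        _validate_frequencies(pi)
        pi = pi / pi.sum()
    else:
        pi = model.frequencies
    S = model.exchangeabilities
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(Q)))
    if mean_rate <= 0:
        raise ValueError("degenerate model: zero mean substitution rate")
    Q = Q / mean_rate
    return RateMatrix(Q=Q, pi=pi, scale=1.0)


def transition_probabilities(rate_matrix: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt): row-stochastic transition probabilities over a branch.

    Computed from the cached symmetric eigendecomposition; tiny negative
    round-off (|x| <= ~1e-12) is clipped to keep rows valid.
    """
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    lam, left, right = rate_matrix.eig()
    P = (left * np.exp(lam * t)[None, :]) @ right
    np.maximum(P, 0.0, out=P)
    return P
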