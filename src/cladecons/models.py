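"""Reversible nucleotide substitution models (JC69, HKY85, GTR).

A model is a reversible 4-state rate matrix Q built from equilibrium
frequencies and exchangeability parameters, normalised so that one unit of
branch length equals one expected substitution per site.  Transition
probability matrices P(t) = exp(Qt) are computed from a symmetric
eigendecomposition cached on the model, which is exact for any reversible Q.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SubstitutionModel", "ALPHABET", "BASE_INDEX"]

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# order of the 6 GTR exchangeabilities: AC, AG, AT, CG, CT, GT
_GTR_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass(frozen=True)
class SubstitutionModel:
    family: str
    pi: np.ndarray
    rates: np.ndarray  # 6 exchangeabilities in _GTR_PAIRS order
    _eig: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be 4 positive values summing to 1")
        object.__setattr__(self, "pi", pi / pi.sum())
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (6,) or np.any(rates <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "_eig", self._decompose())

    # -- constructors --------------------------------------------------- #
    @classmethod
    def jc69(cls) -> "SubstitutionModel":
        return cls("JC69", np.full(4, 0.25), np.ones(6))

    @classmethod
    def hky85(cls, kappa: float, pi=None) -> "SubstitutionModel":
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        pi = np.full(4, 0.25) if pi is None else np.asarray(pi, float)
        rates = np.ones(6)
        rates[1] = rates[4] = kappa  # transitions AG, CT
        return cls("HKY85", pi, rates)

    @classmethod
    def gtr(cls, rates, pi) -> "SubstitutionModel":
        return cls("GTR", np.asarray(pi, float), np.asarray(rates, float))

    @property
    def kappa(self) -> float:
        """Transition/transversion rate ratio (exact for HKY85)."""
        r = self.rates
        return float((r[1] + r[4]) / (r[0] + r[2] + r[3] + r[5]) * 2)

    # -- rate matrix ----------------------------------------------------- #
    @property
    def Q(self) -> np.ndarray:
        q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _GTR_PAIRS):
            q[i, j] = r * self.pi[j]
            q[j, i] = r * self.pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.pi, np.diag(q))  # expected rate, normalise to 1
        return q / mu

    def _decompose(self):
        q = self.Q
        sq = np.sqrt(self.pi)
        s = q * sq[:, None] / sq[None, :]  # symmetric similarity transform
        w, v = np.linalg.eigh((s + s.T) / 2)
        left = v / sq[:, None]   # rows scaled: P(t) = left @ diag(e^{wt}) @ right
        right = v.T * sq[None, :]
        return w, left, right

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        if t == 0:
            return np.eye(4)
        w, left, right = self._eig
        p = (left * np.exp(w * t)) @ right
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for a vector of branch lengths (shape (n,4,4))."""
        ts = np.asarray(ts, float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be non-negative")
        w, left, right = self._eig
        p = np.einsum("ij,nj,jk->nik", left, np.exp(np.outer(ts, w)), right)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        p[ts == 0] = np.eye(4)
        return p

    # -- serialization --------------------------------------------------- #
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "pi": self.pi.tolist(),
            "rates": self.rates.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubstitutionModel":
        return cls(d["family"], np.asarray(d["pi"]), np.asarray(d["rates"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SubstitutionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
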