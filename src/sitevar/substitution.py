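"""Amino acid substitution models and similarity score matrices.

Two distinct objects share the JTT name in this pipeline and must not be
confused:

* :class:`SubstitutionModel` — the time-reversible JTT Markov rate matrix
  (exchangeabilities x stationary frequencies, scaled to one expected
  substitution per site per unit time). It drives the phylogenetic rate
  inference and the sequence simulator.
* :class:`SubstitutionScores` — the JTT 250-PAM log-odds *similarity* matrix
  used by the sum-of-pairs conservation scores, in two normalizations: the
  Karlin & Brocchieri form M'_ab = M_ab / sqrt(M_aa M_bb) (unit diagonal)
  and a min-max rescaling of that form onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .data.jtt import AA_ORDER, JTT_EXCHANGEABILITIES, JTT_FREQUENCIES

AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


class SubstitutionModel:
    """Reversible 20-state CTMC defined by exchangeabilities and frequencies.

    Q_ab = S_ab * pi_b for a != b, diagonal set so rows sum to zero, and the
    whole matrix scaled so that -sum_a pi_a Q_aa = 1 (branch lengths are then
    expected substitutions per site). Transition matrices are computed from
    the symmetric eigendecomposition of Pi^(1/2) Q Pi^(-1/2), which is exact
    for reversible models.
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))
        Q /= mu
        self.frequencies = pi
        self.rate_matrix = Q
        # symmetrize: B = Pi^(1/2) Q Pi^(-1/2)
        sqrt_pi = np.sqrt(pi)
        B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        B = (B + B.T) / 2.0
        self._eigval, U = np.linalg.eigh(B)
        self._left = sqrt_pi[:, None] ** -1 * U      # Pi^(-1/2) U
        self._right = U.T * sqrt_pi[None, :]         # U^T Pi^(1/2)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError("time must be nonnegative")
        P = (self._left * np.exp(self._eigval * t)[None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def spectral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, A, B) with P(t) = A @ diag(exp(lam t)) @ B."""
        return self._eigval, self._left, self._right


@lru_cache(maxsize=1)
def jtt_model() -> SubstitutionModel:
    """The JTT amino acid replacement model (Jones et al. 1992)."""
    return SubstitutionModel(JTT_EXCHANGEABILITIES, JTT_FREQUENCIES)


def discrete_gamma(alpha: float, n_categories: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Equal-probability discretization of the mean-1 gamma rate prior.

    Category boundaries are the k/K quantiles of Gamma(alpha, scale=1/alpha)
    and each category's rate is the conditional mean within its bin, computed
    from the regularized incomplete gamma function; the weighted mean of the
    category rates is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    K = n_categories
    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[r | b_k < r < b_{k+1}] * K  via  P(alpha+1, a*b)
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = K * (upper - lower)
    weights = np.full(K, 1.0 / K)
    return rates, weights


@dataclass
class SubstitutionScores:
    """JTT 250-PAM similarity scores in raw and normalized forms."""

    raw: np.ndarray            # 20x20 symmetric log-odds scores
    kb_normalized: np.ndarray  # unit diagonal
    vt_normalized: np.ndarray  # [0, 1], min 0 and max 1 attained

    def kb(self, a: str, b: str) -> float:
        return float(self.kb_normalized[AA_INDEX[a], AA_INDEX[b]])

    def vt(self, a: str, b: str) -> float:
        return float(self.vt_normalized[AA_INDEX[a], AA_INDEX[b]])


@lru_cache(maxsize=1)
def jtt250_scores() -> SubstitutionScores:
    """Load the JTT 250-PAM matrix and build both normalizations.

    The raw scores are Biopython's "JONES" substitution matrix (the Jones,
    Taylor & Thornton 1992 matrix at 250 PAMs). The min-max form rescales the
    unit-diagonal Karlin & Brocchieri normalization so that the diagonal
    (exact self-similarity) maps to 1 and the most dissimilar pair to 0.
    """
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("JONES")
    raw = np.array([[m[a, b] for b in AA_ORDER] for a in AA_ORDER])
    d = np.diag(raw)
    if np.any(d <= 0):
        raise ValueError("JTT250 diagonal must be positive")
    kb = raw / np.sqrt(np.outer(d, d))
    vt = (kb - kb.min()) / (kb.max() - kb.min())
    return SubstitutionScores(raw=raw, kb_normalized=kb, vt_normalized=vt)
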