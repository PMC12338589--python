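"""Time-reversible 20-state amino-acid substitution models.

The default model is a 20-state equal-rates model (the amino-acid analogue of
Jukes–Cantor) with uniform stationary frequencies, which has closed-form
transition probabilities and is therefore fully testable. An
empirical-exchangeability alternative is derived at run time from the
BLOSUM62 target and background frequencies shipped with Biopython, giving a
more realistic exchange structure for users who want it.

Rate matrices are normalised to one expected substitution per site per unit
branch length.
"""

from __future__ import annotations

import numpy as np

from .alignment_ops import AMINO_ACIDS

N_STATES = 20


class SubstitutionModel:
    """Reversible rate matrix Q = S·diag(π) with spectral transition kernels."""

    def __init__(self, exchangeabilities: np.ndarray, freqs: np.ndarray,
                 name: str = "custom"):
        s = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(freqs, dtype=float)
        if s.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if pi.shape != (N_STATES,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be length 20 and sum to 1")
        self.name = name
        self.freqs = pi / pi.sum()

        q = s * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise to 1 expected substitution / site / unit time
        rate = -(self.freqs * np.diag(q)).sum()
        q /= rate
        self.rate_matrix = q

        sq = np.sqrt(self.freqs)
        b = (sq[:, None] * q) / sq[None, :]
        b = (b + b.T) / 2.0  # symmetrise against round-off
        lam, u = np.linalg.eigh(b)
        self._lam = lam
        self._left = u / sq[:, None]      # D^{-1/2} U
        self._right = (u * sq[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, strictly positive for t > 0."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._left * np.exp(self._lam * t)) @ self._right
        return np.clip(p, 0.0, None)

    def expected_difference(self, t: float) -> float:
        """Probability that the two ends of a branch of length t differ."""
        p = self.transition_matrix(t)
        return float(1.0 - (self.freqs * np.diag(p)).sum())

    def sample_stationary(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(N_STATES, size=n, p=self.freqs)

    def evolve(self, parent_states: np.ndarray, t: float,
               rng: np.random.Generator) -> np.ndarray:
        """Sample child states site-wise given parent states."""
        cum = np.cumsum(self.transition_matrix(t), axis=1)
        u = rng.random(parent_states.shape[0])
        rows = cum[parent_states]
        return (u[:, None] > rows).sum(axis=1).astype(np.int8)


def equal_rates_model() -> SubstitutionModel:
    """20-state equal-rates model with uniform frequencies.

    Closed form: P_ii(t) = 1/20 + (19/20)·exp(−20t/19),
    P_ij(t) = 1/20 − (1/20)·exp(−20t/19).
    """
    s = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(s, 0.0)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return SubstitutionModel(s, pi, name="eq20")


def equal_rates_p_same(t: float) -> float:
    """Closed-form P(same state) across a branch of length t under eq20."""
    k = N_STATES
    return 1.0 / k + (k - 1.0) / k * np.exp(-k * t / (k - 1.0))


def empirical_model() -> SubstitutionModel:
    """Empirical exchangeabilities derived from BLOSUM62 target frequencies.

    The BLOSUM62 log-odds entries are 2·log2(q_ij / p_i p_j); exponentiating
    recovers the odds ratios O. Background frequencies consistent with the
    joint q_ij = p_i p_j O_ij must satisfy O·p = 1, a single linear solve,
    and the odds matrix itself (zero diagonal) serves as the symmetric
    exchangeabilities.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    odds = np.zeros((N_STATES, N_STATES))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            odds[i, j] = 2.0 ** (blosum[a, b] / 2.0)
    pi = np.linalg.solve(odds, np.ones(N_STATES))
    if np.any(pi <= 0):
        raise RuntimeError("inconsistent log-odds matrix")
    pi /= pi.sum()
    s = odds.copy()
    np.fill_diagonal(s, 0.0)
    return SubstitutionModel(s, pi, name="empirical")


_CACHE: dict[str, SubstitutionModel] = {}


def get_model(name: str) -> SubstitutionModel:
    """Look up a model by identifier ('eq20' or 'empirical')."""
    if name not in _CACHE:
        if name == "eq20":
            _CACHE[name] = equal_rates_model()
        elif name == "empirical":
            _CACHE[name] = empirical_model()
        else:
            raise ValueError(f"unknown substitution model {name!r}")
    return _CACHE[name]
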