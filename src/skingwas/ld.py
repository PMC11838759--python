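"""Two-locus linkage-disequilibrium arithmetic and effect-size conversion.

Given the risk-allele frequencies p_a and p_b of two variants and the
observed frequency h_ab of the risk-risk haplotype, the linkage-equilibrium
("theoretical") haplotype frequency is p_a * p_b, the LD coefficient is
D = h_ab - p_a * p_b, its normalised form is D' = D / D_max, and the squared
allelic correlation is r^2 = D^2 / (p_a (1-p_a) p_b (1-p_b)).

``solve_marginals`` inverts this arithmetic: from a printed triple
(theoretical frequency, observed frequency, r^2) it recovers the marginal
frequencies as the roots of t^2 - S t + P = 0 with P = p_a p_b = h_theory
and S = p_a + p_b = 1 + P - D^2 / (r^2 P), a feasibility check on whether
any marginals are consistent with the triple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class LDPair:
    """Two-locus haplotype frequencies and the derived LD statistics."""

    p_a: float
    p_b: float
    h_ab: float
    h_theory: float
    d: float
    d_prime: float
    r2: float


def ld_stats(p_a: float, p_b: float, h_ab: float) -> LDPair:
    """All two-locus LD statistics from the marginals and the observed
    risk-risk haplotype frequency. The Frechet bounds
    max(0, p_a + p_b - 1) <= h_ab <= min(p_a, p_b) must hold."""
    if not (0 < p_a < 1) or not (0 < p_b < 1):
        raise DomainError(f"marginal frequencies must lie in (0, 1), got "
                          f"p_a={p_a}, p_b={p_b}")
    lower = max(0.0, p_a + p_b - 1.0)
    upper = min(p_a, p_b)
    if h_ab < lower - 1e-12:
        raise DomainError(f"h_ab={h_ab} violates the lower Frechet bound "
                          f"max(0, p_a+p_b-1) = {lower}")
    if h_ab > upper + 1e-12:
        raise DomainError(f"h_ab={h_ab} violates the upper Frechet bound "
                          f"min(p_a, p_b) = {upper}")

    h_theory = p_a * p_b
    d = h_ab - h_theory
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = math.nan
    d_prime = 0.0 if d == 0 else d / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDPair(p_a=p_a, p_b=p_b, h_ab=h_ab, h_theory=h_theory,
                  d=d, d_prime=d_prime, r2=r2)


def solve_marginals(h_theory: float, h_obs: float, r2: float
                    ) -> tuple[float, float] | None:
    """Recover marginal frequencies (p_a, p_b) consistent with a printed
    (h_theory, h_obs, r2) triple, or ``None`` when no pair in (0, 1)^2 is.

    The pair solves p_a p_b = h_theory and
    p_a (1-p_a) p_b (1-p_b) = (h_obs - h_theory)^2 / r2; the returned pair
    has p_a >= p_b (the two loci are exchangeable in the triple).
    """
    for name, v in (("h_theory", h_theory), ("h_obs", h_obs)):
        if not (0 < v < 1):
            raise DomainError(f"{name} must lie in (0, 1), got {v}")
    if not (0 <= r2 <= 1):
        raise DomainError(f"r2 must lie in [0, 1], got {r2}")
    d = h_obs - h_theory
    if r2 == 0:
        # d != 0 contradicts r2 = 0; d = 0 leaves the marginals underdetermined
        return None
    variance_product = d * d / r2            # = p_a(1-p_a) p_b(1-p_b)
    P = h_theory
    S = 1.0 + P - variance_product / P       # since (1-p_a)(1-p_b) = var_product / P
    disc = S * S - 4.0 * P
    if disc < 0:
        return None
    root = math.sqrt(disc)
    p_a, p_b = (S + root) / 2.0, (S - root) / 2.0
    if not (0 < p_b <= p_a < 1):
        return None
    # substitute back: the roots must reproduce a valid haplotype frequency
    lower = max(0.0, p_a + p_b - 1.0)
    upper = min(p_a, p_b)
    if not (lower - 1e-12 <= h_obs <= upper + 1e-12):
        return None
    return p_a, p_b


def beta_to_or(beta: float) -> float:
    """Log-odds effect size to odds ratio: exp(beta)."""
    return math.exp(beta)


def haplotype_counts_to_freqs(counts) -> LDPair:
    """LD statistics from a 2x2 haplotype count table.

    ``counts`` is (n_AB, n_Ab, n_aB, n_ab) or a 2x2 array laid out as
    [[AB, Ab], [aB, ab]], where A/B are the risk alleles.
    """
    arr = np.asarray(counts, dtype=float).reshape(-1)
    if arr.size != 4:
        raise DomainError("haplotype count table must have exactly 4 entries")
    if (arr < 0).any():
        raise DomainError("haplotype counts must be >= 0")
    total = arr.sum()
    if total <= 0:
        raise DomainError("total haplotype count must be > 0")
    n_ab_rr, n_ab_r0, n_ab_0r, _ = arr
    p_a = (n_ab_rr + n_ab_r0) / total
    p_b = (n_ab_rr + n_ab_0r) / total
    h_ab = n_ab_rr / total
    if not (0 < p_a < 1) or not (0 < p_b < 1):
        raise DomainError(f"monomorphic locus: p_a={p_a}, p_b={p_b}")
    return ld_stats(p_a, p_b, h_ab)
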