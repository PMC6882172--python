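"""Random-rank null model for the first interface pair.

Draw ``draws`` (default 1000) distinct pairs uniformly, in order, from a
universe of N surface residue pairs of which M are interface pairs; the
random variable X is the position of the first interface pair among the
draws, with ``cap`` (default = draws) assigned when none is drawn.  This is
the null against which a ranking method's RFPP is compared: a predictor is
only useful if its RFPP beats E[min(X, cap)].

The first-success law for ordered sampling without replacement is

    P(X = i) = [prod_{j=0}^{i-2} (N-M-j)/(N-j)] * M/(N-i+1),  i = 1..draws
    P(no success) = prod_{j=0}^{draws-1} (N-M-j)/(N-j)

computed in log space so that N up to ~10^6 never underflows.  The
truncated expectation has two equivalent forms (used to cross-check each
other): sum_i i P(X=i) + cap * P(no success), and the survival-function sum
sum_{i=0}^{draws-1} P(X > i) when cap equals draws.  A Monte-Carlo
estimator simulates the ordered draws directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ValidationError

__all__ = ["BaselineSpec", "BaselinePmf", "rfpp_pmf", "expected_rfpp",
           "simulate_rfpp_mc", "McResult"]


@dataclass(frozen=True)
class BaselineSpec:
    """Parameters of the random first-interface-rank experiment."""

    N: int                  # surface residue pairs
    M: int                  # interface residue pairs among them
    draws: int = 1000       # pairs drawn per experiment
    cap: Optional[int] = None   # rank assigned when no interface pair is drawn
    reps: int = 1_000_000   # Monte-Carlo replicates
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.M <= self.N):
            raise ValidationError(f"need 1 <= M <= N, got M={self.M}, N={self.N}")
        if not (1 <= self.draws <= self.N):
            raise ValidationError(f"need 1 <= draws <= N, got draws={self.draws}")
        if self.cap is None:
            object.__setattr__(self, "cap", self.draws)
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")


@dataclass
class BaselinePmf:
    probabilities: np.ndarray   # P(X = i) for i = 1..draws
    no_success: float           # P(no interface pair among the draws)

    def total_mass(self) -> float:
        return float(self.probabilities.sum() + self.no_success)


def _log_survival_prefix(N: int, M: int, draws: int) -> np.ndarray:
    """log P(first i draws all miss), for i = 0..draws; -inf once the
    non-interface pool is exhausted."""
    i = np.arange(draws)
    num = N - M - i          # remaining non-interface pairs at draw i+1
    den = N - i
    terms = np.full(draws, -np.inf)
    ok = num > 0
    terms[ok] = np.log(num[ok]) - np.log(den[ok])
    # any zero factor makes every later prefix -inf
    if not ok.all():
        first_bad = int(np.argmin(ok))
        terms[first_bad:] = -np.inf
    out = np.empty(draws + 1)
    out[0] = 0.0
    np.cumsum(terms, out=out[1:])
    return out


def rfpp_pmf(spec: BaselineSpec) -> BaselinePmf:
    """Exact pmf of the first-interface rank under ordered sampling without
    replacement, in log space."""
    lsp = _log_survival_prefix(spec.N, spec.M, spec.draws)
    i = np.arange(1, spec.draws + 1)
    with np.errstate(divide="ignore"):
        logp = lsp[:-1] + np.log(spec.M) - np.log(spec.N - i + 1)
    probs = np.exp(logp)
    return BaselinePmf(probabilities=probs, no_success=float(np.exp(lsp[-1])))


def expected_rfpp(spec: BaselineSpec, method: str = "pmf") -> float:
    """Closed-form E[min(X, cap)].

    ``method='pmf'`` evaluates sum_i i P(X=i) + cap * P(no success);
    ``method='survival'`` evaluates sum_{i=0}^{draws-1} P(X > i), valid when
    cap equals draws.  Both agree to high precision and serve as mutual
    checks.
    """
    if method == "pmf":
        pmf = rfpp_pmf(spec)
        i = np.arange(1, spec.draws + 1)
        return float((i * pmf.probabilities).sum() + spec.cap * pmf.no_success)
    if method == "survival":
        if spec.cap != spec.draws:
            raise ValidationError("survival form requires cap == draws")
        lsp = _log_survival_prefix(spec.N, spec.M, spec.draws)
        return float(np.exp(lsp[:-1]).sum())
    raise ValidationError(f"unknown method {method!r}")


@dataclass
class McResult:
    estimate: float
    standard_error: float
    counts: np.ndarray      # counts[i-1] = #replicates with X = i; counts[-1] = capped

    @property
    def n_reps(self) -> int:
        return int(self.counts.sum())


def simulate_rfpp_mc(spec: BaselineSpec) -> McResult:
    """Monte-Carlo estimate of E[min(X, cap)] by simulating the draws.

    Each replicate draws pairs one at a time without replacement; given no
    interface pair among the first j-1 draws, draw j succeeds with
    probability M / (N - j + 1).  The estimate is the mean of min(X, cap)
    over replicates — exactly the frequency-weighted sum
    sum_i i * count(X=i)/reps + cap * count(no success)/reps — with its
    sample standard error.  Fully vectorized over replicates and seeded.
    """
    rng = np.random.default_rng(spec.seed)
    reps = spec.reps
    result = np.full(reps, spec.cap, dtype=np.int64)
    counts = np.zeros(spec.draws + 1, dtype=np.int64)
    active = np.arange(reps)
    for j in range(1, spec.draws + 1):
        if active.size == 0:
            break
        p = spec.M / (spec.N - j + 1)
        hit = rng.random(active.size) < p
        winners = active[hit]
        result[winners] = j
        counts[j - 1] = winners.size
        active = active[~hit]
    counts[spec.draws] = active.size
    vals = np.minimum(result, spec.cap).astype(float)
    est = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")
    return McResult(estimate=est, standard_error=se, counts=counts)
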