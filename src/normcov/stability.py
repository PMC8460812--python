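"""Discriminating chromosome polyploidy from unstable plasmid inheritance.

A plasmid whose bulk NormCov is, say, 0.5 admits two explanations: every cell
carries it but the chromosome is at two copies per cell (polyploidy), or only
half the cells carry it (instability).  A panel of n clonal colonies decides:
under instability each founder cell lacks the plasmid with probability
1 − c (c = the carriage fraction implied by the bulk NormCov), so losses are
frequent; under polyploidy losses occur only at a small background rate ε.

The test is a one-sided exact binomial tail — few observed losses contradict
the instability null — combined with a likelihood ratio between the two
hypotheses:

    p_value_loss = P(X ≤ k | X ~ Binomial(n, 1 − ĉ)),   ĉ = min(NormCov, 1)
    log_lr       = log10 [ Binom(k; n, ε) / Binom(k; n, 1 − ĉ) ]

Verdict: polyploidy_supported iff p_value_loss < α and log_lr > 0;
instability_supported iff p_value_loss ≥ α and log_lr < 0; else inconclusive.
No multiple-testing correction is applied across plasmids by default
(``bonferroni=True`` divides α by the number of plasmids tested).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .coverage import CopyNumberEstimate
from .population import ColonyPanel

__all__ = [
    "StabilityTest",
    "binom_pmf",
    "binom_cdf",
    "expected_losses",
    "test_stability",
    "test_panel",
    "epsilon_sensitivity",
]


def binom_pmf(k: int, n: int, p: float) -> float:
    """Binomial point mass C(n,k) p^k (1−p)^(n−k), evaluated directly."""
    if not 0 <= k <= n:
        return 0.0
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def binom_cdf(k: int, n: int, p: float) -> float:
    """Lower binomial tail P(X ≤ k) by explicit summation of the pmf."""
    if k < 0:
        return 0.0
    return min(1.0, sum(binom_pmf(i, n, p) for i in range(min(k, n) + 1)))


@dataclass
class StabilityTest:
    """Outcome of the polyploidy-vs-instability test for one plasmid."""

    plasmid: str
    c_hat: float  # carriage fraction implied by the instability hypothesis
    n: int  # colonies in the panel
    k: int  # colonies lacking the plasmid
    epsilon: float  # background loss probability under polyploidy
    p_value_loss: float  # P(X <= k | Binomial(n, 1 - c_hat))
    log_lr: float  # log10 LR, polyploidy vs instability
    verdict: str  # polyploidy_supported | instability_supported | inconclusive


def expected_losses(
    carriage: dict[str, float], n: int
) -> tuple[dict[str, float], float]:
    """Expected per-plasmid losses and expected colonies losing >= 1 plasmid.

    Per plasmid the expectation is n·(1 − c); jointly, assuming independent
    presence events, n·(1 − Π c).  With six plasmids at c = 0.5 and n = 14
    this gives 7 losses per plasmid and ≈ 13.8 colonies with at least one
    loss — the "around half of the colonies" intuition understates how
    sensitive a panel is when several plasmids are unstable at once.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, c in carriage.items():
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"carriage[{name!r}] must be in [0, 1]")
    per_plasmid = {name: n * (1.0 - c) for name, c in carriage.items()}
    joint = n * (1.0 - math.prod(carriage.values()))
    return per_plasmid, joint


def _verdict(p_value: float, log_lr: float, alpha: float) -> str:
    if p_value < alpha and log_lr > 0:
        return "polyploidy_supported"
    if p_value >= alpha and log_lr < 0:
        return "instability_supported"
    return "inconclusive"


def test_stability(
    bulk: Union[CopyNumberEstimate, float],
    panel: ColonyPanel,
    plasmid: str,
    epsilon: float = 0.02,
    alpha: float = 0.05,
) -> StabilityTest:
    """Test one plasmid's colony losses against the instability null.

    ``bulk`` is the plasmid's bulk-culture NormCov estimate (the broth-grown
    culture the colony plate was seeded from), either as a
    :class:`CopyNumberEstimate` or a bare number.  NormCov above 1 cannot be
    explained by instability; carriage is capped at 1 with a warning.
    """
    if panel.n < 1:
        raise ValueError("panel must contain at least one colony")
    normcov_mean = bulk.normcov_mean if isinstance(bulk, CopyNumberEstimate) else float(bulk)
    if normcov_mean <= 0:
        raise ValueError("bulk NormCov must be positive")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    if normcov_mean > 1.0:
        warnings.warn(
            f"{plasmid}: bulk NormCov {normcov_mean:.3g} > 1; instability cannot "
            "explain it — carriage capped at 1"
        )
    c_hat = min(normcov_mean, 1.0)
    k = panel.losses[plasmid]
    n = panel.n
    p_loss = 1.0 - c_hat

    if p_loss == 0.0 and k > 0:
        # observed losses are impossible under the (degenerate) instability null
        p_value = 0.0
    else:
        p_value = binom_cdf(k, n, p_loss)

    num = binom_pmf(k, n, epsilon)
    den = binom_pmf(k, n, p_loss)
    if den == 0.0:
        log_lr = math.inf if num > 0 else 0.0
    elif num == 0.0:
        log_lr = -math.inf
    else:
        log_lr = math.log10(num / den)

    return StabilityTest(
        plasmid=plasmid,
        c_hat=c_hat,
        n=n,
        k=k,
        epsilon=epsilon,
        p_value_loss=p_value,
        log_lr=log_lr,
        verdict=_verdict(p_value, log_lr, alpha),
    )


def test_panel(
    bulk: dict[str, Union[CopyNumberEstimate, float]],
    panel: ColonyPanel,
    epsilon: float = 0.02,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Run :func:`test_stability` for every plasmid in the panel.

    ``bulk`` maps plasmid name to its bulk NormCov estimate.  With
    ``bonferroni=True`` the significance level is α divided by the number of
    plasmids tested.
    """
    names = [name for name in panel.losses if name in bulk]
    if not names:
        raise ValueError("no plasmid shared between bulk estimates and panel")
    a = alpha / len(names) if bonferroni else alpha
    rows = []
    for name in names:
        t = test_stability(bulk[name], panel, name, epsilon=epsilon, alpha=a)
        rows.append(
            {
                "plasmid": t.plasmid,
                "c_hat": t.c_hat,
                "n": t.n,
                "k": t.k,
                "epsilon": t.epsilon,
                "p_value_loss": t.p_value_loss,
                "log_lr": t.log_lr,
                "verdict": t.verdict,
            }
        )
    return pd.DataFrame(rows)


def epsilon_sensitivity(
    bulk: Union[CopyNumberEstimate, float],
    panel: ColonyPanel,
    plasmid: str,
    epsilons: Optional[np.ndarray] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Verdict and log-likelihood ratio across a grid of background loss rates.

    The background rate ε under polyploidy is not identified by a single
    panel; this sweep shows how far the verdict depends on it.
    """
    if epsilons is None:
        epsilons = np.array([0.005, 0.01, 0.02, 0.05, 0.1, 0.2])
    rows = []
    for eps in epsilons:
        t = test_stability(bulk, panel, plasmid, epsilon=float(eps), alpha=alpha)
        rows.append(
            {
                "epsilon": float(eps),
                "p_value_loss": t.p_value_loss,
                "log_lr": t.log_lr,
                "verdict": t.verdict,
            }
        )
    return pd.DataFrame(rows)
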