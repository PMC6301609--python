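"""MCMC convergence machinery: Gelman-Rubin R-hat, Geweke z-scores, and the
escalating-run protocol that re-fits with longer chains until both pass.

Pass criteria: R-hat < 1.05 for every monitored variable, and within each
chain no more than 5% of variables with Geweke |z| > 1.96.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

RHAT_THRESHOLD = 1.05
GEWEKE_Z = 1.96
GEWEKE_FRACTION = 0.05


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one variable.

    ``chains`` is an (m, n) array of m >= 2 chains of n >= 4 draws. Computed
    as sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance
    and B = n * variance of the chain means (both with ddof=1).
    """
    X = np.asarray(chains, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 4:
        raise ValueError("need an (m >= 2, n >= 4) array of chains")
    m, n = X.shape
    W = float(X.var(axis=1, ddof=1).mean())
    if W == 0.0:
        raise ValueError("degenerate chain: zero within-chain variance")
    B = n * float(X.mean(axis=1).var(ddof=1))
    return math.sqrt(((n - 1) / n * W + B / n) / W)


def _spectral_variance(x: np.ndarray) -> float:
    """Spectral density of the chain at frequency zero, via Bartlett-windowed
    autocovariances (lag window ~ sqrt of the segment length)."""
    n = len(x)
    xc = x - x.mean()
    L = max(1, int(math.sqrt(n)))
    gamma0 = float(np.dot(xc, xc)) / n
    s = gamma0
    for lag in range(1, min(L, n - 1) + 1):
        gamma = float(np.dot(xc[:-lag], xc[lag:])) / n
        s += 2.0 * (1.0 - lag / (L + 1)) * gamma
    return max(s, 0.0)


def geweke(chain, frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """Geweke convergence z-score for a single chain of one variable.

    Compares the mean of the first ``frac_a`` of the chain with the mean of
    the last ``frac_b``, scaled by spectral-density-at-zero standard errors.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    na, nb = int(frac_a * n), int(frac_b * n)
    if na + nb > n:
        raise ValueError("windows overlap: frac_a + frac_b must be <= 1")
    if na < 10 or nb < 10:
        raise ValueError("each window needs at least 10 draws")
    a, b = x[:na], x[n - nb:]
    va, vb = _spectral_variance(a), _spectral_variance(b)
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero-variance window")
    return float((a.mean() - b.mean()) / math.sqrt(va / na + vb / nb))


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    geweke_z: dict[tuple[str, int], float]  # (variable, chain index) -> z
    pass_rhat: bool
    pass_geweke: bool
    escalation_level: int = 0

    @property
    def converged(self) -> bool:
        return self.pass_rhat and self.pass_geweke


def convergence_report(result, escalation_level: int = 0) -> ConvergenceReport:
    """Diagnose a PosteriorResult on its retained (post burn-in, thinned) draws.

    Monitored variables are the source proportions. Degenerate (numerically
    constant) variables are treated as failing R-hat's preconditions and
    reported as non-converged rather than raising.
    """
    draws = result.draws_by_chain  # (chains, kept, K)
    names = result.source_names
    rhat: dict[str, float] = {}
    gz: dict[tuple[str, int], float] = {}
    pass_rhat = True
    for k, name in enumerate(names):
        try:
            r = gelman_rubin(draws[:, :, k])
        except ValueError:
            r = float("inf")
        rhat[name] = r
        if not (r < RHAT_THRESHOLD):
            pass_rhat = False
    n_chains = draws.shape[0]
    pass_geweke = True
    for c in range(n_chains):
        n_bad = 0
        for k, name in enumerate(names):
            try:
                z = geweke(draws[c, :, k])
            except ValueError:
                z = float("inf")
            gz[(name, c)] = z
            if abs(z) > GEWEKE_Z:
                n_bad += 1
        if n_bad / len(names) > GEWEKE_FRACTION:
            pass_geweke = False
    return ConvergenceReport(rhat, gz, pass_rhat, pass_geweke, escalation_level)


#: Default escalation ladder. Only the first rung is the canonical "very
#: short" setting; later rungs increase run length until convergence.
def default_ladder(seed: int = 0):
    from .simm import MCMCConfig
    return [
        MCMCConfig(10_000, 5_000, 5, 3, seed),
        MCMCConfig(50_000, 25_000, 25, 3, seed),
        MCMCConfig(100_000, 50_000, 50, 3, seed),
        MCMCConfig(300_000, 200_000, 100, 3, seed),
    ]


def run_until_converged(fit_fn, ladder):
    """Re-fit with successively longer runs until both diagnostics pass.

    ``fit_fn`` maps an MCMCConfig to a PosteriorResult. Returns
    ``(result, report)`` for the first passing rung; if the ladder is
    exhausted the last result is returned with its (failing) report — a
    non-converged state is reported, never silently passed.
    """
    if not ladder:
        raise ValueError("ladder must be non-empty")
    result = report = None
    for level, cfg in enumerate(ladder):
        result = fit_fn(cfg)
        report = convergence_report(result, escalation_level=level)
        result.diagnostics = report
        if report.converged:
            return result, report
    return result, report


def report_to_dict(report: ConvergenceReport) -> dict:
    """JSON-serialisable form of a ConvergenceReport."""
    return {
        "rhat": report.rhat,
        "geweke_z": {f"{name}/chain{c}": z for (name, c), z in report.geweke_z.items()},
        "pass_rhat": report.pass_rhat,
        "pass_geweke": report.pass_geweke,
        "converged": report.converged,
        "escalation_level": report.escalation_level,
    }
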