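"""Parameter-recovery estimators.

Each estimator turns simulated output back into one of the configured
generating parameters (CNV state frequencies, odds ratios, fold changes,
methylation differences, beta-binomial overdispersion, eQTM slopes). They
are the engine behind `omicsim validate` and the acceptance checks: the
simulator is trusted only insofar as these recover what was configured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .genomics import CNV_STATES, CNVData
from .methylation import MethylationData, methylation_proportion


@dataclass
class RecoveryReport:
    parameter: str
    configured: float
    estimate: float
    se: float | None
    n: int
    tolerance_rule: str
    passed: bool

    def __str__(self):
        flag = "PASS" if self.passed else "FAIL"
        se = f" (SE {self.se:.4g})" if self.se is not None else ""
        return (f"{flag} {self.parameter}: configured {self.configured:.4g}, "
                f"estimated {self.estimate:.4g}{se}, n={self.n} [{self.tolerance_rule}]")


def empirical_state_frequency(cnv: CNVData, region_id: str, state: str) -> float:
    """Fraction of chromosomes (two per individual) in the given CNV state."""
    if cnv.n_individuals == 0:
        raise ValueError("empty CNV data")
    k = cnv.column(region_id)
    s = CNV_STATES.index(state)
    return float(np.mean(np.concatenate([cnv.s1[:, k], cnv.s2[:, k]]) == s))


def estimate_or(X: np.ndarray, status, term: int | str, names: list | None = None):
    """Fit a logistic regression of status on the coded design and return
    (odds ratio, Wald SE of the log-odds) for the requested term.

    The design must contain every generating term (same codings as the
    penetrance function) for the coefficients to be identifiable from
    case-control data; the intercept absorbs the ascertainment.
    """
    status = np.asarray(status, dtype=float)
    Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    fit = sm.Logit(status, Xc).fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(fit.bse)):
        raise RuntimeError("logistic fit did not converge (separation?)")
    idx = (names.index(term) if isinstance(term, str) else term) + 1  # skip const
    return float(np.exp(fit.params[idx])), float(fit.bse[idx])


def estimate_fold_change(counts_row, status, c) -> float:
    """Ratio of c-adjusted group means, cases over controls."""
    status = np.asarray(status, dtype=bool)
    adj = np.asarray(counts_row, dtype=float) / np.asarray(c, dtype=float)
    if not status.any() or status.all():
        raise ValueError("both groups must be nonempty")
    ctrl = adj[~status].mean()
    if ctrl == 0:
        raise ZeroDivisionError("control group mean is zero")
    return float(adj[status].mean() / ctrl)


def estimate_methylation_difference(data: MethylationData, cpg_id: str, status):
    """Case-minus-control difference of group-mean methylation proportions,
    with its standard error."""
    status = np.asarray(status, dtype=bool)
    prop = methylation_proportion(data, cpg_id)
    case = prop[status & ~np.isnan(prop)]
    ctrl = prop[~status & ~np.isnan(prop)]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("empty group after dropping zero-depth individuals")
    diff = case.mean() - ctrl.mean()
    se = float(np.sqrt(case.var(ddof=1) / case.size + ctrl.var(ddof=1) / ctrl.size))
    return float(diff), se


def fit_beta_binomial(alt_reads, totals) -> tuple:
    """Maximum-likelihood (mean, overdispersion) of a beta-binomial.

    Parameterisation: alpha = p(1-rho)/rho, beta = (1-p)(1-rho)/rho, so rho
    is the pairwise correlation of trials within a draw and rho -> 0 is
    binomial.
    """
    k = np.asarray(alt_reads, dtype=np.int64)
    n = np.asarray(totals, dtype=np.int64)
    keep = n > 0
    k, n = k[keep], n[keep]
    if k.size < 10:
        raise ValueError("need at least 10 observations with positive totals")

    def nll(theta):
        p, rho = theta
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        return -np.sum(stats.betabinom.logpmf(k, n, a, b))

    res = optimize.minimize(nll, x0=np.array([np.clip(k.sum() / n.sum(), 0.01, 0.99), 0.05]),
                            bounds=[(1e-4, 1 - 1e-4), (1e-6, 0.99)],
                            method="L-BFGS-B")
    if not res.success:
        raise RuntimeError(f"beta-binomial MLE failed: {res.message}")
    return float(res.x[0]), float(res.x[1])


def fit_beta_binomial_ci(alt_reads, totals, level: float = 0.95) -> dict:
    """MLE plus a profile-free Wald CI for rho from the observed information
    (finite-difference Hessian)."""
    p_hat, rho_hat = fit_beta_binomial(alt_reads, totals)
    k = np.asarray(alt_reads, dtype=np.int64)
    n = np.asarray(totals, dtype=np.int64)
    keep = n > 0
    k, n = k[keep], n[keep]

    def nll(theta):
        p, rho = theta
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        return -np.sum(stats.betabinom.logpmf(k, n, a, b))

    eps = 1e-4
    theta = np.array([p_hat, rho_hat])
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * eps
            ej = np.eye(2)[j] * eps
            H[i, j] = (nll(theta + ei + ej) - nll(theta + ei - ej)
                       - nll(theta - ei + ej) + nll(theta - ei - ej)) / (4 * eps * eps)
    cov = np.linalg.inv(H)
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(np.maximum(np.diag(cov), 0))
    return {"p": p_hat, "rho": rho_hat, "p_se": float(se[0]), "rho_se": float(se[1]),
            "rho_ci": (rho_hat - z * se[1], rho_hat + z * se[1])}


def estimate_eqtm_slopes(counts: np.ndarray, x, gene_rows) -> tuple:
    """Per-gene least-squares slope of counts on methylation proportion.

    Returns (slopes array, mean slope, SE of the mean).
    """
    x = np.asarray(x, dtype=float)
    keep = ~np.isnan(x)
    if np.ptp(x[keep]) == 0:
        raise ValueError("methylation proportions are constant")
    xk = x[keep]
    xc = xk - xk.mean()
    denom = np.sum(xc ** 2)
    slopes = np.array([
        float(np.sum(xc * (counts[g, keep] - counts[g, keep].mean())) / denom)
        for g in gene_rows])
    mean = float(slopes.mean())
    se = float(slopes.std(ddof=1) / np.sqrt(slopes.size)) if slopes.size > 1 else 0.0
    return slopes, mean, se


def within_se(configured: float, estimate: float, se: float, k: float = 3.0,
              log_scale: bool = False) -> bool:
    if log_scale:
        return abs(np.log(estimate) - np.log(configured)) <= k * se
    return abs(estimate - configured) <= k * se


def within_relative(configured: float, estimate: float, rel: float = 0.10) -> bool:
    return abs(estimate - configured) <= rel * abs(configured)
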