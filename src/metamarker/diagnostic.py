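"""Diagnostic-accuracy analysis: per-dataset ROC with Youden dichotomization
and pooled (bivariate) diagnostic meta-analysis with a summary ROC curve.

Each dataset's continuous marker is dichotomized at the cutoff maximizing
the Youden index J = sensitivity + specificity − 1, producing a 2×2
confusion table (TP/FP/FN/TN).  Tables are pooled with a bivariate
random-effects model on (logit sensitivity, logit specificity) — normal
within-study errors with known variances, an unstructured 2×2
between-study covariance estimated by REML — and the summary ROC curve is
obtained through the Rutter–Gatsonis HSROC parametrization of the
bivariate fit, with its AUC by numerical integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.integrate import quad
from scipy.special import expit, logit

__all__ = [
    "RocResult",
    "TwoByTwo",
    "DiagnosticSummary",
    "empirical_roc",
    "youden_cutoff",
    "confusion_at_cutoff",
    "pool_diagnostics",
    "sroc_points",
]

Z95 = 1.96


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC over all observed cutoffs.

    ``direction`` is ``"case_low"`` when low marker values indicate a case
    (a down-regulated marker) and ``"case_high"`` otherwise.  ``points``
    hold (cutoff, sensitivity, specificity) at every observed value.
    """

    points: list[tuple[float, float, float]]
    auc: float
    direction: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC out of [0,1]: {self.auc}")


@dataclass(frozen=True)
class TwoByTwo:
    """Confusion counts after dichotomization."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    def has_zero(self) -> bool:
        return 0 in (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Pooled diagnostic accuracy at the bivariate summary point.

    Likelihood ratios and the diagnostic odds ratio are derived from the
    summary sensitivity/specificity, with delta-method CIs on the log
    scale; ``sroc_auc`` integrates the HSROC curve over the full
    false-positive-rate axis.  ``method`` records whether the bivariate
    REML fit converged (``"bivariate_reml"``) or the flagged univariate
    DerSimonian–Laird fallback was used (``"univariate_dl"``).
    """

    sens: float
    sens_ci: tuple[float, float]
    spec: float
    spec_ci: tuple[float, float]
    plr: float
    plr_ci: tuple[float, float]
    nlr: float
    nlr_ci: tuple[float, float]
    dor: float
    dor_ci: tuple[float, float]
    sroc_auc: float
    sroc_auc_ci: tuple[float, float]
    k: int
    method: str
    mu: tuple[float, float] = field(repr=False, default=(0.0, 0.0))
    psi: tuple[float, float, float] = field(repr=False, default=(0.0, 0.0, 0.0))


def empirical_roc(
    case_values: Sequence[float],
    control_values: Sequence[float],
    direction: str | None = None,
) -> RocResult:
    """Empirical ROC using every observed value as a candidate cutoff.

    The AUC is the Mann–Whitney pair-count estimator: over all
    case–control pairs, the fraction correctly ordered by the marker in
    the positive direction, with tied pairs counted 0.5.  If ``direction``
    is None the orientation giving AUC ≥ 0.5 is chosen.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both case and control lists must be non-empty")
    # P(case < control) + 0.5 P(case == control), via pair counts
    less = np.sum(cases[:, None] < controls[None, :])
    equal = np.sum(cases[:, None] == controls[None, :])
    auc_low = (less + 0.5 * equal) / (cases.size * controls.size)
    if direction is None:
        direction = "case_low" if auc_low >= 0.5 else "case_high"
    if direction not in ("case_low", "case_high"):
        raise ValueError(f"unknown direction {direction!r}")
    auc = float(auc_low if direction == "case_low" else 1.0 - auc_low)

    cutoffs = np.unique(np.concatenate([cases, controls]))
    points = []
    for c in cutoffs:
        tab = confusion_at_cutoff(cases, controls, float(c), direction)
        sens = tab.tp / tab.n_cases
        spec = tab.tn / tab.n_controls
        points.append((float(c), float(sens), float(spec)))
    return RocResult(points, auc, direction)


def youden_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """Cutoff maximizing the Youden index J = sens + spec − 1.

    Ties in J are broken toward higher specificity (the tighter cutoff in
    the positive direction), then deterministically by cutoff value.
    """
    if not roc.points:
        raise ValueError("ROC has no points")
    best = None
    for cutoff, sens, spec in roc.points:
        j = sens + spec - 1.0
        # key: larger J, then larger spec, then tighter cutoff
        tight = -cutoff if roc.direction == "case_low" else cutoff
        key = (j, spec, tight)
        if best is None or key > best[0]:
            best = (key, (cutoff, sens, spec))
    return best[1]


def confusion_at_cutoff(
    case_values: Sequence[float],
    control_values: Sequence[float],
    cutoff: float,
    direction: str,
) -> TwoByTwo:
    """2×2 confusion table at a cutoff.

    ``case_low``: test-positive means value ≤ cutoff; ``case_high``:
    test-positive means value ≥ cutoff.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if direction == "case_low":
        tp = int(np.sum(cases <= cutoff))
        fp = int(np.sum(controls <= cutoff))
    elif direction == "case_high":
        tp = int(np.sum(cases >= cutoff))
        fp = int(np.sum(controls >= cutoff))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return TwoByTwo(tp=tp, fp=fp, fn=int(cases.size) - tp, tn=int(controls.size) - fp)


def _logit_pairs(tables: Sequence[TwoByTwo]) -> tuple[np.ndarray, np.ndarray]:
    """Continuity-corrected (logit sens, logit spec) and within-study variances."""
    y, s = [], []
    for t in tables:
        c = 0.5 if t.has_zero() else 0.0
        tp, fp, fn, tn = t.tp + c, t.fp + c, t.fn + c, t.tn + c
        y.append([math.log(tp / fn), math.log(tn / fp)])
        s.append([1.0 / tp + 1.0 / fn, 1.0 / tn + 1.0 / fp])
    return np.array(y), np.array(s)


def _reml_nll(par: np.ndarray, y: np.ndarray, s: np.ndarray) -> float:
    ls1, ls2, zr = par
    sd1, sd2 = math.exp(ls1), math.exp(ls2)
    rho = math.tanh(zr)
    psi = np.array([[sd1 * sd1, rho * sd1 * sd2], [rho * sd1 * sd2, sd2 * sd2]])
    winv = np.zeros((2, 2))
    wy = np.zeros(2)
    ll = 0.0
    vis = []
    for i in range(len(y)):
        vmat = psi + np.diag(s[i])
        det = vmat[0, 0] * vmat[1, 1] - vmat[0, 1] * vmat[1, 0]
        if det <= 0:
            return 1e10
        vi = np.array([[vmat[1, 1], -vmat[0, 1]], [-vmat[1, 0], vmat[0, 0]]]) / det
        vis.append(vi)
        ll -= 0.5 * math.log(det)
        winv += vi
        wy += vi @ y[i]
    mu = np.linalg.solve(winv, wy)
    for i in range(len(y)):
        r = y[i] - mu
        ll -= 0.5 * r @ vis[i] @ r
    ll -= 0.5 * math.log(np.linalg.det(winv))
    return -ll


def _fit_bivariate(y: np.ndarray, s: np.ndarray):
    """REML fit of the bivariate normal-normal model; returns (mu, cov_mu, psi)."""
    best = None
    for start in ([0.0, 0.0, 0.0], [-1.0, -1.0, 0.0], [0.5, 0.5, -0.5]):
        res = optimize.minimize(
            _reml_nll, start, args=(y, s), method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-11, maxiter=8000),
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e9:
        raise RuntimeError("bivariate REML did not converge")
    ls1, ls2, zr = best.x
    sd1, sd2 = math.exp(ls1), math.exp(ls2)
    rho = math.tanh(zr)
    psi = np.array([[sd1**2, rho * sd1 * sd2], [rho * sd1 * sd2, sd2**2]])
    winv = np.zeros((2, 2))
    wy = np.zeros(2)
    for i in range(len(y)):
        vi = np.linalg.inv(psi + np.diag(s[i]))
        winv += vi
        wy += vi @ y[i]
    cov = np.linalg.inv(winv)
    mu = cov @ wy
    return mu, cov, psi


def _hsroc_auc(mu: np.ndarray, psi: np.ndarray) -> float:
    """AUC of the Rutter–Gatsonis summary ROC implied by the bivariate fit.

    With σ1² = var(logit sens) and σ2² = var(logit spec), the HSROC shape
    is β = ln(σ2/σ1) and accuracy Λ = (σ2/σ1)^{1/2}·μ1 + (σ1/σ2)^{1/2}·μ2;
    the curve is logit(sens) = Λ·e^{−β/2} + e^{−β}·logit(FPR).  When the
    between-study variances vanish the shape degenerates to β = 0 (a
    symmetric curve through the summary point).
    """
    sd1 = math.sqrt(max(psi[0, 0], 0.0))
    sd2 = math.sqrt(max(psi[1, 1], 0.0))
    if sd1 < 1e-6 or sd2 < 1e-6:
        beta = 0.0
        lam = mu[0] + mu[1]
    else:
        beta = math.log(sd2 / sd1)
        lam = math.sqrt(sd2 / sd1) * mu[0] + math.sqrt(sd1 / sd2) * mu[1]

    def sens_at(fpr: float) -> float:
        lf = logit(min(max(fpr, 1e-12), 1.0 - 1e-12))
        return float(expit(lam * math.exp(-beta / 2.0) + math.exp(-beta) * lf))

    auc, _ = quad(sens_at, 0.0, 1.0, limit=200)
    return float(auc)


def sroc_points(summary: DiagnosticSummary, n: int = 101) -> list[tuple[float, float]]:
    """Sample (FPR, sensitivity) points of the fitted summary ROC curve."""
    mu = np.array(summary.mu)
    p11, p22, p12 = summary.psi
    psi = np.array([[p11, p12], [p12, p22]])
    sd1, sd2 = math.sqrt(max(p11, 0.0)), math.sqrt(max(p22, 0.0))
    if sd1 < 1e-6 or sd2 < 1e-6:
        beta, lam = 0.0, mu[0] + mu[1]
    else:
        beta = math.log(sd2 / sd1)
        lam = math.sqrt(sd2 / sd1) * mu[0] + math.sqrt(sd1 / sd2) * mu[1]
    fprs = np.linspace(1e-6, 1 - 1e-6, n)
    return [
        (float(f), float(expit(lam * math.exp(-beta / 2) + math.exp(-beta) * logit(f))))
        for f in fprs
    ]


def _univariate_dl(y: np.ndarray, s: np.ndarray):
    """Independent DerSimonian–Laird pooling of each logit axis (fallback)."""
    mu = np.zeros(2)
    cov = np.zeros((2, 2))
    psi = np.zeros((2, 2))
    for j in range(2):
        w = 1.0 / s[:, j]
        est = np.sum(w * y[:, j]) / np.sum(w)
        q = np.sum(w * (y[:, j] - est) ** 2)
        df = len(y) - 1
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
        ws = 1.0 / (s[:, j] + tau2)
        mu[j] = np.sum(ws * y[:, j]) / np.sum(ws)
        cov[j, j] = 1.0 / np.sum(ws)
        psi[j, j] = tau2
    return mu, cov, psi


def pool_diagnostics(tables: Sequence[TwoByTwo]) -> DiagnosticSummary:
    """Pool per-dataset 2×2 tables into a diagnostic summary.

    A 0.5 continuity correction is added to every cell of any table with a
    zero cell.  The bivariate REML model is attempted first; on failure the
    univariate DerSimonian–Laird fallback is used and flagged via
    ``method``.  Requires k ≥ 3 tables.
    """
    if len(tables) < 3:
        raise ValueError("diagnostic pooling needs at least 3 tables")
    y, s = _logit_pairs(tables)
    try:
        mu, cov, psi = _fit_bivariate(y, s)
        method = "bivariate_reml"
    except (RuntimeError, np.linalg.LinAlgError):
        mu, cov, psi = _univariate_dl(y, s)
        method = "univariate_dl"

    sens, spec = float(expit(mu[0])), float(expit(mu[1]))
    se1, se2 = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    sens_ci = (float(expit(mu[0] - Z95 * se1)), float(expit(mu[0] + Z95 * se1)))
    spec_ci = (float(expit(mu[1] - Z95 * se2)), float(expit(mu[1] + Z95 * se2)))

    def ratio_ci(value: float, grad: np.ndarray) -> tuple[float, float]:
        var = float(grad @ cov @ grad)
        half = Z95 * math.sqrt(max(var, 0.0))
        return (value * math.exp(-half), value * math.exp(half))

    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    dor = plr / nlr
    # gradients of log PLR / log NLR / log DOR w.r.t. (mu1, mu2)
    plr_ci = ratio_ci(plr, np.array([1.0 - sens, spec]))
    nlr_ci = ratio_ci(nlr, np.array([-sens, -(1.0 - spec)]))
    dor_ci = ratio_ci(dor, np.array([1.0, 1.0]))

    auc = _hsroc_auc(mu, psi)
    # delta-method CI for the AUC w.r.t. the summary means (Psi held fixed)
    eps = 1e-5
    grad = np.array([
        (_hsroc_auc(mu + np.array([eps, 0.0]), psi) - _hsroc_auc(mu - np.array([eps, 0.0]), psi)) / (2 * eps),
        (_hsroc_auc(mu + np.array([0.0, eps]), psi) - _hsroc_auc(mu - np.array([0.0, eps]), psi)) / (2 * eps),
    ])
    auc_se = math.sqrt(max(float(grad @ cov @ grad), 0.0))
    auc_ci = (max(0.0, auc - Z95 * auc_se), min(1.0, auc + Z95 * auc_se))

    return DiagnosticSummary(
        sens=sens, sens_ci=sens_ci, spec=spec, spec_ci=spec_ci,
        plr=float(plr), plr_ci=plr_ci, nlr=float(nlr), nlr_ci=nlr_ci,
        dor=float(dor), dor_ci=dor_ci, sroc_auc=auc, sroc_auc_ci=auc_ci,
        k=len(tables), method=method,
        mu=(float(mu[0]), float(mu[1])),
        psi=(float(psi[0, 0]), float(psi[1, 1]), float(psi[0, 1])),
    )
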