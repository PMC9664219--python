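"""REML estimation of genomic variance components (GREML).

The model is y = 1 mu + sum_k g_k + e with g_k ~ N(0, sigma2_k K_k) for a
set of relationship kernels K_k (A, AA, AA_intra, ..., all n x n) and
e ~ N(0, sigma2_e I).  The REML log-likelihood (constants dropped) is

    l = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ],
    V = sum_k sigma2_k K_k + sigma2_e I,
    P = V^-1 - V^-1 X (X'V^-1 X)^- X'V^-1,   X = column of ones.

Two update rules are provided and combined:

* EM-REML — sigma2_k <- sigma2_k + sigma2_k^2 (y'P K_k P y - tr(K_k P)) / n,
  with K = I for the residual.  Slow near the optimum but monotone in the
  REML likelihood and unconditionally stable: good for warm-up.
* AI-REML — a quasi-Newton step using the average-information matrix
  AI_jk = 1/2 y'P K_j P K_k P y and score
  s_k = -1/2 [tr(K_k P) - y'P K_k P y].  Fast near the optimum; whenever a
  proposed step leaves the feasible region (a variance below the floor),
  fails to increase the likelihood, or the AI matrix is singular, the
  iteration falls back to an EM step.

``fit_greml`` runs a few EM warm-up iterations and then AI steps until the
largest relative parameter change drops below tolerance.  Variances are
floored at a small fraction of var(y); a component estimated at the floor
is effectively a zero-heritability component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import linalg

from .grm import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "HeritabilityEstimate",
    "reml_loglik",
    "reml_em_step",
    "reml_ai_step",
    "fit_greml",
    "heritability_from_vc",
    "save_greml_json",
]

RESIDUAL = "residual"


@dataclass
class VarianceComponents:
    """Estimated variances per genetic component plus the residual."""

    sigma2: dict[str, float]
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False

    def genetic_labels(self) -> list[str]:
        return [k for k in self.sigma2 if k != RESIDUAL]

    def copy_with(self, sigma2: dict[str, float], **kw) -> "VarianceComponents":
        out = VarianceComponents(dict(sigma2), self.loglik, self.n_iter, self.converged)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


def save_greml_json(
    path,
    vc: "VarianceComponents",
    h2: "HeritabilityEstimate | None" = None,
) -> None:
    """Write variance components (and heritabilities) as JSON."""
    import json

    out = {
        "sigma2": {k: float(v) for k, v in vc.sigma2.items()},
        "loglik": float(vc.loglik),
        "n_iter": vc.n_iter,
        "converged": vc.converged,
    }
    if h2 is not None:
        out["h2"] = {k: float(v) for k, v in h2.h2.items()}
        out["total_h2"] = float(h2.total_h2)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)


@dataclass
class HeritabilityEstimate:
    """Per-component genomic heritabilities on the phenotypic-variance scale.

    h2[c] = sigma2_c * meandiag(K_c) / (sum_k sigma2_k meandiag(K_k) + sigma2_e);
    with mean-diagonal-one kernels this is the plain variance ratio.
    """

    h2: dict[str, float]
    total_h2: float


def _kernel_values(K_list: Mapping[str, RelationshipMatrix | np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for label, K in K_list.items():
        out[label] = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    return out


class _RemlWorkspace:
    """Per-iterate quantities shared by the likelihood, EM and AI updates.

    X is the single column of ones, so the projection P = V^-1 - vv'/s with
    v = V^-1 1 and s = 1'V^-1 1 is a rank-one correction of V^-1; traces of
    K P and quadratic forms in P reduce to dense solves plus dot products.
    """

    def __init__(self, y: np.ndarray, kernels: dict[str, np.ndarray], vc: VarianceComponents):
        self.y = y
        self.kernels = kernels
        n = len(y)
        V = vc.sigma2[RESIDUAL] * np.eye(n)
        for label in vc.genetic_labels():
            V += vc.sigma2[label] * kernels[label]
        try:
            cho = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                "V is not positive definite; raise the variance floor or add jitter"
            ) from err
        self.Vinv = linalg.cho_solve(cho, np.eye(n), check_finite=False)
        self.logdetV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        ones = np.ones(n)
        self.v = self.Vinv @ ones
        self.s = float(ones @ self.v)  # X'V^-1 X
        self.Py = self.Vinv @ y - self.v * (self.v @ y) / self.s
        self.yPy = float(y @ self.Py)
        self.loglik = -0.5 * (self.logdetV + np.log(self.s) + self.yPy)
        self.n = n

    def tr_KP(self, label: str | None) -> float:
        """tr(K P); label None means the residual kernel K = I."""
        if label is None:
            return float(np.trace(self.Vinv)) - float(self.v @ self.v) / self.s
        K = self.kernels[label]
        return float(np.sum(K * self.Vinv)) - float(self.v @ (K @ self.v)) / self.s

    def KPy(self, label: str | None) -> np.ndarray:
        return self.Py if label is None else self.kernels[label] @ self.Py

    def P_dot(self, x: np.ndarray) -> np.ndarray:
        return self.Vinv @ x - self.v * (self.v @ x) / self.s


def reml_loglik(
    y: np.ndarray,
    K_list: Mapping[str, RelationshipMatrix | np.ndarray],
    vc: VarianceComponents,
) -> float:
    """REML log-likelihood (additive constant dropped) at the given variances."""
    return _RemlWorkspace(np.asarray(y, float), _kernel_values(K_list), vc).loglik


def _floor(vc_sigma2: dict, floor: float) -> dict:
    return {k: max(v, floor) for k, v in vc_sigma2.items()}


def _em_sigma2(ws: _RemlWorkspace, vc: VarianceComponents, floor: float) -> dict[str, float]:
    new = {}
    for label, s2 in vc.sigma2.items():
        lab = None if label == RESIDUAL else label
        KPy = ws.KPy(lab)
        new[label] = s2 + s2**2 * (float(ws.Py @ KPy) - ws.tr_KP(lab)) / ws.n
    return _floor(new, floor)


def reml_em_step(
    y: np.ndarray,
    K_list: Mapping[str, RelationshipMatrix | np.ndarray],
    vc: VarianceComponents,
    floor: float = 0.0,
) -> VarianceComponents:
    """One EM-REML update of every variance; never decreases the likelihood."""
    y = np.asarray(y, float)
    kernels = _kernel_values(K_list)
    ws = _RemlWorkspace(y, kernels, vc)
    new = _em_sigma2(ws, vc, floor)
    loglik = _RemlWorkspace(y, kernels, vc.copy_with(new)).loglik
    return vc.copy_with(new, loglik=loglik, n_iter=vc.n_iter + 1)


def reml_ai_step(
    y: np.ndarray,
    K_list: Mapping[str, RelationshipMatrix | np.ndarray],
    vc: VarianceComponents,
    floor: float = 0.0,
    n_halvings: int = 5,
) -> VarianceComponents:
    """One AI-REML update with step-halving and EM fallback.

    The full quasi-Newton step is tried first; if it leaves the feasible
    region (a variance below the floor) or would decrease the likelihood,
    the step is halved up to ``n_halvings`` times.  When no halved step is
    acceptable either — or the AI matrix is singular — the iteration falls
    back to the EM update (logged, not an error).  ``n_halvings=0`` gives
    the plain accept-or-EM rule.
    """
    y = np.asarray(y, float)
    kernels = _kernel_values(K_list)
    ws = _RemlWorkspace(y, kernels, vc)
    labels = list(vc.sigma2)
    q = len(labels)
    PKy = {lab: ws.P_dot(ws.KPy(None if lab == RESIDUAL else lab)) for lab in labels}
    KPy = {lab: ws.KPy(None if lab == RESIDUAL else lab) for lab in labels}
    AI = np.empty((q, q))
    score = np.empty(q)
    for a, la in enumerate(labels):
        score[a] = -0.5 * (ws.tr_KP(None if la == RESIDUAL else la) - float(ws.Py @ KPy[la]))
        for b, lb in enumerate(labels):
            AI[a, b] = 0.5 * float(KPy[la] @ PKy[lb])

    def fallback(reason: str) -> VarianceComponents:
        logger.info("AI step fell back to EM: %s", reason)
        new = _em_sigma2(ws, vc, floor)
        loglik = _RemlWorkspace(y, kernels, vc.copy_with(new)).loglik
        return vc.copy_with(new, loglik=loglik, n_iter=vc.n_iter + 1)

    try:
        delta = linalg.solve(AI, score, assume_a="sym")
    except linalg.LinAlgError:
        return fallback("AI matrix is singular")
    if not np.all(np.isfinite(delta)):
        return fallback("non-finite AI solution")

    sigma = np.array([vc.sigma2[lab] for lab in labels])

    def feasible(prop: np.ndarray) -> bool:
        return bool(np.all(prop >= floor)) and prop[labels.index(RESIDUAL)] > 0

    # Active-set reduction: components whose Newton move crosses the floor
    # are pinned there and the AI system is re-solved over the free ones.
    pinned: set[int] = set()
    step = delta.copy()
    for _ in range(q):
        prop = sigma + step
        below = {a for a in range(q) if prop[a] < floor}
        if not (below - pinned):
            break
        pinned |= below
        free = [a for a in range(q) if a not in pinned]
        if not free:
            break
        step = np.full(q, 0.0)
        for a in pinned:
            step[a] = floor - sigma[a]
        try:
            step[free] = linalg.solve(AI[np.ix_(free, free)], score[free], assume_a="sym")
        except linalg.LinAlgError:
            return fallback("reduced AI matrix is singular")

    candidates = [sigma + delta]  # full unconstrained Newton step first
    for t in range(n_halvings):
        candidates.append(np.maximum(sigma + step / 2.0**t, floor))
    for prop in candidates:
        if not feasible(prop):
            continue
        proposed = {lab: float(prop[a]) for a, lab in enumerate(labels)}
        try:
            loglik = _RemlWorkspace(y, kernels, vc.copy_with(proposed)).loglik
        except linalg.LinAlgError:
            continue
        if np.isfinite(loglik) and loglik >= ws.loglik - 1e-10:
            return vc.copy_with(proposed, loglik=loglik, n_iter=vc.n_iter + 1)
    return fallback("no feasible likelihood-increasing AI step")


def heritability_from_vc(
    vc: VarianceComponents, K_list: Mapping[str, RelationshipMatrix | np.ndarray]
) -> HeritabilityEstimate:
    """Heritabilities with each kernel weighted by its mean diagonal."""
    kernels = _kernel_values(K_list)
    contrib = {
        lab: vc.sigma2[lab] * float(np.mean(np.diag(kernels[lab])))
        for lab in vc.genetic_labels()
    }
    denom = sum(contrib.values()) + vc.sigma2[RESIDUAL]
    h2 = {lab: c / denom for lab, c in contrib.items()}
    return HeritabilityEstimate(h2, sum(h2.values()))


def fit_greml(
    y: np.ndarray,
    K_list: Mapping[str, RelationshipMatrix | np.ndarray],
    n_em: int = 3,
    tol: float = 1e-6,
    max_iter: int = 200,
    floor_frac: float = 1e-8,
    start: dict[str, float] | None = None,
) -> tuple[VarianceComponents, HeritabilityEstimate]:
    """Fit variance components by EM warm-up followed by AI-REML.

    Parameters
    ----------
    y
        Phenotype vector (pre-adjusted residuals; only records entering the
        fit — mask validation individuals out before calling).
    K_list
        Mapping label -> relationship kernel for each genetic component.
    n_em, tol, max_iter
        Schedule: ``n_em`` EM warm-up steps, then AI steps until
        max |delta sigma2| / var(y) < tol or ``max_iter`` total iterations.
    floor_frac
        Variance floor as a fraction of var(y); zero-variance components
        rest at the floor.
    start
        Optional starting values; default splits var(y) equally across all
        components (genetic + residual).

    Returns the converged components and the heritability estimates.
    """
    y = np.asarray(y, float)
    if len(K_list) < 1:
        raise ValueError("need at least one genetic component")
    for lab, K in _kernel_values(K_list).items():
        if K.shape != (len(y), len(y)):
            raise ValueError(f"kernel {lab!r} shape {K.shape} does not match n={len(y)}")
    vary = float(np.var(y, ddof=1))
    floor = floor_frac * vary
    if start is None:
        k = len(K_list) + 1
        start = {lab: vary / k for lab in K_list}
        start[RESIDUAL] = vary / k
    vc = VarianceComponents(_floor(dict(start), floor))
    vc.loglik = reml_loglik(y, K_list, vc)
    for it in range(max_iter):
        step = reml_em_step if it < n_em else reml_ai_step
        new = step(y, K_list, vc, floor=floor)
        delta = max(abs(new.sigma2[lab] - vc.sigma2[lab]) for lab in new.sigma2)
        vc = new
        logger.debug(
            "iter %d (%s): loglik=%.6f  %s",
            it + 1,
            "EM" if it < n_em else "AI",
            vc.loglik,
            "  ".join(f"{k}={v:.6g}" for k, v in vc.sigma2.items()),
        )
        if it >= n_em and delta / vary < tol:
            vc.converged = True
            break
    else:
        logger.warning("GREML did not converge in %d iterations", max_iter)
    return vc, heritability_from_vc(vc, K_list)
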