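"""Multi-component GBLUP and per-individual reliabilities.

Given estimated variance components, the mixed model
y = 1 mu + sum_k g_k + e is solved on the training records only (one
record per individual, incidence = identity):

    mu_hat = (X'V^-1 X)^- X'V^-1 y          over training records,
    g_hat_k = sigma2_k K_k[:, train] V^-1 (y_train - 1 mu_hat)   for all n,

so validation individuals receive predictions through their relationship
to the training set while contributing no phenotype.

The reliability of individual i (training or validation) is the squared
accuracy of its genetic-value prediction,

    rel_i = (G Ztr' P Ztr G)_ii / G_ii,

with G = sum_k sigma2_k K_k over the components of the model, Ztr the
selector of training records, and P the REML projection on the training
block.  Under an additive + A×A model the numerator expands into the four
blocks Ga..Ga, Gaa..Gaa and the two cross blocks; the total-genetic-value
reliability uses the full sum while per-component reliabilities use the
component's own block over its own denominator.  For an additive-only
model the A×A terms simply drop from numerator, V and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg

from .greml import RESIDUAL, VarianceComponents, _kernel_values
from .grm import RelationshipMatrix

__all__ = [
    "MixedModelFit",
    "ReliabilityRecord",
    "solve_mixed_model",
    "reliability",
    "prediction_table",
]

TRAIN, VALID = "T", "V"


@dataclass
class MixedModelFit:
    """Fitted mean, per-component GBLUP vectors and projection cache.

    ``role`` flags each individual as training ('T') or validation ('V').
    ``Py`` holds the projection of y (zero at validation rows, whose
    phenotypes never enter the solve).
    """

    mu_hat: float
    gblup: dict[str, np.ndarray]
    total_g: np.ndarray
    role: np.ndarray
    Py: np.ndarray
    sample_ids: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Per-individual table: id, role, each component, total."""
        idx = self.sample_ids if self.sample_ids is not None else np.arange(len(self.total_g))
        df = pd.DataFrame({"sample_id": idx, "role": self.role})
        for lab, g in self.gblup.items():
            df[f"gblup_{lab}"] = g
        df["gblup_total"] = self.total_g
        return df


@dataclass
class ReliabilityRecord:
    """Reliability (squared accuracy) and accuracy per component for one individual."""

    id: object
    role: str
    rel: dict[str, float]

    @property
    def r_i(self) -> dict[str, float]:
        return {k: float(np.sqrt(v)) for k, v in self.rel.items()}


def prediction_table(
    fit: MixedModelFit, recs: "list[ReliabilityRecord]", path=None
) -> pd.DataFrame:
    """Per-individual table (id, role, GBLUP per component and total,
    reliability per component and total), optionally written as TSV."""
    df = fit.to_frame()
    if recs:
        for key in recs[0].rel:
            df[f"rel_{key}"] = [r.rel[key] for r in recs]
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def _train_mask(mask, n: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError("training mask length must equal the kernel dimension")
    if not mask.any():
        raise ValueError("no training records: every phenotype is masked")
    return mask


def solve_mixed_model(
    y: np.ndarray,
    K_list: Mapping[str, RelationshipMatrix | np.ndarray],
    vc: VarianceComponents,
    train: np.ndarray | None = None,
    sample_ids: np.ndarray | None = None,
) -> MixedModelFit:
    """Solve GBLUP for all individuals from training phenotypes only.

    ``train`` is a boolean mask (True = phenotype used); default all True.
    Validation rows of y are ignored entirely.
    """
    y = np.asarray(y, float)
    kernels = _kernel_values(K_list)
    n = len(y)
    train = _train_mask(train if train is not None else np.ones(n, bool), n)
    tr = np.flatnonzero(train)
    yt = y[tr]
    nt = len(tr)

    V = vc.sigma2[RESIDUAL] * np.eye(nt)
    for lab in vc.genetic_labels():
        V += vc.sigma2[lab] * kernels[lab][np.ix_(tr, tr)]
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    ones = np.ones(nt)
    Vinv_y = linalg.cho_solve(cho, yt, check_finite=False)
    Vinv_1 = linalg.cho_solve(cho, ones, check_finite=False)
    s = float(ones @ Vinv_1)
    mu_hat = float(ones @ Vinv_y) / s
    resid_proj = Vinv_y - mu_hat * Vinv_1  # = V^-1 (y - 1 mu_hat) = P y

    gblup: dict[str, np.ndarray] = {}
    for lab in vc.genetic_labels():
        gblup[lab] = vc.sigma2[lab] * (kernels[lab][:, tr] @ resid_proj)
    total = np.sum(list(gblup.values()), axis=0) if gblup else np.zeros(n)
    role = np.where(train, TRAIN, VALID)
    Py = np.zeros(n)
    Py[tr] = resid_proj
    return MixedModelFit(mu_hat, gblup, total, role, Py, sample_ids)


def reliability(
    K_list: Mapping[str, RelationshipMatrix | np.ndarray],
    vc: VarianceComponents,
    train: np.ndarray,
    sample_ids: np.ndarray | None = None,
) -> list[ReliabilityRecord]:
    """Per-individual reliabilities of component and total genetic values.

    Returns one record per individual with reliabilities keyed by component
    label plus ``"total"``.  An individual whose genetic variance
    (denominator) is not positive gets reliability 0 with a warning.
    """
    labels = vc.genetic_labels()
    kernels = _kernel_values(K_list)
    n = kernels[labels[0]].shape[0]
    train = _train_mask(train, n)
    tr = np.flatnonzero(train)
    nt = len(tr)

    V = vc.sigma2[RESIDUAL] * np.eye(nt)
    for lab in labels:
        V += vc.sigma2[lab] * kernels[lab][np.ix_(tr, tr)]
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    Vinv = linalg.cho_solve(cho, np.eye(nt), check_finite=False)
    ones = np.ones(nt)
    v = Vinv @ ones
    P = Vinv - np.outer(v, v) / float(ones @ v)

    # B_k = sigma2_k K_k[:, train]; numerator blocks are B_a P B_b'
    B = {lab: vc.sigma2[lab] * kernels[lab][:, tr] for lab in labels}
    BP = {lab: B[lab] @ P for lab in labels}
    B_tot = np.sum(list(B.values()), axis=0)
    BP_tot = np.sum(list(BP.values()), axis=0)

    num = {lab: np.einsum("ij,ij->i", BP[lab], B[lab]) for lab in labels}
    num["total"] = np.einsum("ij,ij->i", BP_tot, B_tot)
    den = {lab: vc.sigma2[lab] * np.diag(kernels[lab]) for lab in labels}
    den["total"] = np.sum([den[lab] for lab in labels], axis=0)

    records = []
    warned = False
    for i in range(n):
        rel = {}
        for key in [*labels, "total"]:
            d = den[key][i]
            if d <= 0:
                if not warned:
                    warnings.warn(
                        "individual with nonpositive genetic variance; reliability set to 0",
                        stacklevel=2,
                    )
                    warned = True
                rel[key] = 0.0
            else:
                r = num[key][i] / d
                if r < -1e-8 or r > 1 + 1e-8:
                    warnings.warn(
                        f"reliability {r:.3g} outside [0,1] beyond tolerance", stacklevel=2
                    )
                rel[key] = float(min(max(r, 0.0), 1.0))
        rid = sample_ids[i] if sample_ids is not None else i
        records.append(ReliabilityRecord(rid, TRAIN if train[i] else VALID, rel))
    return records
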