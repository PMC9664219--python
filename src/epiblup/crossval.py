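"""k-fold cross-validation of genomic prediction accuracy.

Individuals are randomly divided into k validation populations (the first
k-1 of size floor(n/k), the last taking the remainder).  For each fold the
variance components are re-estimated on the training records only, GBLUP is
computed for everyone with the validation phenotypes masked, and four
accuracy measures are collected:

* Rhat0p — observed accuracy of predicting phenotypic values:
  corr(GBLUP total, y) within the validation population, averaged over folds.
* R0p — expected accuracy of predicting phenotypic values:
  mean(R0i) * sqrt(h2_k) with h2_k the training-population heritability.
* Rtilde0 — expected accuracy of predicting genetic values from the
  observed accuracy: Rhat0p_k / sqrt(h2_k).
* R0 — mean square-root reliability (accuracy of predicting genetic
  values) of the validation individuals.

Model comparisons report 100 * (acc_B - acc_A) / acc_A per fold and on the
means.  The reliability-level analysis pools the validation individuals of
all folds, sorts them by one model's total-genetic-value reliability into
threshold-defined levels, and compares prediction accuracy per level with
the competing model holding the *same number* of individuals per level
(sorted by its own reliability), so accuracy differences cannot be a
sample-size artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gblup import reliability, solve_mixed_model
from .greml import VarianceComponents, fit_greml, _kernel_values
from .grm import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "AccuracyReport",
    "assign_folds",
    "read_folds_tsv",
    "write_folds_tsv",
    "run_cv",
    "compare_models",
    "reliability_level_analysis",
]

MEASURES = ("Rhat0p", "R0p", "Rtilde0", "R0")


@dataclass
class FoldAssignment:
    """A partition of n individuals into folds 1..k."""

    fold_of: np.ndarray
    k: int
    seed: int

    def validation_mask(self, fold: int) -> np.ndarray:
        return self.fold_of == fold

    def sizes(self) -> np.ndarray:
        return np.bincount(self.fold_of, minlength=self.k + 1)[1:]


@dataclass
class AccuracyReport:
    """Per-fold and averaged accuracy measures for one model."""

    per_fold: pd.DataFrame  # fold, n0k, h2_k, Rhat0p, R0p, Rtilde0, R0
    means: dict[str, float]
    sd: dict[str, float]
    model: str = ""

    @classmethod
    def from_folds(cls, per_fold: pd.DataFrame, model: str = "") -> "AccuracyReport":
        means = {m: float(per_fold[m].mean()) for m in MEASURES}
        sd = {m: float(per_fold[m].std(ddof=1)) for m in MEASURES}
        return cls(per_fold, means, sd, model)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "model": self.model,
                    "means": self.means,
                    "sd": self.sd,
                    "per_fold": self.per_fold.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )

    def to_tsv(self, path) -> None:
        self.per_fold.to_csv(path, sep="\t", index=False)


def assign_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Randomly assign n individuals to k folds.

    Folds 1..k-1 have floor(n/k) individuals; fold k takes the remainder
    (e.g. n=6215, k=10 gives nine folds of 621 and a tenth of 626).
    """
    if k < 2:
        raise ValueError("need at least two folds")
    if n < k:
        raise ValueError(f"cannot split {n} individuals into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base = n // k
    fold_of = np.empty(n, dtype=int)
    for j in range(k):
        lo = j * base
        hi = (j + 1) * base if j < k - 1 else n
        fold_of[perm[lo:hi]] = j + 1
    return FoldAssignment(fold_of, k, seed)


def write_folds_tsv(folds: FoldAssignment, sample_ids, path) -> None:
    """Write the fold file as two-column TSV (sample_id, fold)."""
    pd.DataFrame({"sample_id": np.asarray(sample_ids), "fold": folds.fold_of}).to_csv(
        path, sep="\t", index=False
    )


def read_folds_tsv(path, sample_ids) -> FoldAssignment:
    """Read a fold file back, aligned to the given sample order."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    fold_of = df.loc[[str(s) for s in sample_ids], "fold"].to_numpy()
    return FoldAssignment(fold_of, int(fold_of.max()), seed=-1)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def run_cv(
    y: np.ndarray,
    K_list: Mapping[str, RelationshipMatrix | np.ndarray],
    folds: FoldAssignment,
    sample_ids: np.ndarray | None = None,
    model: str = "",
    greml_opts: dict | None = None,
) -> tuple[AccuracyReport, pd.DataFrame]:
    """Run the full cross-validation for one model.

    Per fold: GREML on training records only, GBLUP for all individuals
    with validation phenotypes masked, reliabilities, and the four accuracy
    measures.  Folds with fewer than 3 validation records are skipped with
    a warning (a correlation there is degenerate).

    Returns the accuracy report and a per-validation-individual store
    (sample_id, fold, y, GBLUP per component and total, reliability per
    component and total) pooled across folds, for the reliability-level
    analysis.
    """
    y = np.asarray(y, float)
    kernels = _kernel_values(K_list)
    n = len(y)
    ids = np.asarray(sample_ids) if sample_ids is not None else np.arange(n)
    greml_opts = dict(greml_opts or {})
    labels = list(kernels)

    rows, store_parts = [], []
    for fold in range(1, folds.k + 1):
        val = folds.validation_mask(fold)
        train = ~val
        n0k = int(val.sum())
        if n0k < 3:
            logger.warning("fold %d has %d validation records; skipped", fold, n0k)
            continue
        tr = np.flatnonzero(train)
        K_train = {lab: kernels[lab][np.ix_(tr, tr)] for lab in labels}
        vc, h2 = fit_greml(y[tr], K_train, **greml_opts)
        fit = solve_mixed_model(y, kernels, vc, train=train, sample_ids=ids)
        recs = reliability(kernels, vc, train, sample_ids=ids)

        h2_k = h2.total_h2
        ghat0 = fit.total_g[val]
        rhat0p = _corr(ghat0, y[val])
        r0i = np.array([np.sqrt(recs[i].rel["total"]) for i in np.flatnonzero(val)])
        r0_k = float(r0i.mean())
        r0p_k = r0_k * np.sqrt(h2_k)
        rtilde0_k = rhat0p / np.sqrt(h2_k)
        rows.append(
            {
                "fold": fold,
                "n0k": n0k,
                "h2_k": h2_k,
                "Rhat0p": rhat0p,
                "R0p": r0p_k,
                "Rtilde0": rtilde0_k,
                "R0": r0_k,
            }
        )

        part = pd.DataFrame({"sample_id": ids[val], "fold": fold, "y": y[val]})
        for lab in labels:
            part[f"gblup_{lab}"] = fit.gblup[lab][val]
            part[f"rel_{lab}"] = [recs[i].rel[lab] for i in np.flatnonzero(val)]
        part["gblup_total"] = fit.total_g[val]
        part["rel_total"] = [recs[i].rel["total"] for i in np.flatnonzero(val)]
        store_parts.append(part)

    report = AccuracyReport.from_folds(pd.DataFrame(rows), model)
    store = pd.concat(store_parts, ignore_index=True)
    return report, store


def compare_models(report_a: AccuracyReport, report_b: AccuracyReport) -> pd.DataFrame:
    """Percentage increase of model B over model A, per fold and on means.

    increase = 100 * (acc_B - acc_A) / acc_A for the observed accuracy
    Rhat0p (rows per fold, plus 'mean' and 'sd' summary rows).
    """
    a, b = report_a.per_fold, report_b.per_fold
    if not np.array_equal(a["fold"].values, b["fold"].values) or not np.array_equal(
        a["n0k"].values, b["n0k"].values
    ):
        raise ValueError("reports use different fold layouts")
    inc = 100.0 * (b["Rhat0p"].values - a["Rhat0p"].values) / a["Rhat0p"].values
    out = pd.DataFrame(
        {
            "fold": a["fold"].values,
            "Rhat0p_A": a["Rhat0p"].values,
            "Rhat0p_B": b["Rhat0p"].values,
            "increase_pct": inc,
        }
    )
    summary = pd.DataFrame(
        {
            "fold": ["mean", "sd"],
            "Rhat0p_A": [a["Rhat0p"].mean(), a["Rhat0p"].std(ddof=1)],
            "Rhat0p_B": [b["Rhat0p"].mean(), b["Rhat0p"].std(ddof=1)],
            "increase_pct": [
                100.0 * (report_b.means["Rhat0p"] - report_a.means["Rhat0p"])
                / report_a.means["Rhat0p"],
                float(np.std(inc, ddof=1)),
            ],
        }
    )
    return pd.concat([out, summary], ignore_index=True)


def reliability_level_analysis(
    store_a: pd.DataFrame,
    store_b: pd.DataFrame,
    thresholds: Sequence[float],
    min_level_size: int = 3,
) -> pd.DataFrame:
    """Compare prediction accuracy between two models per reliability level.

    Pooled validation individuals are cut into levels by model B's
    total-genetic-value reliability at the given ascending ``thresholds``.
    Model A's individuals are sorted by A's own reliability (ties broken by
    stable sample-id order) and grouped with the *same count* per level as
    model B, so each level compares equal numbers of (generally different)
    individuals.  Accuracy is corr(GBLUP total, y) per level; levels with
    fewer than ``min_level_size`` individuals report NaN.
    """
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    rel_b = store_b["rel_total"].to_numpy()
    level_b = np.digitize(rel_b, thresholds)  # 0 .. len(thresholds)
    n_levels = len(thresholds) + 1
    counts = np.bincount(level_b, minlength=n_levels)

    # model A: own-reliability descending order, same counts top-down
    order = np.lexsort((store_a["sample_id"].to_numpy(), -store_a["rel_total"].to_numpy()))
    level_a = np.empty(len(store_a), dtype=int)
    pos = 0
    for lev in range(n_levels - 1, -1, -1):
        level_a[order[pos : pos + counts[lev]]] = lev
        pos += counts[lev]

    rows = []
    for lev in range(n_levels):
        sel_b = level_b == lev
        sel_a = level_a == lev
        n_lev = int(counts[lev])
        acc_a = acc_b = float("nan")
        if n_lev >= min_level_size:
            acc_b = _corr(store_b.loc[sel_b, "gblup_total"], store_b.loc[sel_b, "y"])
            acc_a = _corr(store_a.loc[sel_a, "gblup_total"], store_a.loc[sel_a, "y"])
        lo = -np.inf if lev == 0 else thresholds[lev - 1]
        hi = np.inf if lev == n_levels - 1 else thresholds[lev]
        rows.append(
            {
                "level": lev + 1,
                "rel_lo": lo,
                "rel_hi": hi,
                "n": n_lev,
                "mean_rel_A": float(store_a.loc[sel_a, "rel_total"].mean()) if n_lev else np.nan,
                "mean_rel_B": float(store_b.loc[sel_b, "rel_total"].mean()) if n_lev else np.nan,
                "acc_A": acc_a,
                "acc_B": acc_b,
                "increase_pct": 100.0 * (acc_b - acc_a) / acc_a if acc_a else np.nan,
            }
        )
    return pd.DataFrame(rows)
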