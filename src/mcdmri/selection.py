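"""Voxel-wise model ranking by information criteria.

Each candidate model's maximised log-likelihood lnL is penalised for its
number of free parameters k:

    AIC = -2 lnL + 2 k
    BIC = -2 lnL + k ln n

with n the number of data points fitted in that voxel.  The best model
per voxel is the criterion argmin; ties are broken by parsimony
(smallest k) and then lexicographic name, so selection is
permutation-invariant in the model ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import get_model

__all__ = ["aic", "bic", "SelectionResult", "select_models", "summarise_relative"]


def aic(lnL, k):
    """Akaike information criterion -2 lnL + 2k."""
    if np.any(np.asarray(k) < 1):
        raise ValueError("k must be >= 1")
    return -2.0 * np.asarray(lnL, dtype=float) + 2.0 * np.asarray(k)


def bic(lnL, k, n):
    """Bayesian information criterion -2 lnL + k ln n."""
    if np.any(np.asarray(n) < 1):
        raise ValueError("n must be >= 1")
    return -2.0 * np.asarray(lnL, dtype=float) + np.asarray(k) * np.log(
        np.asarray(n, dtype=float)
    )


@dataclass
class SelectionResult:
    """Criterion table and winners for one voxel."""

    per_model: dict           # name -> dict(lnL, k, AIC, BIC)
    best_aic: str
    best_bic: str
    relative_aic: dict        # name -> criterion minus voxel-wise minimum
    relative_bic: dict


def _pick_best(values: dict) -> str:
    # argmin with parsimony tie-break, then name
    return min(
        values,
        key=lambda name: (values[name], get_model(name).k, name),
    )


def select_models(fits) -> SelectionResult | pd.DataFrame:
    """Rank models by AIC and BIC.

    ``fits`` is either a mapping model-name -> FitResult for a single
    voxel (returns a :class:`SelectionResult`), or a tidy DataFrame as
    produced by :func:`mcdmri.fitting.fit_volume` with rows for several
    models per voxel (returns a per-voxel DataFrame with criterion
    columns and winners; voxels missing any model are flagged
    ``complete=False`` and excluded from summaries).
    """
    if isinstance(fits, dict):
        return _select_single(fits)
    df = fits.copy()
    df["AIC"] = aic(df["lnL"], df["k_params"])
    df["BIC"] = bic(df["lnL"], df["k_params"], df["n"])
    n_models = df["model"].nunique()
    out_rows = []
    for (i, j, k), sub in df.groupby(["i", "j", "k"]):
        rec = {"i": i, "j": j, "k": k, "complete": len(sub) == n_models}
        for crit in ("AIC", "BIC"):
            vals = dict(zip(sub["model"], sub[crit]))
            best = _pick_best(vals)
            rec[f"best_{crit.lower()}"] = best
            rec[f"min_{crit.lower()}"] = vals[best]
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def _select_single(fits: dict) -> SelectionResult:
    per_model = {}
    for name, fr in fits.items():
        spec = get_model(name)
        per_model[name] = {
            "lnL": fr.lnL,
            "k": spec.k,
            "AIC": float(aic(fr.lnL, spec.k)),
            "BIC": float(bic(fr.lnL, spec.k, fr.n)),
        }
    aic_vals = {n: d["AIC"] for n, d in per_model.items()}
    bic_vals = {n: d["BIC"] for n, d in per_model.items()}
    best_a = _pick_best(aic_vals)
    best_b = _pick_best(bic_vals)
    rel_a = {n: v - aic_vals[best_a] for n, v in aic_vals.items()}
    rel_b = {n: v - bic_vals[best_b] for n, v in bic_vals.items()}
    return SelectionResult(per_model, best_a, best_b, rel_a, rel_b)


def summarise_relative(fits_df: pd.DataFrame) -> pd.DataFrame:
    """Distribution of relative criteria across voxels, per model.

    For every model, the criterion minus the voxel-wise minimum is
    summarised by median, quartiles and range -- the boxplot surface
    used to compare how well each model explains the data across a
    sample.
    """
    df = fits_df.copy()
    df["AIC"] = aic(df["lnL"], df["k_params"])
    df["BIC"] = bic(df["lnL"], df["k_params"], df["n"])
    n_models = df["model"].nunique()
    complete = df.groupby(["i", "j", "k"])["model"].transform("size") == n_models
    df = df[complete]
    for crit in ("AIC", "BIC"):
        df[f"rel_{crit}"] = df[crit] - df.groupby(["i", "j", "k"])[crit].transform(
            "min"
        )
    recs = []
    for model, sub in df.groupby("model"):
        rec = {"model": model}
        for crit in ("AIC", "BIC"):
            v = sub[f"rel_{crit}"].to_numpy()
            rec.update(
                {
                    f"{crit}_median": np.median(v),
                    f"{crit}_q1": np.percentile(v, 25),
                    f"{crit}_q3": np.percentile(v, 75),
                    f"{crit}_min": v.min(),
                    f"{crit}_max": v.max(),
                }
            )
        recs.append(rec)
    return pd.DataFrame(recs)
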