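"""GBLUP genomic prediction with additive, dominance and inbreeding terms.

Kernels: the VanRaden additive genomic relationship matrix G and a
heterozygosity-coded dominance matrix D.  Models (named after their
terms): A, A+F, A+D, A+D+F, where F enters as a fixed covariate — the
regression coefficient b on the genomic inbreeding coefficient is the
directional-dominance ("inbreeding depression") parameter.

The training-scenario evaluation holds out the dual-genotyped families
and trains on (1) parents at the amplicon panel's markers only, (2)
parents at the merged panel, (3) parents plus all non-test families at
the merged panel; accuracy is Pearson r (clamped at zero) and RMSE on
the held-out families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .gwas import mean_impute
from .lmm import LMMFit, blup, fit_multi_kernel, fit_single_kernel

RIDGE = 1e-6  # diagonal stabilization added to every kernel

MODELS = {"A": ("additive",), "AF": ("additive",),
          "AD": ("additive", "dominance"),
          "ADF": ("additive", "dominance")}
_WITH_F = {"AF", "ADF"}


# ---------------------------------------------------------------------------
# kernels

def additive_kernel(geno: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden G = WW' / (2 sum p(1-p)) on mean-imputed dosages."""
    if geno.n_individuals < 2:
        raise ValueError("need at least two individuals")
    d = mean_impute(geno)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    d, p = d[:, poly], p[poly]
    W = d - 2.0 * p
    denom = 2.0 * float((p * (1.0 - p)).sum())
    G = W @ W.T / denom + RIDGE * np.eye(d.shape[0])
    return pd.DataFrame(G, index=geno.individuals, columns=geno.individuals)


def dominance_kernel(geno: GenotypeMatrix) -> pd.DataFrame:
    """Classical heterozygosity-coded dominance relationship matrix.

    H_ik = 1{het} - 2 p_k (1 - p_k);  D = HH' / sum_k (2 p_k q_k)^2.
    Under Hardy-Weinberg proportions D is uncorrelated with the
    additive matrix.  A population with no heterozygous calls yields
    the zero matrix (with a warning).
    """
    if geno.n_individuals < 2:
        raise ValueError("need at least two individuals")
    d = mean_impute(geno)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    d, p = d[:, poly], p[poly]
    het = (d == 1.0).astype(float)
    if het.sum() == 0:
        warnings.warn("no heterozygous calls; dominance matrix is zero",
                      stacklevel=2)
        return pd.DataFrame(np.zeros((geno.n_individuals,) * 2),
                            index=geno.individuals, columns=geno.individuals)
    twopq = 2.0 * p * (1.0 - p)
    H = het - twopq
    denom = float((twopq ** 2).sum())
    D = H @ H.T / denom + RIDGE * np.eye(d.shape[0])
    return pd.DataFrame(D, index=geno.individuals, columns=geno.individuals)


# ---------------------------------------------------------------------------
# model fitting

@dataclass
class GPFit:
    """Fitted genomic-prediction model.

    ``genetic_values`` are total genetic BLUPs (sum over kernels) for
    every individual in the kernel, phenotyped or not;
    ``predictions`` adds the fixed part (intercept and, if in the
    model, b * F).
    """

    model: str
    fit: LMMFit
    inbreeding_b: float | None
    genetic_values: pd.Series
    predictions: pd.Series
    train_ids: list[str]


def fit_gblup(y: pd.Series, F_coeffs: pd.Series | None,
              kernels: dict[str, pd.DataFrame], model: str = "A") -> GPFit:
    """Fit a GBLUP model and predict all individuals in the kernels.

    Parameters
    ----------
    y
        Phenotypes indexed by individual; NaN marks unphenotyped
        (test) individuals, which still receive BLUPs.
    F_coeffs
        Marker-based (ROH) inbreeding coefficients, required for the
        models with an inbreeding fixed effect ("AF", "ADF").
    kernels
        "additive" (and "dominance" for AD/ADF) relationship matrices
        over all individuals, indexed consistently.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {list(MODELS)}")
    names = MODELS[model]
    use_f = model in _WITH_F
    ids = list(kernels["additive"].index)
    y = y.reindex(ids)
    train = y.index[y.notna()].tolist()
    if not train:
        raise ValueError("no phenotyped individuals to train on")
    yv = y.loc[train].to_numpy(float)
    X_all = np.ones((len(ids), 1))
    b_col = None
    if use_f:
        if F_coeffs is None:
            raise ValueError(f"model {model} requires inbreeding coefficients")
        f_all = F_coeffs.reindex(ids).to_numpy(float)
        if np.nanstd(f_all[[ids.index(t) for t in train]]) < 1e-10:
            warnings.warn("inbreeding coefficient is constant in training "
                          "data; dropping the inbreeding term", stacklevel=2)
            use_f = False
        else:
            X_all = np.column_stack([X_all, np.nan_to_num(f_all)])
            b_col = 1
    tr_idx = [ids.index(t) for t in train]
    X = X_all[tr_idx]
    k_train = {k: kernels[k].values[np.ix_(tr_idx, tr_idx)] for k in names}
    k_cross = {k: kernels[k].values[:, tr_idx] for k in names}
    if len(names) == 1:
        fit = fit_single_kernel(yv, X, k_train["additive"],
                                kernel_name="additive")
    else:
        fit = fit_multi_kernel(yv, X, k_train)
    effects = blup(fit, yv, X, k_train, k_cross)
    genetic = np.sum([effects[k] for k in names], axis=0)
    pred = X_all @ fit.beta + genetic
    b = float(fit.beta[b_col]) if (use_f and b_col is not None) else None
    return GPFit(model, fit, b,
                 pd.Series(genetic, index=ids, name="genetic_value"),
                 pd.Series(pred, index=ids, name="prediction"), train)


# ---------------------------------------------------------------------------
# accuracy metrics

def prediction_accuracy(predicted: pd.Series, observed: pd.Series
                        ) -> tuple[float, float]:
    """Pearson r (negative values clamped to zero) and RMSE."""
    common = predicted.index.intersection(observed.dropna().index)
    if len(common) < 3:
        raise ValueError("need at least three test individuals")
    a = predicted.loc[common].to_numpy(float)
    b = observed.loc[common].to_numpy(float)
    r = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else 0.0
    r = max(r, 0.0)
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    return r, rmse


def improvement_rate(r_with: float, r_without: float,
                     rmse_with: float, rmse_without: float
                     ) -> tuple[float | None, float | None]:
    """Accuracy-improvement ratios from adding the inbreeding term.

    r ratio = r_with / r_without and RMSE ratio = rmse_without /
    rmse_with, so values above 1 mean improvement on both scales.
    Undefined ratios (zero denominators) are returned as None.
    """
    r_ratio = r_with / r_without if r_without > 0 else None
    rmse_ratio = rmse_without / rmse_with if rmse_with > 0 else None
    return r_ratio, rmse_ratio


def project_inbreeding_effect(child_effect: float, generations: int) -> float:
    """Expected phenotype shift in a descendant ``generations`` down.

    The inbreeding contribution of an ancestor halves each generation,
    so the grandchild effect is half the child effect:
    effect = child_effect * (1/2)**(generations - 1).
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    return child_effect * 0.5 ** (generations - 1)


# ---------------------------------------------------------------------------
# training scenarios

def run_train_scenarios(merged: GenotypeMatrix, phenotypes: pd.Series,
                        design, scenarios=(1, 2, 3),
                        f_coeffs: pd.Series | None = None,
                        model: str = "A") -> pd.DataFrame:
    """Evaluate GBLUP under the three training-population designs.

    Test set: offspring of the dual-genotyped families.  Train 1 =
    parents, amplicon-panel (platform B) markers only; Train 2 =
    parents, merged markers; Train 3 = parents plus all non-test
    families, merged markers.  Returns r (clamped at 0), RMSE and n
    per scenario.
    """
    test_ids = [i for i in design.offspring_of(design.dual_families)
                if i in set(merged.individuals)]
    if not test_ids:
        raise ValueError("empty test set")
    rows = []
    for sc in scenarios:
        if sc == 1:
            train_pool = list(design.parental_ids)
            marker_mask = (merged.markers["platform"] == "B").values
        elif sc == 2:
            train_pool = list(design.parental_ids)
            marker_mask = np.ones(merged.n_markers, dtype=bool)
        elif sc == 3:
            others = design.offspring_of(design.single_families)
            train_pool = list(design.parental_ids) + others
            marker_mask = np.ones(merged.n_markers, dtype=bool)
        else:
            raise ValueError("scenario must be 1, 2 or 3")
        train_pool = [i for i in train_pool if i in set(merged.individuals)
                      and i in phenotypes.dropna().index]
        overlap = set(train_pool) & set(test_ids)
        if overlap:
            raise ValueError(f"training set contains test individuals: "
                             f"{sorted(overlap)[:5]}")
        ids = train_pool + test_ids
        sub = merged.subset(individuals=ids, marker_mask=marker_mask)
        kernels = {"additive": additive_kernel(sub)}
        if model in ("AD", "ADF"):
            kernels["dominance"] = dominance_kernel(sub)
        y = phenotypes.reindex(ids).copy()
        y.loc[test_ids] = np.nan  # hold out
        gp = fit_gblup(y, f_coeffs, kernels, model)
        r, rmse = prediction_accuracy(gp.predictions.loc[test_ids],
                                      phenotypes.reindex(test_ids))
        rows.append((f"Train {sc}", r, rmse, len(test_ids), len(train_pool)))
    return pd.DataFrame(rows, columns=["scenario", "r", "rmse", "n_test",
                                       "n_train"])
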