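"""Covariate design-matrix construction shared by the association fits.

All models adjust for sex, country (fixed-effect indicators, first country
as reference) and 10 ancestry principal components.  Constant columns are
dropped with a warning so stratified subsets (e.g. a single-country cohort)
stay full rank.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

PC_COLS = [f"pc{i}" for i in range(1, 11)]


def covariate_matrix(meta: pd.DataFrame, include_pcs: bool = True) -> tuple[np.ndarray, list[str]]:
    """Sex + country indicators + PCs for the rows of ``meta`` (no intercept)."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    sex = (meta["sex"].astype(str) == "male").astype(float).to_numpy()
    cols.append(sex)
    names.append("sex_male")
    countries = sorted(meta["country"].astype(str).unique())
    for c in countries[1:]:  # first country is the reference level
        cols.append((meta["country"].astype(str) == c).astype(float).to_numpy())
        names.append(f"country_{c}")
    if include_pcs:
        for c in PC_COLS:
            if c in meta.columns:
                cols.append(meta[c].to_numpy(float))
                names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(meta), 0))
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    if len(keep) < X.shape[1]:
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        warnings.warn(f"dropping constant covariate columns: {dropped}", stacklevel=2)
    return X[:, keep], [names[i] for i in keep]


def build_design(
    meta: pd.DataFrame,
    predictor: np.ndarray,
    predictor_name: str = "predictor",
    intercept: bool = True,
    include_pcs: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Assemble [intercept, predictor, covariates] for the rows of ``meta``."""
    cov, cov_names = covariate_matrix(meta, include_pcs=include_pcs)
    parts, names = [], []
    if intercept:
        parts.append(np.ones(len(meta)))
        names.append("intercept")
    parts.append(np.asarray(predictor, float))
    names.append(predictor_name)
    if cov.shape[1]:
        parts.append(cov)
        names.extend(cov_names)
    return np.column_stack(parts), names
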