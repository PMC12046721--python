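"""Fixed-effects design matrix with treatment coding.

Column order mirrors the reporting convention of the analysis: intercept,
three lending-trajectory dummies (reference = ``disinvested``), nine ADI
decile dummies Q2–Q10 (reference = Q1, the least deprived 10%), then the
raw Simpson diversity index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trajectory import REFERENCE_TRAJECTORY, TRAJECTORY_LEVELS

TRAJECTORY_DUMMIES = tuple(t for t in TRAJECTORY_LEVELS if t != REFERENCE_TRAJECTORY)
ADI_DUMMIES = tuple(f"adi_q{d}" for d in range(2, 11))

VALID_TERMS = ("trajectory", "adi_decile", "diversity")


def coefficient_names(covariates: tuple[str, ...] = VALID_TERMS) -> list[str]:
    names = ["intercept"]
    for term in covariates:
        if term == "trajectory":
            names.extend(TRAJECTORY_DUMMIES)
        elif term == "adi_decile":
            names.extend(ADI_DUMMIES)
        elif term == "diversity":
            names.append("diversity")
        else:
            raise ValueError(f"unknown model term {term!r}")
    return names


def build_design(
    table: pd.DataFrame, covariates: tuple[str, ...] = VALID_TERMS
) -> tuple[np.ndarray, list[str]]:
    """Build the n x p design matrix for the requested terms.

    Requires the relevant columns (``trajectory``, ``adi_decile``,
    ``diversity``) to be present and complete; excluded tracts must be
    dropped beforehand. A category entirely absent from the data would
    yield an all-zero dummy and is refused.
    """
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names = coefficient_names(covariates)
    for term in covariates:
        if term == "trajectory":
            traj = table["trajectory"].to_numpy()
            if (traj == "").any():
                raise ValueError("unclassified tracts present; drop excluded rows first")
            for level in TRAJECTORY_DUMMIES:
                col = (traj == level).astype(float)
                cols.append(col)
            missing = [lv for lv in TRAJECTORY_LEVELS if lv not in set(traj)]
            if missing:
                raise ValueError(f"trajectory categories absent from data: {missing}")
        elif term == "adi_decile":
            dec = table["adi_decile"].to_numpy(dtype=int)
            present = set(dec)
            missing_d = [d for d in range(1, 11) if d not in present]
            if missing_d:
                raise ValueError(f"ADI deciles absent from data: {missing_d}")
            for d in range(2, 11):
                cols.append((dec == d).astype(float))
        elif term == "diversity":
            div = table["diversity"].to_numpy(dtype=float)
            if np.isnan(div).any():
                raise ValueError("missing diversity values; drop flagged tracts first")
            cols.append(div)
        else:
            raise ValueError(f"unknown model term {term!r}")
    X = np.column_stack(cols)
    assert X.shape[1] == len(names)
    return X, names
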