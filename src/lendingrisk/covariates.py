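"""Tract-level covariate construction.

Racial diversity (Simpson's index over seven census race groups),
deprivation deciles from the raw area deprivation index (ADI), and
internally standardized expected counts with the implied standardized
mortality ratios (SMR).
"""

from __future__ import annotations

import warnings

import numpy as np

RACE_COLUMNS = (
    "race_white",
    "race_black",
    "race_native_american",
    "race_asian",
    "race_pacific_islander",
    "race_hispanic",
    "race_other",
)


def simpson_diversity(race_counts: np.ndarray) -> np.ndarray:
    """Simpson's index of diversity, ``1 - sum_k (n_k / N)^2``.

    Probability that two randomly drawn residents belong to different race
    groups; 0 for a single-group tract, at most ``1 - 1/K`` for ``K`` equal
    groups. Tracts with all-zero counts get NaN (undefined, flagged upstream).

    Parameters
    ----------
    race_counts
        ``(n_tracts, n_groups)`` nonnegative counts (or a single tract's
        1-D vector).
    """
    counts = np.asarray(race_counts, dtype=float)
    squeeze = counts.ndim == 1
    counts = np.atleast_2d(counts)
    if (counts < 0).any():
        raise ValueError("race counts must be nonnegative")
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = counts / total[:, None]
        out = 1.0 - (shares**2).sum(axis=1)
    out[total == 0] = np.nan
    return out[0] if squeeze else out


def adi_decile(adi: np.ndarray) -> np.ndarray:
    """Rank-based decile of the raw ADI, 1 = least deprived 10%.

    Ties are resolved by average rank, then stable input order, so every
    decile has size within one of ``n / 10``; assignment is invariant to
    monotone transforms of the index. All-equal input triggers a warning
    (the split is then pure input order).
    """
    x = np.asarray(adi, dtype=float)
    if np.isnan(x).any():
        raise ValueError("adi contains missing values; exclude those tracts first")
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 tracts to form deciles, got {n}; use fewer bins")
    if np.unique(x).size == 1:
        warnings.warn("all ADI values equal: decile assignment falls back to input order", stacklevel=2)
    # stable sort by value breaks ties in input order, matching average-rank + order
    order = np.argsort(x, kind="stable")
    deciles = np.empty(n, dtype=np.int64)
    positions = np.arange(n)
    deciles[order] = positions * 10 // n + 1
    return deciles


def expected_counts_and_smr(
    homicide_count: np.ndarray, population: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Internal standardization: ``E_i = pop_i * (sum y / sum pop)``, ``SMR_i = y_i / E_i``.

    The citywide crude rate is applied to each tract's population, so
    ``sum(E) == sum(y)`` by construction and the E-weighted mean SMR is 1.
    Zero-population tracts get ``E = 0`` and NaN SMR; a death in such a
    tract is a data error.
    """
    y = np.asarray(homicide_count, dtype=float)
    pop = np.asarray(population, dtype=float)
    if (y < 0).any():
        raise ValueError("homicide counts must be nonnegative")
    if pop.sum() <= 0:
        raise ValueError("total population is zero; cannot standardize")
    bad = (pop == 0) & (y > 0)
    if bad.any():
        raise ValueError(f"tracts {np.flatnonzero(bad).tolist()} have deaths but zero population")
    rate = y.sum() / pop.sum()
    expected = pop * rate
    with np.errstate(invalid="ignore", divide="ignore"):
        smr = y / expected
    smr[expected == 0] = np.nan
    return expected, smr
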