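"""Class characterization: exact contingency tests and survival comparison.

Two tools connect detected molecular subtypes to external phenotype data:

* **Fisher's exact test for r×c tables.** The null fixes both margins; the
  two-sided p-value sums the probabilities of all margin-consistent tables
  whose probability does not exceed that of the observed table (the
  probability-ordering convention, as in R's ``fisher.test``). Tables with
  up to six free cells are enumerated exhaustively; larger tables fall back
  to seeded Monte Carlo sampling with a reported standard error.

* **Kaplan-Meier / log-rank.** Product-limit survival estimates per class
  and the standard (unstratified) log-rank chi-square comparison, delegated
  to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SurvivalTable


# ---------------------------------------------------------------------------
# exact r x c Fisher test
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    p: float
    method: str                 # "exact" | "monte-carlo"
    se: float | None = None     # Monte Carlo standard error

    def __float__(self) -> float:
        return self.p


def _log_factorials(n: int) -> np.ndarray:
    return np.array([lgamma(i + 1) for i in range(n + 1)])


def _table_logprob(table: np.ndarray, lf: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a margin-fixed table."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = int(table.sum())
    lp = lf[rows].sum() + lf[cols].sum() - lf[total] - lf[table].sum()
    return float(lp)


def _enumerate_tables(row_margins: np.ndarray, col_margins: np.ndarray):
    """Yield every non-negative integer table with the given margins."""
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=int)

    def fill(row: int, col_remaining: np.ndarray):
        if row == r - 1:
            if np.all(col_remaining >= 0):
                table[row] = col_remaining
                yield table
            return
        target = row_margins[row]

        def fill_row(col: int, remaining: int):
            if col == c - 1:
                if 0 <= remaining <= col_remaining[col]:
                    table[row, col] = remaining
                    yield True
                return
            upper = min(remaining, col_remaining[col])
            for v in range(upper + 1):
                table[row, col] = v
                yield from fill_row(col + 1, remaining - v)

        for _ in fill_row(0, target):
            yield from fill(row + 1, col_remaining - table[row])

    yield from fill(0, col_margins.copy())


def _exact_two_by_c(t: np.ndarray, lf: np.ndarray, lp_obs: float,
                    tol: float) -> float:
    """Vectorized exhaustive two-sided p for a 2×c table.

    With two rows the table probability factorizes over columns,
    P = Π_j C(col_j, x_j) / C(N, R1), so all first-row vectors x can be
    enumerated on a dense grid and scored in one shot.
    """
    cols = t.sum(axis=0)
    r1 = int(t[0].sum())
    c = len(cols)
    # log C(col_j, x) per column over x = 0..col_j
    log_binoms = [lf[cols[j]] - lf[np.arange(cols[j] + 1)]
                  - lf[cols[j] - np.arange(cols[j] + 1)] for j in range(c)]
    lp = log_binoms[0]
    sums = np.arange(cols[0] + 1)
    for j in range(1, c - 1):
        lp = lp[:, None] + log_binoms[j][None, :]
        sums = sums[:, None] + np.arange(cols[j] + 1)[None, :]
        lp, sums = lp.ravel(), sums.ravel()
        keep = sums <= r1
        lp, sums = lp[keep], sums[keep]
    last = r1 - sums
    valid = (last >= 0) & (last <= cols[-1])
    lp = lp[valid] + log_binoms[-1][last[valid]]
    lp -= lf[int(cols.sum())] - lf[r1] - lf[int(cols.sum()) - r1]
    return float(np.exp(lp[lp <= lp_obs + tol]).sum())


def fisher_exact_rxc(table, mc_reps: int = 20000, seed: int = 0,
                     max_free_cells: int = 6) -> FisherResult:
    """Two-sided Fisher's exact test for an r×c contingency table.

    Exhaustive enumeration over all margin-fixed tables when the number of
    free cells (r−1)(c−1) is at most ``max_free_cells``; otherwise a seeded
    Monte Carlo estimate from Patefield-sampled tables, reporting the
    binomial standard error of the p estimate. Tables must have all row and
    column margins positive.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2×2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    total = int(t.sum())
    lf = _log_factorials(total)
    lp_obs = _table_logprob(t, lf)
    tol = 1e-7  # guards against float noise around ties, as in R

    free_cells = (t.shape[0] - 1) * (t.shape[1] - 1)
    if free_cells <= max_free_cells:
        if t.shape[0] == 2 or t.shape[1] == 2:
            p = _exact_two_by_c(t if t.shape[0] == 2 else t.T, lf, lp_obs, tol)
        else:
            p = 0.0
            for cand in _enumerate_tables(rows, cols):
                lp = _table_logprob(cand, lf)
                if lp <= lp_obs + tol:
                    p += np.exp(lp)
        return FisherResult(p=min(float(p), 1.0), method="exact")

    sampler = stats.random_table(rows, cols, seed=np.random.default_rng(seed))
    draws = sampler.rvs(size=mc_reps, method="patefield").astype(int)
    hits = sum(
        1 for k in range(mc_reps)
        if _table_logprob(draws[k], lf) <= lp_obs + tol
    )
    # add-one estimator keeps p in (0, 1]
    p = (hits + 1) / (mc_reps + 1)
    se = float(np.sqrt(p * (1 - p) / mc_reps))
    return FisherResult(p=float(p), method="monte-carlo", se=se)


# ---------------------------------------------------------------------------
# characteristic tables
# ---------------------------------------------------------------------------

@dataclass
class CharacteristicResult:
    characteristic: str
    counts: pd.DataFrame            # levels × classes
    percentages: pd.DataFrame       # of the total cohort
    fisher: FisherResult
    n_missing: int


def characteristic_table(labels: pd.Series, phenotypes: pd.DataFrame,
                         mc_reps: int = 20000, seed: int = 0) -> list[CharacteristicResult]:
    """Level × class count tables with Fisher p per phenotype characteristic.

    ``labels`` maps sample id → class; ``phenotypes`` is indexed by sample id
    with one categorical column per characteristic. Missing entries are
    dropped per characteristic (not listwise), and percentages refer to the
    total cohort size. A characteristic with fewer than two observed levels
    cannot be tested and is an error.
    """
    classes = sorted(labels.unique())
    cohort_n = len(labels)
    results = []
    for col in phenotypes.columns:
        values = phenotypes[col].reindex(labels.index)
        mask = values.notna()
        if mask.sum() == 0:
            raise ValueError(f"characteristic {col!r} has no observed values")
        observed = values[mask].astype(str)
        levels = sorted(observed.unique())
        if len(levels) < 2:
            raise ValueError(f"characteristic {col!r} has a single observed level")
        counts = pd.DataFrame(0, index=levels, columns=classes, dtype=int)
        for level in levels:
            for cls in classes:
                counts.loc[level, cls] = int(
                    ((observed == level) & (labels[mask.index[mask]] == cls)).sum()
                )
        fisher = fisher_exact_rxc(counts.to_numpy(), mc_reps=mc_reps, seed=seed)
        results.append(CharacteristicResult(
            characteristic=col,
            counts=counts,
            percentages=100.0 * counts / cohort_n,
            fisher=fisher,
            n_missing=int((~mask).sum()),
        ))
    return results


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate with at-risk counts and censor marks."""

    times: np.ndarray               # event/censoring time grid (ascending)
    survival: np.ndarray            # S(t) step values at those times
    at_risk: np.ndarray
    censor_times: np.ndarray


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate of the survival function."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    # at-risk counts just before each grid time
    order = np.sort(times)
    at_risk = len(times) - np.searchsorted(order, grid, side="left")
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk.astype(int),
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Unstratified log-rank test across ≥2 groups.

    Returns the chi-square statistic (groups − 1 degrees of freedom) and its
    p-value. Undefined when no events are observed in any group.
    """
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank needs at least two groups")
    if events.sum() == 0:
        raise ValueError("log-rank is undefined when every record is censored")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def survival_by_group(table: SurvivalTable) -> dict[str, KMCurve]:
    """One KM curve per group label of a survival table."""
    if "group" not in table.data.columns:
        raise ValueError("survival table has no 'group' column")
    out = {}
    for name, sub in table.data.groupby("group", sort=True):
        out[str(name)] = km_estimate(sub["time"].to_numpy(), sub["event"].to_numpy())
    return out
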