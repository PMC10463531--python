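"""Nonparametric repeated-measures statistical plan.

The plan mirrors a within-subject design with factors *session* (pre,
post0, post10) and *stimulation condition* (sham, peak, trough):
Shapiro-Wilk as a normality screen, Friedman's test as the omnibus over
sessions (and over conditions for the pre-session baselines), pairwise
Wilcoxon signed-rank post-hocs gated on a significant omnibus, and
Benjamini-Hochberg FDR correction within each measure's family of
pairwise contrasts.

Friedman uses mid-ranks with the standard tie correction and the
chi-square reference distribution (k-1 df).  The signed-rank test is
exact — full enumeration of the 2^n sign-assignment distribution via a
convolution over (doubled, hence integer) ranks — for n <= 25, and uses
the tie/continuity-corrected normal approximation beyond that.  Zeros
are dropped before ranking (Wilcoxon's original treatment); Pratt's
method is available by flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _sps

SESSIONS = ("pre", "post0", "post10")
CONDITIONS = ("sham", "peak", "trough")
SESSION_PAIRS = tuple(combinations(SESSIONS, 2))


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (normality screen only)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk defined for 3 <= n <= 5000 here")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    w, p = _sps.shapiro(x)
    return float(w), float(p)


def _midrank(row: np.ndarray) -> np.ndarray:
    order = np.argsort(row, kind="mergesort")
    ranks = np.empty(len(row))
    sorted_row = row[order]
    i = 0
    while i < len(row):
        j = i
        while j + 1 < len(row) and sorted_row[j + 1] == sorted_row[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def friedman_statistic(values: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square for a subjects x levels matrix."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = np.apply_along_axis(_midrank, 1, values)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(
        (col_sums - n * (k + 1) / 2) ** 2
    )
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0  # every subject constant across levels
    return float(stat / c)


def _exact_friedman_p(values: np.ndarray) -> float:
    """Exact permutation p for the Friedman statistic.

    Under H0 the k observations within each subject are exchangeable, so
    the reference distribution enumerates all (k!)^n within-row rank
    arrangements.  Because the tie correction is constant across
    arrangements, it suffices to track the distribution of the column
    rank-sum vector, built row by row over (doubled, hence integer)
    mid-ranks.
    """
    from collections import defaultdict
    from itertools import permutations

    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks2 = [tuple(np.rint(2 * _midrank(row)).astype(int)) for row in values]
    target = n * (k + 1)  # doubled expected column sum
    state: dict[tuple, int] = {tuple([0] * k): 1}
    for r in ranks2:
        new: dict[tuple, int] = defaultdict(int)
        for cols, cnt in state.items():
            for pm in permutations(r):  # k! arrangements, ties included
                new[tuple(c + x for c, x in zip(cols, pm))] += cnt
        state = new
    obs2 = np.rint(2 * np.apply_along_axis(_midrank, 1, values).sum(axis=0))
    obs_ssq = int(np.sum((obs2 - target) ** 2))
    hits = total = 0
    for cols, cnt in state.items():
        total += cnt
        if sum((c - target) ** 2 for c in cols) >= obs_ssq:
            hits += cnt
    return hits / total


#: largest cohort for which the exact permutation p is used by default
EXACT_FRIEDMAN_MAX_N = 12


def friedman(values, method: str = "auto") -> tuple[float, float]:
    """Friedman test over a subjects x levels matrix.

    Returns (chi-square statistic with tie correction, p).  ``method``
    is ``"chi2"`` (k-1 df reference distribution), ``"exact"`` (full
    permutation distribution), or ``"auto"`` (exact for n <= 12 subjects
    with k <= 5 levels — where the chi-square approximation is visibly
    off — chi-square otherwise).  Requires k >= 3 levels and n >= 2
    subjects.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a subjects x levels matrix")
    n, k = values.shape
    if k < 3:
        raise ValueError("Friedman needs >= 3 levels; use the Wilcoxon "
                         "signed-rank test for two paired levels")
    if n < 2:
        raise ValueError("Friedman needs >= 2 subjects")
    if method not in ("auto", "chi2", "exact"):
        raise ValueError(f"unknown method: {method!r}")
    stat = friedman_statistic(values)
    if stat == 0.0:
        return 0.0, 1.0
    if method == "auto":
        method = "exact" if (n <= EXACT_FRIEDMAN_MAX_N and k <= 5) else "chi2"
    if method == "exact":
        return stat, float(_exact_friedman_p(values))
    return stat, float(_sps.chi2.sf(stat, k - 1))


def _exact_signed_rank_p(ranks2: np.ndarray, w2_obs: float) -> float:
    """Two-sided exact p over all 2^n sign assignments.

    *ranks2* holds doubled mid-ranks (integers); the null distribution
    of the doubled positive-rank sum W+ is built by convolution.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w = int(round(w2_obs))
    p_le = dist[: w + 1].sum()
    p_ge = dist[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(diffs, zero_method: str = "wilcox") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns (W+, p).  Exact enumeration of the sign-assignment
    distribution for n <= 25 (after zero handling); tie/continuity
    corrected normal approximation otherwise.  ``zero_method`` is
    ``"wilcox"`` (drop zeros, default) or ``"pratt"``.
    """
    d = np.asarray(diffs, dtype=float)
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method: {zero_method!r}")
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    if zero_method == "wilcox":
        d = d[d != 0]
    ranks = _midrank(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        d, ranks = d[keep], ranks[keep]
    n = len(d)
    if n < 5:
        raise ValueError("need >= 5 nonzero paired differences")
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return w_plus, _exact_signed_rank_p(2 * ranks, 2 * w_plus)
    # normal approximation with tie correction
    mu = n * (n + 1) / 4
    tie_term = 0.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    return w_plus, float(2 * _sps.norm.sf(abs(z)))


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# the full testing scheme

@dataclass
class StatPlanResult:
    """Tidy outcome table of the full plan plus skipped-measure log."""

    table: pd.DataFrame  # measure, condition, test, contrast, statistic, raw_p, adj_p, significant
    alpha: float
    skipped: list[str] = field(default_factory=list)

    def omnibus(self) -> pd.DataFrame:
        return self.table[self.table["test"] == "friedman"]

    def posthoc(self) -> pd.DataFrame:
        return self.table[self.table["test"] == "wilcoxon"]


def run_stat_plan(
    data: pd.DataFrame,
    alpha: float = 0.05,
    fdr_scope: str = "per-measure",
    zero_method: str = "wilcox",
    friedman_method: str = "auto",
) -> StatPlanResult:
    """Run the full nonparametric plan on a long-form measure table.

    *data* has columns ``subject, condition, session, measure, value``.
    Per (measure, condition): Friedman over sessions; if significant at
    *alpha*, the three pairwise session contrasts by Wilcoxon signed
    rank, FDR-corrected within the measure's post-hoc family (or
    globally with ``fdr_scope="global"``).  Additionally, per measure, a
    Friedman over conditions on the pre-session baselines.  Measures
    with incomplete cells are skipped with a logged reason.
    """
    if fdr_scope not in ("per-measure", "global"):
        raise ValueError(f"unknown fdr_scope: {fdr_scope!r}")
    rows: list[dict] = []
    skipped: list[str] = []
    posthoc_keys: list[tuple] = []  # parallel to posthoc rows, for FDR families

    for measure in sorted(data["measure"].unique()):
        md = data[data["measure"] == measure]
        for condition in sorted(md["condition"].unique()):
            wide = (
                md[md["condition"] == condition]
                .pivot(index="subject", columns="session", values="value")
                .dropna()
            )
            if not set(SESSIONS) <= set(wide.columns) or len(wide) < 2:
                skipped.append(f"{measure}/{condition}: incomplete cells")
                continue
            wide = wide[list(SESSIONS)]
            chi2, p = friedman(wide.to_numpy(), method=friedman_method)
            rows.append(dict(measure=measure, condition=condition, test="friedman",
                             contrast="session", statistic=chi2, raw_p=p))
            if p < alpha:
                for a, b in SESSION_PAIRS:
                    try:
                        w, pw = wilcoxon_signed_rank(
                            wide[b].to_numpy() - wide[a].to_numpy(),
                            zero_method=zero_method,
                        )
                    except ValueError as err:
                        skipped.append(f"{measure}/{condition} {a}-{b}: {err}")
                        continue
                    rows.append(dict(measure=measure, condition=condition,
                                     test="wilcoxon", contrast=f"{a}-{b}",
                                     statistic=w, raw_p=pw))
                    posthoc_keys.append((measure, condition))

        # baseline comparability: Friedman over conditions at pre
        pre = (
            md[md["session"] == "pre"]
            .pivot(index="subject", columns="condition", values="value")
            .dropna()
        )
        if set(CONDITIONS) <= set(pre.columns) and len(pre) >= 2:
            chi2, p = friedman(pre[list(CONDITIONS)].to_numpy(), method=friedman_method)
            rows.append(dict(measure=measure, condition="(pre baselines)",
                             test="friedman", contrast="condition",
                             statistic=chi2, raw_p=p))
        else:
            skipped.append(f"{measure}: incomplete pre baselines")

    table = pd.DataFrame(
        rows, columns=["measure", "condition", "test", "contrast", "statistic", "raw_p"]
    )
    table["adj_p"] = table["raw_p"]
    ph_mask = table["test"] == "wilcoxon"
    if ph_mask.any():
        ph_idx = table.index[ph_mask]
        if fdr_scope == "global":
            table.loc[ph_idx, "adj_p"] = fdr_bh(table.loc[ph_idx, "raw_p"])
        else:
            keys = pd.Series(posthoc_keys, index=ph_idx)
            for _, idx in keys.groupby(keys).groups.items():
                table.loc[idx, "adj_p"] = fdr_bh(table.loc[idx, "raw_p"])
    table["significant"] = table["adj_p"] < alpha
    return StatPlanResult(table=table, alpha=alpha, skipped=skipped)
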