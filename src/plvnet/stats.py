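"""Group formation and permutation statistics.

Subjects are median-split on online BCI accuracy into High and Low
performers (subjects exactly at the median are excluded, giving balanced
groups for odd cohorts with distinct values).  Scale-averaged PLV is then
compared with a 2x2 factorial ANOVA — BCI group (High/Low) x imagined hand
(left/right) with interaction — whose p-values come from a permutation null
rather than the F distribution.  Post-hoc contrasts use two-sample
permutation t-tests (Welch statistic).  Significance across the 3 activity
types x 2 bands is Bonferroni-controlled at 0.05/6.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

EFFECTS = ("group", "hand", "interaction")
PERM_SCHEMES = ("subject", "manly", "freedman_lane")


@dataclass
class GroupAssignment:
    """Median-split outcome: subject -> 'High'/'Low', plus exclusions."""

    group: dict
    accuracy: dict
    excluded: tuple
    median: float

    @property
    def high(self) -> tuple:
        return tuple(s for s, g in self.group.items() if g == "High")

    @property
    def low(self) -> tuple:
        return tuple(s for s, g in self.group.items() if g == "Low")


@dataclass(frozen=True)
class PermutationResult:
    """One effect of the permutation factorial ANOVA."""

    effect: str
    F_obs: float
    p_perm: float
    n_perm: int
    seed: int | None = None
    alpha_adjusted: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.alpha_adjusted is None:
            return None
        return self.p_perm <= self.alpha_adjusted


def median_split(accuracies) -> GroupAssignment:
    """Split subjects at the median accuracy.

    Strictly above the median -> High, strictly below -> Low, exactly at the
    median -> excluded.  With an odd cohort of distinct values this removes
    one subject and leaves equal-sized groups.
    """
    acc = dict(pd.Series(dict(accuracies)).items())
    if len(acc) < 3:
        raise ValueError("median split needs at least 3 subjects")
    values = np.array(list(acc.values()), float)
    if np.ptp(values) == 0:
        raise ValueError("all accuracies identical: no split possible")
    med = float(np.median(values))
    group, excluded = {}, []
    for s, a in acc.items():
        if a > med:
            group[s] = "High"
        elif a < med:
            group[s] = "Low"
        else:
            excluded.append(s)
    return GroupAssignment(group=group, accuracy=acc,
                           excluded=tuple(excluded), median=med)


# ---------------------------------------------------------------------------
# factorial permutation ANOVA
# ---------------------------------------------------------------------------

def _design(table: pd.DataFrame):
    """Validate the 2x2 layout and return (y, A, B, n_subjects).

    ``table`` needs columns subject_id, group, hand, value with exactly one
    row per subject x hand.  Rows are sorted (subject, hand) so that
    subject-block permutation schemes can rely on the layout.
    """
    required = {"subject_id", "group", "hand", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"ANOVA table needs columns {sorted(required)}")
    t = table.sort_values(["subject_id", "hand"]).reset_index(drop=True)
    per_subj = t.groupby("subject_id")["hand"].nunique()
    if (t.groupby(["subject_id", "hand"]).size() != 1).any() or \
            (per_subj != 2).any():
        raise ValueError("need exactly one value per subject x hand")
    groups = t.groupby("subject_id")["group"].nunique()
    if (groups != 1).any():
        raise ValueError("a subject appears in both groups")
    counts = t.groupby(["group", "hand"]).size()
    if len(counts) != 4 or counts.min() == 0:
        raise ValueError("empty cell in the 2x2 design")
    n_high = (t.groupby("subject_id")["group"].first() == "High").sum()
    n_low = t["subject_id"].nunique() - n_high
    if n_high != n_low:
        raise ValueError("groups must be equal-sized (median split "
                         "guarantees this); got "
                         f"{n_high} High vs {n_low} Low")
    y = t["value"].to_numpy(float)
    a = np.where(t["group"].to_numpy() == "High", 1.0, -1.0)
    b = np.where(t["hand"].to_numpy() == t["hand"].min(), 1.0, -1.0)
    return y, a, b, t["subject_id"].nunique()


def _f_stats(y: np.ndarray, contrasts: np.ndarray) -> np.ndarray:
    """F statistics for orthogonal +/-1 contrasts.

    ``y`` may be (N,) or (P, N); returns (3,) or (P, 3).  With the balanced
    design the three contrasts are mutually orthogonal, so Type I/II/III
    sums of squares coincide.
    """
    y = np.atleast_2d(np.asarray(y, float))
    n = y.shape[1]
    yc = y - y.mean(axis=1, keepdims=True)
    sst = np.einsum("pn,pn->p", yc, yc)
    proj = yc @ contrasts.T  # (P, 3)
    ss = proj ** 2 / np.einsum("en,en->e", contrasts, contrasts)
    sse = sst - ss.sum(axis=1)
    df_err = n - 4
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss / (sse / df_err)[:, None]
    f = np.nan_to_num(f, nan=0.0, posinf=np.inf)
    return f[0] if f.shape[0] == 1 else f


def _perm_indices_manly(rng, n_obs, n_perm):
    return np.argsort(rng.random((n_perm, n_obs)), axis=1)


def _perm_indices_block(rng, n_obs, n_subj, n_perm):
    """Permute subjects as blocks; both hand rows of a subject move together."""
    order = np.argsort(rng.random((n_perm, n_subj)), axis=1)
    base = np.arange(n_obs).reshape(n_subj, 2)
    return base[order].reshape(n_perm, n_obs)


def _perm_indices_swap(rng, n_obs, n_subj, n_perm):
    """Randomly swap the two hand rows within each subject."""
    base = np.broadcast_to(np.arange(n_obs).reshape(1, n_subj, 2),
                           (n_perm, n_subj, 2))
    swapped = base[:, :, ::-1]
    flip = rng.random((n_perm, n_subj, 1)) < 0.5
    return np.where(flip, swapped, base).reshape(n_perm, n_obs)


def perm_anova_2x2(table: pd.DataFrame, n_perm: int = 999, seed=None,
                   scheme: str = "subject",
                   alpha_adjusted: float | None = None) -> list:
    """Permutation 2x2 factorial ANOVA (group x hand, with interaction).

    Observed F statistics come from the classical balanced two-way ANOVA;
    the null distribution is built by permuting the response.  Schemes:

    * ``'subject'`` (default) respects the within-subject dependence of the
      two hand values: the group and interaction nulls shuffle whole
      subject blocks (equivalent to permuting group labels at the subject
      level), the hand null randomly swaps the two hand values within each
      subject.  Shuffling single observations instead would destroy the
      hand-pair correlation and make the group test anti-conservative.
    * ``'manly'`` shuffles all observations for every effect (valid when
      observations are exchangeable, e.g. one value per subject).
    * ``'freedman_lane'`` residualizes each effect under the reduced model
      before shuffling.

    p = (b + 1)/(B + 1) with b = #{F_perm >= F_obs}.  Returns a
    :class:`PermutationResult` per effect (group, hand, interaction).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in PERM_SCHEMES:
        raise ValueError(f"scheme must be one of {PERM_SCHEMES}")
    y, a, b, n_subj = _design(table)
    contrasts = np.vstack([a, b, a * b])
    f_obs = _f_stats(y, contrasts)
    rng = np.random.default_rng(seed)

    if scheme == "freedman_lane":
        exceed = np.zeros(3)
        x_full = np.vstack([np.ones_like(a), contrasts]).T  # orthogonal
        for e in range(3):
            reduced = np.delete(x_full, e + 1, axis=1)
            beta = np.linalg.lstsq(reduced, y, rcond=None)[0]
            fitted = reduced @ beta
            resid = y - fitted
            idx = _perm_indices_manly(rng, y.size, n_perm)
            y_star = fitted[None, :] + resid[idx]
            f_perm = _f_stats(y_star, contrasts)
            exceed[e] = np.sum(f_perm[:, e] >= f_obs[e])
    elif scheme == "manly":
        idx = _perm_indices_manly(rng, y.size, n_perm)
        f_perm = _f_stats(y[idx], contrasts)
        exceed = np.sum(f_perm >= f_obs[None, :], axis=0)
    else:  # subject
        idx_block = _perm_indices_block(rng, y.size, n_subj, n_perm)
        idx_swap = _perm_indices_swap(rng, y.size, n_subj, n_perm)
        f_block = _f_stats(y[idx_block], contrasts)
        f_swap = _f_stats(y[idx_swap], contrasts)
        exceed = np.array([np.sum(f_block[:, 0] >= f_obs[0]),
                           np.sum(f_swap[:, 1] >= f_obs[1]),
                           np.sum(f_block[:, 2] >= f_obs[2])])

    p = (exceed + 1.0) / (n_perm + 1.0)
    return [PermutationResult(effect=EFFECTS[e], F_obs=float(f_obs[e]),
                              p_perm=float(p[e]), n_perm=n_perm,
                              seed=None if seed is None else int(seed)
                              if np.isscalar(seed) else None,
                              alpha_adjusted=alpha_adjusted)
            for e in range(3)]


# ---------------------------------------------------------------------------
# post-hoc permutation t-test
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        return 0.0 if ma == mb else np.inf * np.sign(ma - mb)
    return float((ma - mb) / np.sqrt(se2))


def perm_ttest(values_a, values_b, n_perm: int = 999, seed=None,
               exact: bool = False):
    """Two-sample permutation t-test (Welch statistic, two-sided).

    ``exact=True`` enumerates all label assignments (small samples only)
    and returns the exact tail proportion including the identity; otherwise
    Monte-Carlo relabeling with p = (b + 1)/(B + 1).

    Returns ``(t_obs, p)``.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    t_obs = _welch_t(a, b)
    if t_obs == 0.0 and a.var(ddof=1) == b.var(ddof=1) == 0:
        return 0.0, 1.0
    pooled = np.concatenate([a, b])
    na = a.size
    if exact:
        total = comb(pooled.size, na)
        if total > 200_000:
            raise ValueError("too many relabelings for exact enumeration")
        hits = 0
        for ia in combinations(range(pooled.size), na):
            mask = np.zeros(pooled.size, bool)
            mask[list(ia)] = True
            if abs(_welch_t(pooled[mask], pooled[~mask])) >= abs(t_obs):
                hits += 1
        return t_obs, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(_welch_t(perm[:na], perm[na:])) >= abs(t_obs):
            hits += 1
    return t_obs, (hits + 1.0) / (n_perm + 1.0)


def bonferroni(alpha: float = 0.05, m: int = 6) -> float:
    """Bonferroni-adjusted per-test threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def format_alpha(alpha_adjusted: float) -> str:
    """3-decimal display of the adjusted threshold (0.05/6 -> '0.008')."""
    return f"{alpha_adjusted:.3f}"
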