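"""Trial filtering and group-level statistics.

All tests are computed from first-principles sums of squares rather than
delegated, so that the suite can cross-check them against independent
library implementations.  Effect sizes follow the conventional definitions:
eta^2 = SS_between / SS_total for the one-way design and partial
eta^2 = SS_effect / (SS_effect + SS_error) for repeated measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, PairingError, PipelineError

GROUP_ORDER = ("low", "medium", "high")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta2: float


@dataclass(frozen=True)
class RegressionResult:
    r2: float
    beta_std: float
    t: float
    df: int
    p: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class MixedAnovaResult:
    F_time: float
    p_time: float
    eta2p_time: float
    F_interaction: float
    p_interaction: float
    eta2p_interaction: float


def filter_rts(
    trials: pd.DataFrame, lo_ms: float = 200.0, hi_ms: float = 2000.0
) -> tuple[pd.DataFrame, float]:
    """Keep trials with lo_ms <= rt_ms <= hi_ms; report the excluded fraction.

    Raises :class:`PipelineError` naming the first participant whose trials
    are all excluded (their downstream metrics would be undefined).
    """
    if "rt_ms" not in trials.columns:
        raise DomainError("trial table lacks an rt_ms column")
    rt = trials["rt_ms"].to_numpy(dtype=float)
    if np.any(rt <= 0):
        raise DomainError("rt_ms must be positive")
    mask = (rt >= lo_ms) & (rt <= hi_ms)
    kept = trials.loc[mask]
    excluded_fraction = 1.0 - mask.mean() if len(trials) else 0.0
    if "participant_id" in trials.columns:
        before = set(trials["participant_id"].unique())
        after = set(kept["participant_id"].unique())
        lost = sorted(before - after)
        if lost:
            raise PipelineError(
                f"all trials excluded by the RT filter for participant {lost[0]}",
                stage="filter_rts",
                participant_id=lost[0],
            )
    return kept.reset_index(drop=True), float(excluded_fraction)


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise DomainError("values and groups must be 1-d and aligned")
    labels = ordered_labels(groups)
    cells = [values[groups == g] for g in labels]
    if len(cells) < 2:
        raise DomainError("need at least 2 groups")
    for g, cell in zip(labels, cells):
        if cell.size < 2:
            raise DomainError(f"group {g!r} has fewer than 2 members")
    return labels, cells


def ordered_labels(groups) -> list:
    """Unique group labels in low < medium < high order when applicable."""
    uniq = list(pd.unique(np.asarray(groups)))
    if set(uniq) <= set(GROUP_ORDER):
        return [g for g in GROUP_ORDER if g in uniq]
    return sorted(uniq)


def oneway_anova_eta2(values, groups) -> AnovaResult:
    """Classical one-way ANOVA with eta^2 = SS_between / SS_total."""
    _, cells = _split_groups(values, groups)
    all_vals = np.concatenate(cells)
    grand = all_vals.mean()
    ss_between = sum(c.size * (c.mean() - grand) ** 2 for c in cells)
    ss_within = sum(((c - c.mean()) ** 2).sum() for c in cells)
    ss_total = ss_between + ss_within
    df_b = len(cells) - 1
    df_w = all_vals.size - len(cells)
    if ss_total == 0:
        return AnovaResult(0.0, df_b, df_w, 1.0, 0.0)
    eta2 = ss_between / ss_total
    if ss_within == 0:
        return AnovaResult(float("inf"), df_b, df_w, 0.0, eta2)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p, float(eta2))


def bonferroni_pairwise(values, groups) -> pd.DataFrame:
    """All pairwise pooled-variance t-tests, Bonferroni-adjusted.

    ``mean_diff`` is first group minus second in the fixed label order
    (low < medium < high when those labels are used).
    """
    labels, cells = _split_groups(values, groups)
    by_label = dict(zip(labels, cells))
    pairs = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    rows = []
    for g1, g2 in pairs:
        a, b = by_label[g1], by_label[g2]
        n1, n2 = a.size, b.size
        df = n1 + n2 - 2
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        diff = a.mean() - b.mean()
        if se == 0:
            t = 0.0 if diff == 0 else float("inf") * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = float(2 * stats.t.sf(abs(t), df))
        rows.append(
            {
                "pair": f"{g1}-{g2}",
                "mean_diff": float(diff),
                "se": float(se),
                "t": float(t),
                "df": df,
                "p_adjusted": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def regress_auc_on_cortisol(summaries: pd.DataFrame | None = None, *, auc=None, c2=None) -> RegressionResult:
    """OLS of metacognitive AUC on the peak cortisol sample.

    Accepts either a per-participant summary frame (columns ``auc`` and
    ``c2_nmol_l``) or explicit arrays.  ``beta_std`` is the standardized
    slope (equal to Pearson r in simple regression), ``df = n - 2``.
    """
    if summaries is not None:
        auc = summaries["auc"].to_numpy(dtype=float)
        c2 = summaries["c2_nmol_l"].to_numpy(dtype=float)
    y = np.asarray(auc, dtype=float)
    x = np.asarray(c2, dtype=float)
    if y.size != x.size or y.size < 4:
        raise DomainError("need >= 4 aligned (auc, c2) observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("zero variance in AUC or C2; regression undefined")
    n = y.size
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    r = sxy / np.sqrt(sxx * ((y - ym) ** 2).sum())
    r2 = r**2
    df = n - 2
    if r2 >= 1.0:
        t = float("inf") * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r2))
        p = float(2 * stats.t.sf(abs(t), df))
    beta_std = slope * np.std(x, ddof=1) / np.std(y, ddof=1)
    return RegressionResult(
        r2=float(r2),
        beta_std=float(beta_std),
        t=float(t),
        df=df,
        p=p,
        slope=float(slope),
        intercept=float(intercept),
    )


def rm_anova_prepost(pre, post, groups) -> MixedAnovaResult:
    """Two-way mixed ANOVA: time (pre/post, within) x group (between).

    With only two within-subject levels sphericity holds trivially
    (epsilon = 1), so no Greenhouse-Geisser correction is needed.  When a
    mean square collapses to zero the F statistic is reported as 0 when the
    effect is also zero and +inf otherwise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    groups = np.asarray(groups)
    if not (pre.shape == post.shape == groups.shape) or pre.ndim != 1:
        raise PairingError("pre, post and groups must be aligned 1-d arrays")
    if np.any(np.isnan(pre)) or np.any(np.isnan(post)):
        raise PairingError("missing pre/post value; rows cannot be paired")
    labels = ordered_labels(groups)
    n_total = pre.size
    n_groups = len(labels)
    for g in labels:
        if (groups == g).sum() < 2:
            raise DomainError(f"group {g!r} has fewer than 2 members")

    y = np.stack([pre, post], axis=1)  # (subjects, 2)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)

    ss_between_subj = 2.0 * ((subj_means - grand) ** 2).sum()
    ss_group = 0.0
    ss_cells = 0.0
    for g in labels:
        sel = groups == g
        gmean = y[sel].mean()
        ss_group += 2.0 * sel.sum() * (gmean - grand) ** 2
        for s in range(2):
            cell = y[sel, s].mean()
            ss_cells += sel.sum() * (cell - gmean - time_means[s] + grand) ** 2
    ss_time = n_total * ((time_means - grand) ** 2).sum()
    ss_within_subj = ((y - subj_means[:, None]) ** 2).sum()
    ss_error_within = ss_within_subj - ss_time - ss_cells

    df_time = 1
    df_int = n_groups - 1
    df_err = n_total - n_groups
    ms_err = ss_error_within / df_err

    def f_and_p(ss_effect, df_effect):
        if ms_err <= 1e-300:
            if ss_effect <= 1e-12:
                return 0.0, 1.0
            return float("inf"), 0.0
        F = (ss_effect / df_effect) / ms_err
        return float(F), float(stats.f.sf(F, df_effect, df_err))

    F_time, p_time = f_and_p(ss_time, df_time)
    F_int, p_int = f_and_p(ss_cells, df_int)

    def eta2p(ss_effect):
        denom = ss_effect + ss_error_within
        return float(ss_effect / denom) if denom > 0 else 0.0

    return MixedAnovaResult(
        F_time=F_time,
        p_time=p_time,
        eta2p_time=eta2p(ss_time),
        F_interaction=F_int,
        p_interaction=p_int,
        eta2p_interaction=eta2p(ss_cells),
    )
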