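"""Cross-validated decoding performance and condition-level statistics.

The decoding score of a feature set is the area under the ROC curve (AUC) of
out-of-fold Gaussian-naive-Bayes posteriors under 4-fold cross-validation
with ReliefF top-6 feature selection refitted inside every training split.
AUC is the Mann-Whitney statistic: the probability that a randomly chosen
"upper" window is scored above a randomly chosen "lower" one, with ties
counted one half; 0.5 is chance.

Burst-conditioned AUC follows the two contact configurations used when six
directional contacts are available: the *same best three* contacts (the
triple maximizing the state-averaged AUC, applied to every state) or a
*different best three* per state.  The latter maximizes over a superset of
configurations, so it can never be smaller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

from . import features as feat
from . import gnb

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "upper"  # ROC scores are posteriors of this class

TASK_PERIODS = ("rest", "pre_cue", "pre_move", "post_move")


def auc(scores: np.ndarray, labels: np.ndarray,
        positive=POSITIVE_CLASS) -> float:
    """Mann-Whitney AUC of ``scores`` for the positive class (ties at 1/2).

    Returns NaN when only one class is present.
    """
    labels = np.asarray(labels)
    y = labels == positive
    if y.all() or not y.any():
        return float("nan")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def crossval_scores(
    X: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
    k_folds: int = 4,
    top_n: int = 6,
    n_neighbors: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, feat.SelectionResult]:
    """Out-of-fold posterior scores with per-fold selection and scaling.

    Every row is scored exactly once by a model that never saw it: folds are
    stratified at the trial (group) level, the scaler and the ReliefF ranking
    are fitted on the training split only, and a Gaussian naive Bayes model
    on the selected features scores the held-out rows.
    """
    rng = rng or np.random.default_rng()
    labels = np.asarray(labels)
    n = len(X)
    classes, counts = np.unique(labels, return_counts=True)
    k_eff = min(k_folds, int(counts.min()))
    if k_eff < k_folds:
        logger.warning("reducing folds from %d to %d (smallest class)",
                       k_folds, k_eff)
    sel = feat.select_and_score(X, labels, groups=groups, k_folds=k_eff,
                                top_n=top_n, n_neighbors=n_neighbors, rng=rng)
    scores = np.empty(n)
    for val, cols, (mu, sd) in zip(sel.fold_masks, sel.selected, sel.scalers):
        train = ~val
        Xs = (X - mu) / sd
        model = gnb.fit(Xs[train][:, cols], labels[train])
        scores[val] = gnb.score(model, Xs[val][:, cols], POSITIVE_CLASS)
    return scores, sel


def period_auc(window_auc: pd.DataFrame) -> pd.Series:
    """Period-level AUC: mean over a period's windows, then over contacts.

    ``window_auc`` is tidy with columns ``contact, period, t_center_s, auc``.
    Empty periods are reported missing.
    """
    per_contact = (window_auc.dropna(subset=["auc"])
                   .groupby(["period", "contact"])["auc"].mean())
    return per_contact.groupby("period").mean()


@dataclass
class ContactConfiguration:
    """Chosen contacts and per-state AUC for one averaging mode."""

    mode: str  # 'same_best_three' | 'different_best_three'
    contacts: dict[str, list[str]]  # state -> the three chosen contacts
    state_auc: dict[str, float]


def burst_conditioned_auc(
    state_auc: pd.DataFrame, n_best: int = 3
) -> dict[str, ContactConfiguration]:
    """Best-contact averaging of per-contact per-state AUC.

    ``state_auc`` is tidy with columns ``contact, state, auc`` (one row per
    contact per burst state; NaN where a state had too few windows).  In
    ``same_best_three`` mode the triple maximizing the state-averaged AUC is
    applied to all states; in ``different_best_three`` each state gets its
    own best triple.  By construction the latter is >= the former per state.
    """
    wide = state_auc.pivot(index="contact", columns="state", values="auc")
    configs: dict[str, ContactConfiguration] = {}

    mean_over_states = wide.mean(axis=1)
    complete = wide.notna().all(axis=1)
    if complete.sum() >= n_best:
        # prefer contacts with every state available, so the same-contact
        # triple yields a value for each state whenever possible
        mean_over_states = mean_over_states.where(complete, -np.inf)
    same = mean_over_states.sort_values(ascending=False).index[:n_best]
    configs["same_best_three"] = ContactConfiguration(
        mode="same_best_three",
        contacts={s: list(same) for s in wide.columns},
        state_auc={s: float(wide.loc[same, s].mean()) for s in wide.columns},
    )
    diff_contacts, diff_auc = {}, {}
    for s in wide.columns:
        best = wide[s].sort_values(ascending=False).index[:n_best]
        diff_contacts[s] = list(best)
        diff_auc[s] = float(wide.loc[best, s].mean())
    configs["different_best_three"] = ContactConfiguration(
        mode="different_best_three", contacts=diff_contacts,
        state_auc=diff_auc,
    )
    return configs


def compare_conditions(
    values: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Matched-samples comparison across conditions with the standard chain.

    ``values`` is wide: one row per subject/hemisphere, one column per
    condition.  The chain is: Lilliefors normality check per condition ->
    Box-Cox transform of all values if any condition is non-normal ->
    repeated-measures ANOVA (Mauchly sphericity; Greenhouse-Geisser
    correction applied when sphericity is violated) -> all pairwise paired
    t-tests -> Benjamini-Hochberg FDR.  All intermediate statistics are
    returned.  Refuses to run with fewer than 3 matched samples.
    """
    from statsmodels.stats.diagnostic import lilliefors
    from statsmodels.stats.multitest import multipletests
    import pingouin as pg

    values = values.dropna()
    n, m = values.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 matched samples")
    report: dict = {"n": n, "conditions": list(values.columns)}

    lillie = {}
    for c in values.columns:
        try:
            _, p = lilliefors(values[c].to_numpy(), dist="norm")
        except Exception:  # degenerate (constant) column
            p = 1.0
        lillie[c] = float(p)
    report["lilliefors_p"] = lillie
    non_normal = any(p < alpha for p in lillie.values())
    report["box_cox_applied"] = bool(non_normal)

    data = values.to_numpy(dtype=float)
    if non_normal:
        flat = data.ravel()
        shift = 0.0
        if flat.min() <= 0:
            shift = -flat.min() + 1e-6
        transformed, lam = sstats.boxcox(flat + shift)
        report["box_cox_lambda"] = float(lam)
        report["box_cox_shift"] = float(shift)
        data = transformed.reshape(data.shape)

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), m),
        "condition": np.tile(values.columns.to_numpy(), n),
        "value": data.ravel(),
    })
    if m > 2:
        sph = pg.sphericity(long, dv="value", within="condition",
                            subject="subject")
        report["mauchly_W"] = float(sph.W)
        report["mauchly_p"] = float(sph.pval)
        report["sphericity_ok"] = bool(sph.spher)
    else:
        report["sphericity_ok"] = True
    aov = pg.rm_anova(long, dv="value", within="condition",
                      subject="subject", correction=True, detailed=True)
    row = aov.iloc[0]
    use_gg = m > 2 and not report["sphericity_ok"]
    p_unc = next(c for c in ("p_unc", "p-unc") if c in aov.columns)
    p_gg = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns),
                None)
    report["anova_F"] = float(row["F"])
    report["anova_p"] = float(row[p_gg] if use_gg and p_gg else row[p_unc])
    report["gg_correction_used"] = bool(use_gg)
    if "eps" in aov.columns:
        report["gg_epsilon"] = float(row["eps"])

    pairs, tstats, pvals = [], [], []
    cols = list(values.columns)
    for i in range(m):
        for j in range(i + 1, m):
            tt = sstats.ttest_rel(data[:, i], data[:, j])
            pairs.append((cols[i], cols[j]))
            tstats.append(float(tt.statistic))
            pvals.append(float(tt.pvalue))
    if pvals:
        rej, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        report["posthoc"] = [
            {"pair": list(pr), "t": t, "p": p, "p_fdr": float(pa),
             "significant": bool(r)}
            for pr, t, p, pa, r in zip(pairs, tstats, pvals, p_adj, rej)
        ]
    return report
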