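"""Information-theoretic ensemble variable ranking and DeLong-test pruning.

Eight greedy forward-selection criteria from the mutual-information feature
selection literature (MIM, MRMR, CMIM, JMI, DISR, CIFE, ICAP, CONDRED) each
produce a full ranking of the candidate variables; the eight ranks are
averaged into an ensemble order.  Nested sets S_1 c S_2 c ... built along
that order are scored by cross-validated AUC, and the final selection is the
smallest set whose paired DeLong test against the best-performing set S_max
shows no significant AUC loss (p >= alpha).

Mutual information uses plug-in estimates on discretised data
(equal-frequency binning, 10 bins by default), in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from neurocascade.metrics import roc_auc

CRITERIA = ("mim", "mrmr", "cmim", "jmi", "disr", "cife", "icap", "condred")


# ---------------------------------------------------------------------------
# discrete information measures
# ---------------------------------------------------------------------------


def discretize(X: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning per column into integer codes 0..n_bins-1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    codes = np.empty_like(X, dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, j], qs))
        codes[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return codes


def _as_codes(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    _, codes = np.unique(v, return_inverse=True)
    return codes


def _joint_code(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a * (b.max() + 1) + b


def _entropy_from_codes(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    p = counts[counts > 0] / len(codes)
    return float(-np.sum(p * np.log(p)))


def entropy(x: np.ndarray) -> float:
    """Plug-in Shannon entropy H(X) in nats."""
    return _entropy_from_codes(_as_codes(x))


def joint_entropy(*vars_: np.ndarray) -> float:
    code = _as_codes(vars_[0])
    for v in vars_[1:]:
        code = _as_codes(_joint_code(code, _as_codes(v)))
    return _entropy_from_codes(code)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in I(X;Y) = H(X) + H(Y) - H(X,Y), in nats; nonnegative."""
    x, y = np.asarray(x), np.asarray(y)
    if len(x) == 0 or len(x) != len(y):
        raise ValueError("x and y must be nonempty and of equal length")
    mi = entropy(x) + entropy(y) - joint_entropy(x, y)
    return max(mi, 0.0)


def conditional_mutual_information(x, y, z) -> float:
    """I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z)."""
    cmi = joint_entropy(x, z) + joint_entropy(y, z) - entropy(z) - joint_entropy(x, y, z)
    return max(cmi, 0.0)


# ---------------------------------------------------------------------------
# greedy criterion rankings
# ---------------------------------------------------------------------------


def rank_by_criterion(data: np.ndarray, labels: np.ndarray, criterion: str) -> np.ndarray:
    """Full greedy forward-selection ranking under one criterion.

    ``data`` must already be discretised (integer codes).  Returns a
    1-based rank per variable: rank 1 is selected first.  Ties in the greedy
    score break toward the lower column index.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion: {criterion}")
    X = np.asarray(data)
    y = _as_codes(labels)
    n, m = X.shape
    cols = [_as_codes(X[:, j]) for j in range(m)]
    rel = np.array([mutual_information(cols[j], y) for j in range(m)])

    ranks = np.zeros(m, dtype=np.int64)
    if criterion == "mim":
        order = np.lexsort((np.arange(m), -rel))
        ranks[order] = np.arange(1, m + 1)
        return ranks

    selected: list[int] = []
    remaining = list(range(m))
    # running accumulators over the selected set, per candidate
    red_sum = np.zeros(m)        # sum_S I(Xj; Xs)
    cred_sum = np.zeros(m)       # sum_S I(Xj; Xs | Y)
    jmi_sum = np.zeros(m)        # sum_S I(Xj, Xs; Y)
    disr_sum = np.zeros(m)       # sum_S I(Xj, Xs; Y) / H(Xj, Xs, Y)
    icap_sum = np.zeros(m)       # sum_S max(0, I(Xj;Xs) - I(Xj;Xs|Y))
    cmim_min = np.full(m, np.inf)  # min_S I(Xj; Y | Xs)

    def score(j: int, k: int) -> float:
        if criterion == "mrmr":
            return rel[j] - (red_sum[j] / k if k else 0.0)
        if criterion == "cife":
            return rel[j] - (red_sum[j] - cred_sum[j])
        if criterion == "icap":
            return rel[j] - icap_sum[j]
        if criterion == "condred":
            return rel[j] + cred_sum[j]
        if criterion == "jmi":
            return jmi_sum[j] if k else rel[j]
        if criterion == "disr":
            return disr_sum[j] if k else rel[j]
        if criterion == "cmim":
            return min(rel[j], cmim_min[j]) if k else rel[j]
        raise AssertionError(criterion)

    while remaining:
        k = len(selected)
        best = max(remaining, key=lambda j: (score(j, k), -j))
        selected.append(best)
        remaining.remove(best)
        if remaining:
            xs = cols[best]
            for j in remaining:
                xj = cols[j]
                if criterion == "mrmr":
                    red_sum[j] += mutual_information(xj, xs)
                elif criterion in ("cife", "icap"):
                    r = mutual_information(xj, xs)
                    c = conditional_mutual_information(xj, xs, y)
                    red_sum[j] += r
                    cred_sum[j] += c
                    icap_sum[j] += max(0.0, r - c)
                elif criterion == "condred":
                    cred_sum[j] += conditional_mutual_information(xj, xs, y)
                elif criterion in ("jmi", "disr"):
                    pair = _as_codes(_joint_code(xj, xs))
                    i_pair = mutual_information(pair, y)
                    jmi_sum[j] += i_pair
                    h = joint_entropy(pair, y)
                    disr_sum[j] += i_pair / h if h > 0 else 0.0
                elif criterion == "cmim":
                    cmim_min[j] = min(
                        cmim_min[j], conditional_mutual_information(xj, y, xs)
                    )
    ranks[selected] = np.arange(1, m + 1)
    return ranks


# ---------------------------------------------------------------------------
# ensemble ranking
# ---------------------------------------------------------------------------


@dataclass
class RankingTable:
    per_criterion_ranks: dict  # criterion -> 1-based rank per variable
    mean_rank: np.ndarray
    final_order: np.ndarray  # column indices, best first
    variable_names: list[str] | None = None

    def ordered_names(self) -> list[str]:
        if self.variable_names is None:
            return [str(i) for i in self.final_order]
        return [self.variable_names[i] for i in self.final_order]


def ensemble_rank(
    per_criterion_ranks: dict, variable_names: list[str] | None = None
) -> RankingTable:
    """Average the per-criterion ranks and sort ascending.

    Ties in mean rank break by the best (smallest) single-criterion rank,
    then by variable name (or column index when names are absent).
    """
    mats = []
    m = None
    for crit, ranks in per_criterion_ranks.items():
        r = np.asarray(ranks)
        if m is None:
            m = len(r)
        elif len(r) != m:
            raise ValueError("criteria rank vectors cover different variable sets")
        if sorted(r) != list(range(1, m + 1)):
            raise ValueError(f"ranks for {crit} are not a permutation of 1..m")
        mats.append(r)
    R = np.array(mats)  # criteria x variables
    mean_rank = R.mean(axis=0)
    best_single = R.min(axis=0)
    names = variable_names if variable_names is not None else [f"{i:09d}" for i in range(m)]
    order = sorted(range(m), key=lambda j: (mean_rank[j], best_single[j], names[j]))
    return RankingTable(
        per_criterion_ranks={k: np.asarray(v) for k, v in per_criterion_ranks.items()},
        mean_rank=mean_rank,
        final_order=np.array(order),
        variable_names=variable_names,
    )


def rank_ensemble(
    X: np.ndarray,
    labels: np.ndarray,
    variable_names: list[str] | None = None,
    n_bins: int = 10,
    criteria: tuple[str, ...] = CRITERIA,
) -> RankingTable:
    """Convenience: discretise, run every criterion, combine."""
    D = discretize(X, n_bins=n_bins)
    per = {c: rank_by_criterion(D, labels, c) for c in criteria}
    return ensemble_rank(per, variable_names)


# ---------------------------------------------------------------------------
# DeLong test for paired AUCs
# ---------------------------------------------------------------------------


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = psi.mean(axis=1)  # per-positive placement values
    v01 = psi.mean(axis=0)  # per-negative placement values
    return v10, v01, float(psi.mean())


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Paired DeLong test for two correlated AUCs on the same subjects.

    Returns (auc_a, auc_b, two-sided p).  The AUC estimate is the
    tie-corrected Mann-Whitney statistic; its variance comes from the
    placement-value covariance construction.  Degenerate variance (e.g.
    identical score vectors) yields p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired test requires equal-length score vectors")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if n_pos > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n_neg > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n_pos + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n_neg
    if var <= 1e-16:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return auc_a, auc_b, p


# ---------------------------------------------------------------------------
# nested-set evaluation and minimal-set selection
# ---------------------------------------------------------------------------


@dataclass
class VariableSet:
    i: int
    members: list
    auc_mean: float
    auc_std: float
    delong_p: float = float("nan")
    oof_scores: np.ndarray | None = field(default=None, repr=False)


def default_eval_classifier():
    """Lightweight evaluation classifier for the per-set loop."""
    return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))


def nested_set_evaluation(
    ranking: RankingTable,
    X: np.ndarray,
    labels: np.ndarray,
    classifier_builder=None,
    cv: int = 5,
    seed: int = 0,
    sizes: list[int] | None = None,
) -> list[VariableSet]:
    """Cross-validated AUC of each nested top-i variable set.

    Out-of-fold scores are retained for the paired DeLong comparison against
    the best set; ``delong_p`` is filled in against S_max.  ``sizes``
    restricts which i are evaluated (default: every i from 1 to m).
    """
    if classifier_builder is None:
        classifier_builder = default_eval_classifier
    y = np.asarray(labels)
    m = len(ranking.final_order)
    sizes = sorted(set(sizes)) if sizes is not None else list(range(1, m + 1))
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    sets: list[VariableSet] = []
    for i in sizes:
        cols = ranking.final_order[:i]
        oof = np.empty(len(y))
        fold_aucs = []
        for tr, va in folds:
            clf = clone(classifier_builder())
            clf.fit(X[tr][:, cols], y[tr])
            if hasattr(clf, "predict_proba"):
                s = clf.predict_proba(X[va][:, cols])[:, 1]
            else:
                s = clf.decision_function(X[va][:, cols])
            oof[va] = s
            fold_aucs.append(roc_auc(s, y[va]))
        members = (
            [ranking.variable_names[c] for c in cols]
            if ranking.variable_names is not None
            else list(cols)
        )
        sets.append(
            VariableSet(
                i=i,
                members=members,
                auc_mean=float(np.mean(fold_aucs)),
                auc_std=float(np.std(fold_aucs)),
                oof_scores=oof,
            )
        )
    best = max(sets, key=lambda s: s.auc_mean)
    for s in sets:
        _, _, p = delong_test(s.oof_scores, best.oof_scores, y)
        s.delong_p = p
    return sets


def select_minimal_set(sets: list[VariableSet], alpha: float = 0.05) -> VariableSet:
    """Smallest set statistically indistinguishable (DeLong p >= alpha) from
    the best-performing set; the best set itself always qualifies."""
    qualifying = [s for s in sets if s.delong_p >= alpha]
    if not qualifying:  # cannot happen: S_max has p = 1 vs itself
        qualifying = [max(sets, key=lambda s: s.auc_mean)]
    return min(qualifying, key=lambda s: s.i)
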