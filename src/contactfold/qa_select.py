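"""Model selection, ensemble quality assessment and fold classification.

Selection: energy ranking (top-1, top-5, best-top-5 against a native) and
greedy TM-score clustering.  Quality assessment without a native: the
long-range contact-satisfaction score MQA_LR = CON_LR * ln(1 + N_LR)
(N_LR = top-L predicted contacts with separation > 23, CON_LR the fraction
of them satisfied at CB-CB <= 8 A in the assessed model), the mean pairwise
TM-score of the ensemble, and the combined score CS = W_TM * TM + W_LR *
MQA_LR with the calibrated weights W_TM = 7, W_LR = 1.  CS > 3.4 flags a
predicted-correct fold (TM >= 0.5 operating point); alternative operating
points CS > 3.0 (TM >= 0.4) and CS > 6.0 (TM >= 0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactList, D_CON, MID_MAX
from .geometry import tm_score

logger = logging.getLogger("contactfold")

W_TM = 7.0
W_LR = 1.0
CS_THRESHOLDS = {0.4: 3.0, 0.5: 3.4, 0.7: 6.0}  # TM operating point -> CS cut
CS_DEFAULT_THRESHOLD = 3.4
TMCLUST_THRESHOLD = 0.5
SIGNIFICANT_TM_DIFF = 0.05  # TM differences above this count as significant


@dataclass
class SelectionReport:
    top1: int
    top5: list[int]
    best_top5_tm: float | None = None
    cluster_top5: list[int] | None = None


@dataclass
class QAReport:
    n_lr: int
    con_lr: float
    mqa_lr: float
    mean_pairwise_tm: float
    cs: float
    predicted_correct: bool


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def rank_by_energy(ensemble, native=None) -> SelectionReport:
    """Ascending-energy ranking; ties break by decoy index."""
    n = len(ensemble)
    if n == 0:
        raise ValueError("empty ensemble")
    order = sorted(range(n), key=lambda k: (ensemble[k].energy, k))
    if n < 5:
        logger.warning("fewer than 5 decoys; top-5 truncated to %d", n)
    top5 = order[: min(5, n)]
    best_tm = None
    if native is not None:
        best_tm = max(
            tm_score(ensemble[k].conformation, native) for k in top5
        )
    return SelectionReport(top1=order[0], top5=top5, best_top5_tm=best_tm)


def pairwise_tm_matrix(ensemble) -> np.ndarray:
    """Symmetric pairwise TM matrix; entry = max of the two orientations."""
    n = len(ensemble)
    m = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            t1 = tm_score(ensemble[a].conformation, ensemble[b].conformation)
            t2 = tm_score(ensemble[b].conformation, ensemble[a].conformation)
            m[a, b] = m[b, a] = max(t1, t2)
    return m


def tmclust(ensemble, threshold: float = TMCLUST_THRESHOLD, tm_matrix=None):
    """Greedy neighbour clustering on pairwise TM-score.

    Repeatedly takes the unassigned decoy with most unassigned neighbours at
    TM >= threshold as a representative, removes it with its neighbours.
    Returns a list of clusters, largest first; each cluster is
    (representative_index, member_indices).
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("need at least 2 decoys to cluster")
    m = pairwise_tm_matrix(ensemble) if tm_matrix is None else tm_matrix
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best_rep, best_members = None, None
        for k in sorted(unassigned):
            members = [
                j for j in unassigned if j != k and m[k, j] >= threshold
            ]
            if best_members is None or len(members) > len(best_members):
                best_rep, best_members = k, members
        cluster = [best_rep] + best_members
        clusters.append((best_rep, cluster))
        unassigned -= set(cluster)
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return clusters


def mean_pairwise_tm(ensemble, tm_matrix=None) -> float:
    """Mean TM-score over all unordered decoy pairs."""
    n = len(ensemble)
    if n < 2:
        raise ValueError("need at least 2 decoys")
    m = pairwise_tm_matrix(ensemble) if tm_matrix is None else tm_matrix
    iu = np.triu_indices(n, 1)
    return float(m[iu].mean())


# ---------------------------------------------------------------------------
# quality scores
# ---------------------------------------------------------------------------

def mqa_lr(model, contacts: ContactList, d_con: float = D_CON) -> float:
    """Long-range contact-satisfaction score of one model.

    Counts top-L predicted contacts with separation > 23 (N_LR) and the
    fraction of them satisfied at CB-CB <= d_con (CON_LR); the score is
    CON_LR * ln(1 + N_LR), monotone in both ingredients.
    """
    con_lr, n_lr = _con_lr(model, contacts, d_con)
    if n_lr == 0:
        logger.warning("no long-range contacts in the top-L list; MQA_LR = 0")
        return 0.0
    return con_lr * float(np.log1p(n_lr))


def _con_lr(model, contacts: ContactList, d_con: float = D_CON):
    top = contacts.top_l(1.0)
    lr = [r for r in top if r.separation > MID_MAX]
    if not lr:
        return 0.0, 0
    cb = model.cb
    sat = sum(
        1
        for r in lr
        if float(np.linalg.norm(cb[r.i] - cb[r.j])) <= d_con
    )
    return sat / len(lr), len(lr)


def combined_score(
    mean_tm: float, mqa: float, w_tm: float = W_TM, w_lr: float = W_LR
) -> float:
    """CS = W_TM * mean pairwise TM + W_LR * MQA_LR (linear combination)."""
    return w_tm * mean_tm + w_lr * mqa


def classify_fold(cs: float, threshold: float = CS_DEFAULT_THRESHOLD) -> bool:
    """Predicted-correct call: CS above the configured operating point."""
    return cs > threshold


def evaluate_classification(predictions, truths):
    """Precision and recall of predicted-correct calls against labels."""
    predictions = list(predictions)
    truths = list(truths)
    if not predictions or len(predictions) != len(truths):
        raise ValueError("need equal, non-empty prediction/truth lists")
    tp = sum(1 for p, t in zip(predictions, truths) if p and t)
    fp = sum(1 for p, t in zip(predictions, truths) if p and not t)
    fn = sum(1 for p, t in zip(predictions, truths) if not p and t)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def assess_ensemble(
    ensemble,
    contacts: ContactList,
    model_index: int | None = None,
    cs_threshold: float = CS_DEFAULT_THRESHOLD,
    tm_matrix=None,
) -> QAReport:
    """Full QA report for one ensemble.

    The assessed model is the lowest-energy decoy when energies are present
    (NaNs ignored), the ensemble medoid (highest mean TM to the others)
    otherwise; ``model_index`` overrides.
    """
    if tm_matrix is None:
        tm_matrix = pairwise_tm_matrix(ensemble)
    if model_index is None:
        energies = ensemble.energies
        if np.isfinite(energies).any():
            cand = np.where(np.isfinite(energies))[0]
            model_index = int(cand[np.argmin(energies[cand])])
        else:
            model_index = int(np.argmax(tm_matrix.sum(axis=1)))
    model = ensemble[model_index].conformation
    con_lr, n_lr = _con_lr(model, contacts)
    mqa = con_lr * float(np.log1p(n_lr)) if n_lr else 0.0
    mtm = mean_pairwise_tm(ensemble, tm_matrix=tm_matrix)
    cs = combined_score(mtm, mqa)
    return QAReport(
        n_lr=n_lr,
        con_lr=con_lr,
        mqa_lr=mqa,
        mean_pairwise_tm=mtm,
        cs=cs,
        predicted_correct=classify_fold(cs, cs_threshold),
    )


# ---------------------------------------------------------------------------
# fragment-fit outlier rule
# ---------------------------------------------------------------------------

def iqr_outliers(values) -> set:
    """Values >= Q3 + 1.5 * IQR (type-7 linear-interpolation quartiles).

    A constant list has IQR 0 and returns no outliers.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 values for the IQR rule")
    q1, q3 = np.percentile(vals, [25, 75])  # numpy default = type-7
    iqr = q3 - q1
    if iqr == 0 and np.all(vals == vals[0]):
        return set()
    fence = q3 + 1.5 * iqr
    return {float(v) for v in vals if v >= fence}


def qa_table(ensemble, contacts: ContactList, native=None,
             cs_threshold: float = CS_DEFAULT_THRESHOLD) -> str:
    """Per-decoy QA as TSV (the assess command's output)."""
    tm_matrix = pairwise_tm_matrix(ensemble)
    report = assess_ensemble(ensemble, contacts, tm_matrix=tm_matrix,
                             cs_threshold=cs_threshold)
    order = sorted(
        range(len(ensemble)), key=lambda k: (ensemble[k].energy, k)
    )
    rank_of = {k: r + 1 for r, k in enumerate(order)}
    cols = [
        "decoy_id", "energy", "rank", "N_LR", "CON_LR", "mqa_lr",
        "mean_pairwise_tm", "cs", "predicted_correct",
    ]
    if native is not None:
        cols.append("tm_to_native")
    lines = ["\t".join(cols)]
    for k, decoy in enumerate(ensemble):
        con_lr, n_lr = _con_lr(decoy.conformation, contacts)
        mqa = con_lr * float(np.log1p(n_lr)) if n_lr else 0.0
        row = [
            str(k),
            f"{decoy.energy:.4f}",
            str(rank_of[k]),
            str(n_lr),
            f"{con_lr:.4f}",
            f"{mqa:.4f}",
            f"{report.mean_pairwise_tm:.4f}",
            f"{combined_score(report.mean_pairwise_tm, mqa):.4f}",
            str(int(classify_fold(
                combined_score(report.mean_pairwise_tm, mqa), cs_threshold
            ))),
        ]
        if native is not None:
            row.append(f"{tm_score(decoy.conformation, native):.4f}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
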