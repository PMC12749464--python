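"""Ward clustering of sequence dissimilarities and cluster-quality indices.

The linkage operates directly on the precomputed OM dissimilarity matrix via
the Lance–Williams recurrence on squared dissimilarities with heights
reported on the distance scale (the "ward.D2" convention); the "ward.D"
convention (recurrence on the dissimilarities as given) is available through
``variant="ward_d"``.

Quality indices use Studer-style pseudo-variances for dissimilarity data:
with SS(A) = (1/(2|A|)) * sum_{i,j in A} d_ij^2, T = SS(all),
W = sum_c SS(c) and B = T - W,

    R^2 = 1 - W/T            CH = (B/(k-1)) / (W/(n-k))

Hubert's Gamma is the Goodman–Kruskal-style concordance between
within-cluster and between-cluster pair distances, and HC is the
Hubert–Levin C index (0 = the within-cluster pairs are the globally
smallest distances possible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .sequences import AGE_MIN, STATE_INDEX, SequenceSet, state_distribution
from .om import DissimilarityMatrix


@dataclass
class LinkageTree:
    Z: np.ndarray          # scipy linkage matrix, heights on the distance scale
    n: int
    variant: str = "ward_d2"


@dataclass
class QualityReport:
    asw: float
    r2: float
    ch: float
    hg: float
    hc: float
    k: int
    n: int

    def to_dict(self) -> dict:
        return {"asw": self.asw, "r2": self.r2, "ch": self.ch,
                "hg": self.hg, "hc": self.hc, "k": self.k, "n": self.n}


def _as_square(D) -> np.ndarray:
    d = D.d if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    return d


def ward_linkage(D, variant: str = "ward_d2") -> LinkageTree:
    """Agglomerative Ward merges on a precomputed dissimilarity matrix."""
    d = _as_square(D)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    cond = squareform(d, checks=False)
    if variant == "ward_d2":
        Z = hierarchy.linkage(cond, method="ward")
    elif variant == "ward_d":
        # recurrence applied to the raw dissimilarities: run the squared-input
        # algorithm on sqrt(d) and report the squared heights
        Z = hierarchy.linkage(np.sqrt(cond), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unknown ward variant {variant!r}")
    return LinkageTree(Z=Z, n=n, variant=variant)


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Labels 1..k, renumbered by descending cluster size then smallest member."""
    if not 1 <= k <= tree.n:
        raise ValueError(f"k={k} out of range 1..{tree.n}")
    flat = hierarchy.cut_tree(tree.Z, n_clusters=k).ravel()
    return _renumber(flat)


def _renumber(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    keys = []
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        keys.append((-len(members), members.min(), c))
    keys.sort()
    remap = {c: i + 1 for i, (_, _, c) in enumerate(keys)}
    return np.array([remap[c] for c in labels], dtype=int)


def silhouette(D, labels) -> tuple[np.ndarray, float]:
    """Per-observation silhouette widths and their unweighted mean (ASW).

    s(i) = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance to the own
    cluster (excluding self) and b_i the smallest mean distance to another
    cluster; members of singleton clusters score 0.
    """
    d = _as_square(D)
    labels = np.asarray(labels)
    n = d.shape[0]
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    # mean distance from every observation to every cluster
    sums = np.stack([d[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    own = np.searchsorted(uniq, labels)
    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        a = sums[i, c] / (sizes[c] - 1)
        other = [sums[i, j] / sizes[j] for j in range(len(uniq)) if j != c]
        b = min(other)
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s, float(s.mean())


def quality_indices(D, labels) -> QualityReport:
    """ASW, pseudo-R^2, Calinski–Harabasz, Hubert's Gamma and Hubert's C."""
    d = _as_square(D)
    labels = np.asarray(labels)
    n = d.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2 or n <= k:
        raise ValueError("indices require 2 <= k < n")

    d2 = d ** 2
    T = d2.sum() / (2 * n)
    if T == 0:
        raise ValueError("degenerate data: all dissimilarities are zero")
    W = 0.0
    for c in uniq:
        m = labels == c
        W += d2[np.ix_(m, m)].sum() / (2 * m.sum())
    B = T - W
    r2 = 1.0 - W / T
    ch = (B / (k - 1)) / (W / (n - k)) if W > 0 else np.inf

    iu, ju = np.triu_indices(n, 1)
    within_pair = labels[iu] == labels[ju]
    dw = d[iu, ju][within_pair]
    db = d[iu, ju][~within_pair]
    hg = _hubert_gamma(dw, db)
    hc = _hubert_c(dw, d[iu, ju])

    _, asw = silhouette(d, labels)
    return QualityReport(asw=asw, r2=float(r2), ch=float(ch), hg=hg, hc=hc, k=k, n=n)


def _hubert_gamma(dw: np.ndarray, db: np.ndarray) -> float:
    """(C - D)/(C + D) over all (within-pair, between-pair) comparisons.

    C counts comparisons with d_within < d_between, D the reverse; ties are
    dropped.  Counted exactly by sorting the between-pair distances.
    """
    if dw.size == 0 or db.size == 0:
        return float("nan")
    db_sorted = np.sort(db)
    lt = np.searchsorted(db_sorted, dw, side="left")    # between < within
    le = np.searchsorted(db_sorted, dw, side="right")   # between <= within
    discordant = lt.sum()
    concordant = (db.size - le).sum()
    tot = concordant + discordant
    return float("nan") if tot == 0 else float((concordant - discordant) / tot)


def _hubert_c(dw: np.ndarray, all_d: np.ndarray) -> float:
    """Hubert–Levin C: (S - S_min)/(S_max - S_min) for within-pair sum S."""
    m = dw.size
    if m == 0:
        return 0.0
    srt = np.sort(all_d)
    s = dw.sum()
    s_min = srt[:m].sum()
    s_max = srt[-m:].sum()
    return 0.0 if s_max == s_min else float((s - s_min) / (s_max - s_min))


def quality_scan(D, tree: LinkageTree, ks) -> pd.DataFrame:
    """Index-vs-k table over candidate cluster counts (no automatic choice)."""
    rows = []
    for k in ks:
        rep = quality_indices(D, cut_tree(tree, k))
        rows.append(rep.to_dict())
    return pd.DataFrame(rows).set_index("k")


# ---------------------------------------------------------------------------
# cluster summaries

def age_at_first_marriage(states: np.ndarray) -> np.ndarray:
    """First age with state M per row; NaN for rows never in M."""
    m = states == STATE_INDEX["M"]
    first = m.argmax(axis=1).astype(float) + AGE_MIN
    first[~m.any(axis=1)] = np.nan
    return first


def summarize_clusters(seqs: SequenceSet, labels) -> dict[int, dict]:
    """Per-cluster size, sample share, state-distribution table, and the mean
    and median age at first marriage over ever-married members."""
    labels = np.asarray(labels)
    n = len(seqs)
    if labels.shape[0] != n:
        raise ValueError("labels not aligned to sequences")
    afm = age_at_first_marriage(seqs.states)
    out: dict[int, dict] = {}
    for c in np.unique(labels):
        m = labels == c
        sub = SequenceSet(ids=[i for i, keep in zip(seqs.ids, m) if keep],
                          states=seqs.states[m])
        ages = afm[m]
        ever = ~np.isnan(ages)
        out[int(c)] = {
            "size": int(m.sum()),
            "share": float(m.sum() / n),
            "state_distribution": state_distribution(sub),
            "n_never_married": int((~ever).sum()),
            "mean_age_first_marriage": float(np.mean(ages[ever])) if ever.any() else None,
            "median_age_first_marriage": float(np.median(ages[ever])) if ever.any() else None,
        }
    return out


def summary_table(summaries: dict[int, dict]) -> pd.DataFrame:
    rows = []
    for c, s in sorted(summaries.items()):
        rows.append({
            "cluster": c, "size": s["size"], "share": s["share"],
            "n_never_married": s["n_never_married"],
            "mean_age_first_marriage": s["mean_age_first_marriage"],
            "median_age_first_marriage": s["median_age_first_marriage"],
        })
    return pd.DataFrame(rows).set_index("cluster")
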