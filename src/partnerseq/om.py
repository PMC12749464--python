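"""Optimal-matching (OM) dissimilarities between state sequences.

Substitution costs follow the transition-rate (TRATE) scheme: for states
a != b,

    sub(a, b) = 2 - p(b | a) - p(a | b),

where p(b | a) is the empirical probability of being in state b at age t+1
given state a at age t, pooled over all persons and ages.  Frequent
transitions are cheap to substitute, never-observed ones cost the scheme
maximum of 2.  Insertions and deletions cost ``indel`` (1 by default), and
the OM distance is the minimum total edit cost computed by the standard
dynamic program.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import STATES, SequenceSet, states_arr

try:  # optional JIT acceleration for all-pairs matrices
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


@dataclass
class TransitionRateMatrix:
    p: np.ndarray             # row-normalized probabilities
    counts: np.ndarray        # raw transition counts
    zero_rows: np.ndarray     # states never observed as a source
    alphabet: str = STATES


@dataclass
class CostScheme:
    sub: np.ndarray
    indel: float = 1.0
    alphabet: str = STATES

    def __post_init__(self) -> None:
        self.sub = np.asarray(self.sub, dtype=float)
        k = len(self.alphabet)
        if self.sub.shape != (k, k):
            raise ValueError("substitution matrix does not match alphabet size")
        if not np.allclose(self.sub, self.sub.T):
            raise ValueError("substitution matrix must be symmetric")
        if np.diag(self.sub).any():
            raise ValueError("substitution matrix must have a zero diagonal")


@dataclass
class DissimilarityMatrix:
    d: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.d, checks=False)


def estimate_transition_rates(
    seqs: SequenceSet | np.ndarray, n_states: int | None = None, alphabet: str = STATES
) -> TransitionRateMatrix:
    """Pooled age-to-age transition counts and row-normalized rates."""
    states = states_arr(seqs)
    if states.shape[0] == 0:
        raise ValueError("empty sequence set")
    k = n_states if n_states is not None else len(alphabet)
    src = states[:, :-1].ravel()
    dst = states[:, 1:].ravel()
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (src, dst), 1)
    row_tot = counts.sum(axis=1)
    zero_rows = row_tot == 0
    p = np.zeros((k, k), dtype=float)
    nz = ~zero_rows
    p[nz] = counts[nz] / row_tot[nz, None]
    return TransitionRateMatrix(p=p, counts=counts, zero_rows=zero_rows,
                                alphabet=alphabet[:k])


def trate_costs(rates: TransitionRateMatrix, indel: float = 1.0) -> CostScheme:
    """Transition-rate substitution costs: sub(a,b) = 2 - p(b|a) - p(a|b).

    Any pair involving a never-observed source state falls back to the scheme
    maximum of 2 (no evidence the transition is common).
    """
    p = rates.p
    sub = 2.0 - p - p.T
    if rates.zero_rows.any():
        z = rates.zero_rows
        sub[z, :] = 2.0
        sub[:, z] = 2.0
    np.fill_diagonal(sub, 0.0)
    return CostScheme(sub=sub, indel=indel, alphabet=rates.alphabet)


def constant_costs(value: float = 2.0, indel: float = 1.0, alphabet: str = STATES) -> CostScheme:
    sub = np.full((len(alphabet), len(alphabet)), float(value))
    np.fill_diagonal(sub, 0.0)
    return CostScheme(sub=sub, indel=indel, alphabet=alphabet)


def _om_dist_py(a: np.ndarray, b: np.ndarray, sub: np.ndarray, indel: float) -> float:
    n, m = len(a), len(b)
    prev = np.arange(m + 1, dtype=np.float64) * indel
    cur = np.empty(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        cur[0] = i * indel
        ai = a[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + sub[ai, b[j - 1]],
                prev[j] + indel,
                cur[j - 1] + indel,
            )
        prev, cur = cur, prev
    return float(prev[m])


if _njit is not None:
    _om_dist_jit = _njit(cache=False)(_om_dist_py)

    @_njit(cache=False)
    def _pairwise_jit(U: np.ndarray, sub: np.ndarray, indel: float) -> np.ndarray:
        m = U.shape[0]
        out = np.zeros((m, m), dtype=np.float64)
        for i in range(m):
            for j in range(i + 1, m):
                d = _om_dist_jit(U[i], U[j], sub, indel)
                out[i, j] = d
                out[j, i] = d
        return out
else:  # pragma: no cover
    _om_dist_jit = None
    _pairwise_jit = None


def om_dist(s1, s2, scheme: CostScheme) -> float:
    """Minimum edit cost transforming s1 into s2 under the cost scheme."""
    a = _as_codes(s1, scheme)
    b = _as_codes(s2, scheme)
    return _om_dist_py(a, b, scheme.sub, scheme.indel)


def _as_codes(s, scheme: CostScheme) -> np.ndarray:
    if isinstance(s, str):
        idx = {c: i for i, c in enumerate(scheme.alphabet)}
        try:
            return np.array([idx[c] for c in s], dtype=np.int8)
        except KeyError as e:
            raise ValueError(f"symbol {e.args[0]!r} not in alphabet {scheme.alphabet!r}")
    arr = np.asarray(s, dtype=np.int8)
    if arr.size and (arr.min() < 0 or arr.max() >= len(scheme.alphabet)):
        raise ValueError("sequence codes outside the scheme alphabet")
    return arr


def pairwise_matrix(
    seqs: SequenceSet | np.ndarray, scheme: CostScheme, ids: list[str] | None = None
) -> DissimilarityMatrix:
    """All-pairs OM distances; identical sequences are deduplicated first."""
    states = states_arr(seqs)
    if ids is None:
        ids = seqs.ids if isinstance(seqs, SequenceSet) else [str(i) for i in range(len(states))]
    if states.shape[0] == 0:
        raise ValueError("empty sequence set")
    uniq, inverse = np.unique(states, axis=0, return_inverse=True)
    uniq = np.ascontiguousarray(uniq, dtype=np.int8)
    sub = np.ascontiguousarray(scheme.sub, dtype=np.float64)
    if _pairwise_jit is not None:
        du = _pairwise_jit(uniq, sub, float(scheme.indel))
    else:
        m = uniq.shape[0]
        du = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                du[i, j] = du[j, i] = _om_dist_py(uniq[i], uniq[j], sub, scheme.indel)
    d = du[np.ix_(inverse, inverse)]
    return DissimilarityMatrix(d=d, ids=list(ids))


# ---------------------------------------------------------------------------
# file interfaces

def write_costs(scheme: CostScheme, csv_path, sidecar_path) -> None:
    labels = list(scheme.alphabet)
    pd.DataFrame(scheme.sub, index=labels, columns=labels).to_csv(csv_path)
    with open(sidecar_path, "w") as fh:
        json.dump({"indel": scheme.indel, "alphabet": scheme.alphabet}, fh)


def read_costs(csv_path, sidecar_path) -> CostScheme:
    df = pd.read_csv(csv_path, index_col=0)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return CostScheme(sub=df.to_numpy(), indel=float(meta["indel"]),
                      alphabet=str(meta["alphabet"]))


def write_distance_matrix(dm: DissimilarityMatrix, path) -> None:
    pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids).to_csv(path)


def read_distance_matrix(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(d=df.to_numpy(float), ids=[str(c) for c in df.columns])


def write_distance_binary(dm: DissimilarityMatrix, bin_path, ids_path) -> None:
    """Row-major float64 sidecar for large n (plus a plain-text id index)."""
    np.ascontiguousarray(dm.d, dtype="<f8").tofile(bin_path)
    with open(ids_path, "w") as fh:
        fh.write("\n".join(dm.ids) + "\n")


def read_distance_binary(bin_path, ids_path) -> DissimilarityMatrix:
    with open(ids_path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    n = len(ids)
    d = np.fromfile(bin_path, dtype="<f8").reshape(n, n)
    return DissimilarityMatrix(d=d, ids=ids)
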