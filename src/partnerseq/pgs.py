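"""Polygenic scores from SNP weights and effect-allele dosages.

A polygenic score aggregates GWAS effect sizes over a SNP panel,

    PGS_i = sum_j W_j * G_ij,

with G_ij the count (0, 1, 2) of the effect allele carried by person i at
SNP j.  Negative weights are removed beforehand by flipping the allele
coding (W_j <- -W_j, G_ij <- 2 - G_ij), which shifts every raw score by a
constant and therefore leaves the standardized score unchanged.  Scores are
standardized to mean 0 / SD 1 within the scored sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

WEIGHT_COLUMNS = ["snp_id", "effect_allele", "other_allele", "weight"]


def _check_weights(weights: pd.DataFrame) -> None:
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table lacks columns {missing}")
    if weights["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in weight table")


def _check_alignment(weights: pd.DataFrame, genotypes: pd.DataFrame) -> None:
    panel = list(weights["snp_id"])
    missing = [s for s in panel if s not in genotypes.columns]
    if missing:
        raise ValueError(f"genotype matrix lacks SNPs: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))


def flip_negative_weights(
    weights: pd.DataFrame, genotypes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Make all weights nonnegative by swapping allele coding where W_j < 0."""
    _check_weights(weights)
    _check_alignment(weights, genotypes)
    weights = weights.copy()
    genotypes = genotypes.copy()
    neg = weights["weight"] < 0
    flip_ids = weights.loc[neg, "snp_id"].tolist()
    weights.loc[neg, "weight"] = -weights.loc[neg, "weight"]
    ea = weights.loc[neg, "effect_allele"].copy()
    weights.loc[neg, "effect_allele"] = weights.loc[neg, "other_allele"].to_numpy()
    weights.loc[neg, "other_allele"] = ea.to_numpy()
    for snp in flip_ids:
        genotypes[snp] = 2 - genotypes[snp]
    return weights, genotypes


def compute_pgs(weights: pd.DataFrame, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Raw and standardized scores; columns person_id, raw, z."""
    _check_weights(weights)
    _check_alignment(weights, genotypes)
    G = genotypes[list(weights["snp_id"])].to_numpy(float)
    if np.isin(G, (0.0, 1.0, 2.0)).all():
        pass
    elif ((G >= 0) & (G <= 2)).all():
        warnings.warn("fractional dosages supplied; hard calls {0,1,2} expected")
    else:
        raise ValueError("dosages outside [0, 2]")
    raw = G @ weights["weight"].to_numpy(float)
    sd = raw.std(ddof=0)
    z = np.zeros_like(raw) if sd == 0 else (raw - raw.mean()) / sd
    return pd.DataFrame({
        "person_id": genotypes.index.astype(str),
        "raw": raw,
        "z": z,
    }).reset_index(drop=True)


def read_weights(path) -> pd.DataFrame:
    w = pd.read_csv(path, dtype={"snp_id": str})
    _check_weights(w)
    return w


def read_genotypes(path) -> pd.DataFrame:
    """Persons x SNPs CSV; first column person_id becomes the index."""
    g = pd.read_csv(path, dtype={"person_id": str})
    return g.set_index("person_id")


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)
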