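"""Synthetic cohort generator with full ground truth.

The generator emulates the statistical structure the pipeline assumes:

* six archetypal partnership trajectories (never married; married in the 30s
  then widowed; married then divorced; married in the 20s and continuously
  married; married by 20 and continuously married; married, divorced and
  remarried), with noisy truncated-normal event timing inside ages 15–50;
* class membership drawn from a multinomial logit on education, gender,
  four polygenic scores and birth cohort, with baseline log-odds set so that
  zero coefficients reproduce the configured class shares;
* an SNP panel (independent binomial(2, f_j) genotypes with signed GWAS-style
  weights) from which the educational-attainment PGS is computed through the
  scoring pipeline; the remaining three PGSs are drawn standard normal;
* self-rated health (5 categories) from an ordered logit and a CESD-style
  symptom count from an NB2 model, both with known coefficients.

Every latent quantity (class, state matrix, linear predictors) is retained
so that any estimand can be computed exactly, and ``truth_report`` scores
parameter recovery of fits run on the simulated data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pgs as pgs_mod
from .models import (
    CLUSTER_ORDER,
    REFERENCE_CLUSTER,
    MultinomialLogit,
    NegativeBinomial,
    OrderedLogit,
)
from .sequences import AGE_MIN, MISSING, SEQ_LEN, STATE_INDEX, SequenceSet

NEVER = "never_married"
W30 = "married_30s_widowed"
DIV = "married_divorced"
C20 = "married_20s_continuous"
BY20 = "married_by20_continuous"
REM = "married_remarried"

#: per-class event-timing laws: truncated normal (mean, sd, lo, hi) on ages
DEFAULT_TIMING: dict[str, dict] = {
    NEVER: {},
    W30: {"marriage": (32.0, 2.5, 30, 39), "widowhood": (45.0, 3.0, None, 50)},
    DIV: {"marriage": (24.0, 3.0, 18, 33), "divorce": (35.0, 5.0, None, 49)},
    C20: {"marriage": (24.5, 2.2, 21, 29)},
    BY20: {"marriage": (18.3, 1.5, 15, 20)},
    REM: {"marriage": (22.0, 3.0, 16, 30), "divorce": (30.0, 4.0, None, 42),
          "remarriage_gap": (5.0, 2.0, 1, 8)},
}

MEMBERSHIP_COLUMNS = ["educ_z", "female", "pgs_ea", "pgs_wb", "pgs_dep",
                      "pgs_bmi", "cohort[c1948_1959]", "cohort[post1960]"]

#: membership-model coefficients (reference class: married in 20s, continuous)
DEFAULT_GAMMA: dict[str, dict[str, float]] = {
    NEVER: {"educ_z": 0.0, "female": 0.11, "pgs_ea": 0.05, "pgs_wb": -0.25,
            "pgs_dep": -0.05, "pgs_bmi": -0.03,
            "cohort[c1948_1959]": -0.36, "cohort[post1960]": -0.50},
    W30: {"educ_z": -0.11, "female": -0.25, "pgs_ea": 0.13, "pgs_wb": -0.04,
          "pgs_dep": 0.00, "pgs_bmi": -0.15,
          "cohort[c1948_1959]": -0.42, "cohort[post1960]": -0.40},
    DIV: {"educ_z": -0.22, "female": 0.00, "pgs_ea": -0.10, "pgs_wb": 0.09,
          "pgs_dep": 0.12, "pgs_bmi": -0.03,
          "cohort[c1948_1959]": 0.38, "cohort[post1960]": -0.52},
    BY20: {"educ_z": -0.51, "female": 0.91, "pgs_ea": -0.20, "pgs_wb": 0.04,
           "pgs_dep": 0.07, "pgs_bmi": 0.00,
           "cohort[c1948_1959]": -0.05, "cohort[post1960]": -0.68},
    REM: {"educ_z": -0.36, "female": 0.48, "pgs_ea": -0.25, "pgs_wb": 0.03,
          "pgs_dep": -0.08, "pgs_bmi": 0.02,
          "cohort[c1948_1959]": 0.22, "cohort[post1960]": -0.22},
}

DEFAULT_SRH_BETA: dict[str, float] = {
    f"cluster[{NEVER}]": -0.30, f"cluster[{W30}]": 0.15,
    f"cluster[{DIV}]": -0.30, f"cluster[{BY20}]": 0.00,
    f"cluster[{REM}]": 0.10,
    "pgs_ea": 0.01, "pgs_wb": 0.10, "pgs_dep": -0.07, "pgs_bmi": -0.21,
    "educ_years": 0.15, "mother_educ": 0.05, "female": 0.09,
    "agediff_srh": -0.054, "ses[average]": 0.20,
}
DEFAULT_SRH_CUTPOINTS = (-0.80, 0.60, 2.10, 3.80)

DEFAULT_CESD_BETA: dict[str, float] = {
    "const": 1.05,
    f"cluster[{NEVER}]": 0.24, f"cluster[{W30}]": 0.07,
    f"cluster[{DIV}]": 0.14, f"cluster[{BY20}]": -0.03,
    f"cluster[{REM}]": 0.04,
    "pgs_ea": 0.02, "pgs_wb": -0.07, "pgs_dep": 0.10, "pgs_bmi": 0.03,
    "educ_years": -0.08, "mother_educ": -0.02, "female": 0.33,
    "agediff_cesd": 0.010, "ses[average]": -0.20,
}
DEFAULT_CESD_LNALPHA = 0.45


@dataclass
class GeneratorConfig:
    n: int = 1000
    seed: int = 0
    class_names: tuple[str, ...] = tuple(CLUSTER_ORDER)
    class_shares: tuple[float, ...] = (0.057, 0.055, 0.037, 0.360, 0.442, 0.048)
    timing: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TIMING.items()})
    gamma: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GAMMA.items()})
    srh_beta: dict = field(default_factory=lambda: dict(DEFAULT_SRH_BETA))
    srh_cutpoints: tuple[float, ...] = DEFAULT_SRH_CUTPOINTS
    cesd_beta: dict = field(default_factory=lambda: dict(DEFAULT_CESD_BETA))
    cesd_lnalpha: float = DEFAULT_CESD_LNALPHA
    missing_rate: float = 0.0
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.1, 0.9)
    weight_scale: float = 0.05
    female_share: float = 0.6

    def __post_init__(self) -> None:
        shares = np.asarray(self.class_shares, dtype=float)
        if shares.min() <= 0:
            raise ValueError("class shares must be positive")
        self.class_shares = tuple(shares / shares.sum())
        for cls, law in self.timing.items():
            if "divorce" in law or "widowhood" in law:
                if "marriage" not in law:
                    raise ValueError(f"{cls}: dissolution without a marriage law")


@dataclass
class SimulatedCohort:
    config: GeneratorConfig
    persons: pd.DataFrame
    marriages: pd.DataFrame
    snp_weights: pd.DataFrame
    genotypes: pd.DataFrame
    data: pd.DataFrame            # analytic table: covariates + outcomes
    raw_sequences: np.ndarray     # int8[n, 36], MISSING where a gap was punched
    truth: dict


def _truncnorm_int(rng, mean, sd, lo, hi, size=None) -> np.ndarray:
    """Rounded truncated-normal ages via rejection (bounds inclusive)."""
    single = size is None
    size = 1 if single else size
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, need.sum())
        out[need] = draw
        need = (out < lo) | (out > hi)
    res = np.round(out).astype(int)
    res = np.clip(res, int(np.ceil(lo)), int(np.floor(hi)))
    return int(res[0]) if single else res


def _draw_events(rng, cls: str, law: dict) -> list[tuple[str, int]]:
    """Ordered (event, age) list for one person of the given class."""
    if not law:
        return []
    m_mean, m_sd, m_lo, m_hi = law["marriage"]
    m = _truncnorm_int(rng, m_mean, m_sd, m_lo, m_hi)
    events = [("marriage", m)]
    for kind in ("divorce", "widowhood"):
        if kind in law:
            mean, sd, lo, hi = law[kind]
            lo = m + 2 if lo is None else max(lo, m + 1)
            hi = max(hi, lo)
            d = _truncnorm_int(rng, mean, sd, lo, hi)
            events.append((kind, d))
            if "remarriage_gap" in law:
                g_mean, g_sd, g_lo, g_hi = law["remarriage_gap"]
                gap = _truncnorm_int(rng, g_mean, g_sd, g_lo, g_hi)
                events.append(("remarriage", min(d + gap, 49)))
            break
    return events


def _states_from_events(events: list[tuple[str, int]]) -> np.ndarray:
    """Direct latent-state construction (independent of assign_states)."""
    s = np.full(SEQ_LEN, STATE_INDEX["N"], dtype=np.int8)
    for kind, age in events:
        p = age - AGE_MIN
        if kind == "marriage":
            s[p:] = STATE_INDEX["M"]
        elif kind == "divorce":
            s[p:] = STATE_INDEX["D"]
        elif kind == "widowhood":
            s[p:] = STATE_INDEX["W"]
        elif kind == "remarriage":
            s[p:] = STATE_INDEX["R"]
    return s


def _records_from_events(pid, birth, events) -> list[dict]:
    recs = []
    start = None
    order = 0
    for kind, age in events:
        year = birth + age
        if kind in ("marriage", "remarriage"):
            order += 1
            recs.append({"person_id": pid, "order": order, "start_year": year,
                         "end_year": np.nan, "end_reason": "ongoing"})
        else:
            recs[-1]["end_year"] = year
            recs[-1]["end_reason"] = "divorce" if kind == "divorce" else "widowhood"
    return recs


def simulate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    cfg = config if config is not None else GeneratorConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    ids = [f"p{i:06d}" for i in range(n)]

    # --- covariates -------------------------------------------------------
    female = (rng.random(n) < cfg.female_share).astype(int)
    birth_year = _truncnorm_int(rng, 1944.0, 10.0, 1914, 1968, size=n)
    cohort = np.where(birth_year < 1948, "pre1948",
                      np.where(birth_year < 1960, "c1948_1959", "post1960"))
    educ = np.clip(np.round(rng.normal(13.8, 2.3, n)), 8, 20)
    mother_educ = np.clip(np.round(rng.normal(11.2, 2.9, n)), 0, 17)
    father_educ = np.clip(np.round(rng.normal(10.9, 3.5, n)), 0, 17)
    ses = rng.choice(["poor", "average", "well_off", "varied_missing"],
                     size=n, p=[0.212, 0.689, 0.086, 0.013])
    pcs = rng.normal(0.0, 1.0, (n, 10))
    agediff_srh = np.clip(np.round(np.abs(rng.normal(4.9, 5.4, n))), 0, 18)
    agediff_cesd = np.clip(np.round(np.abs(rng.normal(5.7, 5.6, n))), 0, 18)

    # --- genotypes and polygenic scores -----------------------------------
    freqs = rng.uniform(*cfg.maf_range, cfg.n_snps)
    weights_signed = rng.normal(0.0, cfg.weight_scale, cfg.n_snps)
    snp_ids = [f"rs{i:05d}" for i in range(cfg.n_snps)]
    alleles = np.array(["A", "C", "G", "T"])
    ea = rng.choice(alleles, cfg.n_snps)
    oa = np.array([rng.choice([a for a in alleles if a != e]) for e in ea])
    G = rng.binomial(2, freqs, size=(n, cfg.n_snps))
    snp_weights = pd.DataFrame({"snp_id": snp_ids, "effect_allele": ea,
                                "other_allele": oa, "weight": weights_signed})
    genotypes = pd.DataFrame(G, index=pd.Index(ids, name="person_id"),
                             columns=snp_ids)
    w_flip, g_flip = pgs_mod.flip_negative_weights(snp_weights, genotypes)
    scores = pgs_mod.compute_pgs(w_flip, g_flip)
    pgs_ea = scores["z"].to_numpy()
    pgs_wb = rng.normal(0.0, 1.0, n)
    pgs_dep = rng.normal(0.0, 1.0, n)
    pgs_bmi = rng.normal(0.0, 1.0, n)

    # --- class membership (multinomial logit) -----------------------------
    educ_z = (educ - educ.mean()) / educ.std(ddof=0)
    xm = pd.DataFrame({
        "educ_z": educ_z, "female": female.astype(float),
        "pgs_ea": pgs_ea, "pgs_wb": pgs_wb, "pgs_dep": pgs_dep,
        "pgs_bmi": pgs_bmi,
        "cohort[c1948_1959]": (cohort == "c1948_1959").astype(float),
        "cohort[post1960]": (cohort == "post1960").astype(float),
    })
    logits = np.tile(np.log(np.asarray(cfg.class_shares)), (n, 1))
    for ci, cls in enumerate(cfg.class_names):
        for col, g in cfg.gamma.get(cls, {}).items():
            logits[:, ci] += g * xm[col].to_numpy()
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng.random(n)
    class_idx = (u[:, None] > cum).sum(axis=1)
    latent_class = np.asarray(cfg.class_names)[class_idx]

    # --- event histories and latent states --------------------------------
    all_events = [_draw_events(rng, cls, cfg.timing[cls]) for cls in latent_class]
    latent_states = np.vstack([_states_from_events(ev) for ev in all_events])
    marriage_rows: list[dict] = []
    for pid, by, ev in zip(ids, birth_year, all_events):
        marriage_rows.extend(_records_from_events(pid, int(by), ev))
    marriages = pd.DataFrame(
        marriage_rows,
        columns=["person_id", "order", "start_year", "end_year", "end_reason"],
    )

    raw_sequences = latent_states.copy()
    if cfg.missing_rate > 0:
        holes = rng.random((n, SEQ_LEN)) < cfg.missing_rate
        holes[:, 0] = False  # position at age 15 stays observed
        raw_sequences[holes] = MISSING

    # --- outcomes ----------------------------------------------------------
    base = pd.DataFrame({
        "person_id": ids, "female": female.astype(float),
        "birth_year": birth_year.astype(float), "cohort": cohort,
        "educ_years": educ, "mother_educ": mother_educ,
        "father_educ": father_educ, "childhood_ses": ses,
        "pgs_ea": pgs_ea, "pgs_wb": pgs_wb, "pgs_dep": pgs_dep,
        "pgs_bmi": pgs_bmi,
        "agediff_srh": agediff_srh, "agediff_cesd": agediff_cesd,
        "cluster": latent_class,
    })
    for j in range(10):
        base[f"pc{j + 1}"] = pcs[:, j]
    for cls in cfg.class_names:
        if cls != REFERENCE_CLUSTER:
            base[f"cluster[{cls}]"] = (latent_class == cls).astype(float)
    base["ses[average]"] = (ses == "average").astype(float)
    base["const"] = 1.0

    eta_srh = np.zeros(n)
    for col, b in cfg.srh_beta.items():
        eta_srh += b * base[col].to_numpy(float)
    kappa = np.asarray(cfg.srh_cutpoints, dtype=float)
    from scipy.special import expit

    cdf = expit(kappa[None, :] - eta_srh[:, None])
    u = rng.random(n)
    srh = (u[:, None] > cdf).sum(axis=1) + 1  # 1..5

    eta_cesd = np.zeros(n)
    for col, b in cfg.cesd_beta.items():
        eta_cesd += b * base[col].to_numpy(float)
    mu = np.exp(eta_cesd)
    alpha = float(np.exp(cfg.cesd_lnalpha))
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    cesd = rng.poisson(lam)

    data = base.drop(columns=[c for c in base.columns
                              if c.startswith("cluster[") or c == "ses[average]"
                              or c == "const"])
    data["srh"] = srh
    data["cesd"] = cesd

    persons = pd.DataFrame({
        "person_id": ids, "birth_year": birth_year,
        "gender": np.where(female == 1, "female", "male"),
    })
    truth = {
        "latent_class": latent_class,
        "class_probs": probs,
        "latent_states": latent_states,
        "eta_srh": eta_srh,
        "mu_cesd": mu,
        "alpha_cesd": alpha,
        "educ_mean": float(educ.mean()),
        "educ_sd": float(educ.std(ddof=0)),
        "allele_freqs": freqs,
    }
    return SimulatedCohort(config=cfg, persons=persons, marriages=marriages,
                           snp_weights=snp_weights, genotypes=genotypes,
                           data=data, raw_sequences=raw_sequences, truth=truth)


def latent_sequence_set(cohort: SimulatedCohort) -> SequenceSet:
    return SequenceSet(ids=list(cohort.persons["person_id"]),
                       states=cohort.truth["latent_states"].copy())


# ---------------------------------------------------------------------------
# recovery reporting


def _membership_design(cohort: SimulatedCohort) -> tuple[np.ndarray, pd.DataFrame]:
    d = cohort.data
    educ_z = (d["educ_years"] - cohort.truth["educ_mean"]) / cohort.truth["educ_sd"]
    X = pd.DataFrame({
        "educ_z": educ_z, "female": d["female"].astype(float),
        "pgs_ea": d["pgs_ea"], "pgs_wb": d["pgs_wb"],
        "pgs_dep": d["pgs_dep"], "pgs_bmi": d["pgs_bmi"],
        "cohort[c1948_1959]": (d["cohort"] == "c1948_1959").astype(float),
        "cohort[post1960]": (d["cohort"] == "post1960").astype(float),
    })
    order = [REFERENCE_CLUSTER] + [c for c in cohort.config.class_names
                                   if c != REFERENCE_CLUSTER]
    codes = pd.Series(cohort.truth["latent_class"]).map(
        {c: i for i, c in enumerate(order)}).to_numpy()
    return codes, X


def _outcome_design(cohort: SimulatedCohort, beta: dict, drop=("const",)) -> pd.DataFrame:
    d = cohort.data
    cols = {}
    for name in beta:
        if name in drop:
            continue
        if name.startswith("cluster["):
            cls = name[len("cluster["):-1]
            cols[name] = (cohort.truth["latent_class"] == cls).astype(float)
        elif name == "ses[average]":
            cols[name] = (d["childhood_ses"] == "average").astype(float)
        else:
            cols[name] = d[name].astype(float)
    return pd.DataFrame(cols)


def truth_report(cohort: SimulatedCohort, labels=None) -> pd.DataFrame:
    """Refit the membership and outcome models on the simulated cohort with
    the generator's own design and score parameter recovery: one row per
    parameter with truth, estimate, SE, and z = (estimate - truth)/SE.

    With cluster ``labels`` given, appends an adjusted-Rand-index row
    comparing them to the latent classes.
    """
    cfg = cohort.config
    rows = []

    codes, Xm = _membership_design(cohort)
    order = [REFERENCE_CLUSTER] + [c for c in cfg.class_names if c != REFERENCE_CLUSTER]
    Xc = np.column_stack([np.ones(len(Xm)), Xm.to_numpy(float)])
    names = [f"{c}:{v}" for c in order[1:] for v in ["const"] + list(Xm.columns)]
    res = MultinomialLogit(codes, Xc, param_names=names,
                           category_names=order).fit()
    shares = dict(zip(cfg.class_names, cfg.class_shares))
    for name, est, se in zip(res.param_names, res.params, res.bse):
        cls, term = name.split(":", 1)
        if term == "const":
            truth = float(np.log(shares[cls] / shares[REFERENCE_CLUSTER]))
        else:
            truth = float(cfg.gamma.get(cls, {}).get(term, 0.0))
        rows.append(("membership", name, truth, est, se))

    Xs = _outcome_design(cohort, cfg.srh_beta)
    res_s = OrderedLogit(cohort.data["srh"].to_numpy(int) - 1,
                         Xs.to_numpy(float), param_names=list(Xs.columns)).fit()
    truth_s = [cfg.srh_beta[c] for c in Xs.columns] + list(cfg.srh_cutpoints)
    for name, tr, est, se in zip(res_s.param_names, truth_s, res_s.params, res_s.bse):
        rows.append(("srh", name, float(tr), est, se))

    Xn = _outcome_design(cohort, cfg.cesd_beta)
    Xn_full = np.column_stack([np.ones(len(Xn)), Xn.to_numpy(float)])
    res_n = NegativeBinomial(cohort.data["cesd"].to_numpy(int), Xn_full,
                             param_names=["const"] + list(Xn.columns)).fit()
    truth_n = ([cfg.cesd_beta["const"]] + [cfg.cesd_beta[c] for c in Xn.columns]
               + [cfg.cesd_lnalpha])
    for name, tr, est, se in zip(res_n.param_names, truth_n, res_n.params, res_n.bse):
        rows.append(("cesd", name, float(tr), est, se))

    rep = pd.DataFrame(rows, columns=["model", "parameter", "truth",
                                      "estimate", "se"])
    rep["z"] = (rep["estimate"] - rep["truth"]) / rep["se"]
    if labels is not None:
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(cohort.truth["latent_class"], labels)
        rep.attrs["ari"] = float(ari)
    return rep


def cluster_recovery_ari(cohort: SimulatedCohort, labels) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(cohort.truth["latent_class"], np.asarray(labels)))


# ---------------------------------------------------------------------------
# file emission


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Emit the file set consumed by the pipeline plus ground truth + config."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.10g"
    cohort.persons.to_csv(out / "persons.csv", index=False)
    m = cohort.marriages.copy()
    m["end_year"] = m["end_year"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    m.to_csv(out / "marriages.csv", index=False)
    cohort.snp_weights.to_csv(out / "snp_weights.csv", index=False, float_format=ff)
    cohort.genotypes.to_csv(out / "genotypes.csv")
    cohort.data.to_csv(out / "covariates.csv", index=False, float_format=ff)
    from .sequences import STATES

    chars = np.where(cohort.raw_sequences == MISSING, "-",
                     np.array(list(STATES))[np.clip(cohort.raw_sequences, 0, 4)])
    seq_df = pd.DataFrame(chars, columns=[f"a{a}" for a in range(AGE_MIN, AGE_MIN + SEQ_LEN)])
    seq_df.insert(0, "person_id", list(cohort.persons["person_id"]))
    seq_df.to_csv(out / "raw_sequences.csv", index=False)
    truth = {
        "config": _config_dict(cohort.config),
        "latent_class": list(map(str, cohort.truth["latent_class"])),
        "eta_srh": [round(float(v), 10) for v in cohort.truth["eta_srh"]],
        "mu_cesd": [round(float(v), 10) for v in cohort.truth["mu_cesd"]],
        "alpha_cesd": cohort.truth["alpha_cesd"],
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key, val in list(d.items()):
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
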