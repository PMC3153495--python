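"""Seeded synthetic cohorts with the statistical structure of an
EGFR-mutation IHC study.

The generator emulates a surgically resected lung-adenocarcinoma cohort
in which each tumor is sequenced (ground truth) and stained with two
mutation-specific antibodies, a total-EGFR antibody and a pan-cytokeratin
control.  The features it reproduces, and the default parameters, mirror
the published study conditions the pipeline is designed for:

* genotype mix proportional to 31 : 10 : 43 : 8 : 50 over
  {E746-A750 deletion, other Del-19, L858R (incl. complex forms),
  other mutations, wild type} in a cohort of 143;
* sex and smoking drawn with mutation-dependent rates (mutation prevalence
  79.2% in females vs 50.7% in males; 77.7% in never-smokers vs 40.8% in
  ever-smokers);
* carriers stain their cognate marker strongly (intensity 2-3, high
  percent) except a minority of IHC false negatives (11.6% for L858R,
  6.5% for the E746-A750 antibody);
* **cross-reactivity**: non-carriers receive mutation-marker staining whose
  propensity grows with kappa x (total-EGFR quickscore)/300 — the
  total-EGFR-driven nonspecific staining that makes a wild-type tumor with
  high EGFR expression weakly positive for the L858R antibody.  This is the
  false-positive structure the combined logistic score corrects.  With
  kappa = 0 non-carriers never stain and the single-marker rule is
  perfectly specific by construction;
* one in ten other-Del-19 tumors cross-stains the E746-A750 antibody
  (the L747-T751 phenomenon);
* TKI outcomes: responder probability 0.773 for IHC-positive vs 0.333 for
  IHC-negative patients; exponential PFS with group medians 12.0 vs 4.7
  months under independent uniform censoring; optional ECOG-PS effect
  multiplying the hazard by a configurable ratio (5.52 in the tabulated
  scenario).

Intensities are drawn by cutting a latent Gaussian (carriers/total EGFR)
or a scaled exponential (cross-reactive staining) at 0.5/1.5/2.5; percents
are Beta draws scaled to [0, 100].  All draws flow from a single
numpy Generator seeded from ``SimConfig.seed``: the same config yields a
byte-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["SimConfig", "simulate_cohort", "simulate_outcomes"]

GENOTYPE_CLASSES = ("E746-A750", "other-del19", "L858R", "other", "wild")
DEFAULT_GENOTYPE_WEIGHTS = (31.0, 10.0, 43.0, 8.0, 50.0)

# complex L858R forms and their relative frequency among L858R carriers
_COMPLEX_L858R = ("L858R+V834L", "L858R+E709V", "L858R+T790M", "L858R+K757N")
_OTHER_DEL19 = ("delL747-T751", "delL747-P753", "delE746-T751insQ")
_OTHER_MUTANTS = (
    "L861Q",
    "E709K+G719A",
    "E709K+G719S",
    "G719A+L861Q",
    "N771-H773dupNPH",
    "K860I+L861Q",
    "R831C+L861R",
    "delE709-T710insD",
)
_INTENSITY_CUTS = np.array([0.5, 1.5, 2.5])


def _normalized(weights) -> tuple:
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("genotype weights must be nonnegative with positive sum")
    return tuple(w / w.sum())


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    ``cross_reactivity`` (kappa) scales the per-marker base strengths in
    ``marker_cross_base``; 0 switches nonspecific staining off entirely.
    ``pfs_medians`` are (IHC-positive, IHC-negative) exponential medians in
    months; ``response_probs`` the corresponding responder probabilities.
    ``n_low_tumor_content`` appends extra rows below the 60% tumor-content
    gate so loader exclusion behaviour can be exercised end to end.
    """

    n_patients: int = 143
    seed: int = 0
    genotype_probs: tuple = field(
        default_factory=lambda: _normalized(DEFAULT_GENOTYPE_WEIGHTS)
    )
    cross_reactivity: float = 1.0
    marker_cross_base: tuple = (("l858r", 2.6), ("del19", 0.55))
    false_negative_rate: tuple = (("l858r", 5 / 43), ("del19", 2 / 31))
    complex_fraction_l858r: float = 5 / 43
    del19_antibody_cross_rate: float = 0.1
    total_latent_mean_mutant: float = 1.8
    total_latent_mean_wild: float = 1.0
    female_prob_mutant: float = 57 / 93
    female_prob_wild: float = 15 / 50
    nonsmoker_prob_mutant: float = 73 / 93
    nonsmoker_prob_wild: float = 21 / 50
    recurrence_rate: float = 80 / 143
    tki_fraction: float = 37 / 80
    response_probs: tuple = (0.773, 0.333)
    pfs_medians: tuple = (12.0, 4.7)
    censor_rate: float = 0.2
    ecog_ps24_rate: float = 9 / 37
    ecog_hazard_ratio: float | None = None
    n_low_tumor_content: int = 0

    def __post_init__(self) -> None:
        probs = _normalized(self.genotype_probs)
        if len(probs) != len(GENOTYPE_CLASSES):
            raise ValueError(f"genotype_probs must have {len(GENOTYPE_CLASSES)} entries")
        object.__setattr__(self, "genotype_probs", probs)
        if self.cross_reactivity < 0:
            raise ValueError("cross_reactivity must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        for p in (*self.response_probs, self.recurrence_rate, self.tki_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if any(m <= 0 for m in self.pfs_medians):
            raise ValueError("pfs_medians must be positive")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _cut_latent(latent: np.ndarray) -> np.ndarray:
    return np.digitize(latent, _INTENSITY_CUTS).astype(int)


def _percent(rng, a: float, b: float, size: int) -> np.ndarray:
    return np.round(np.clip(rng.beta(a, b, size=size) * 100.0, 1.0, 100.0), 1)


def _genotype_strings(rng, classes: np.ndarray, cfg: SimConfig) -> np.ndarray:
    out = np.empty(len(classes), dtype=object)
    for i, c in enumerate(classes):
        name = GENOTYPE_CLASSES[c]
        if name == "E746-A750":
            out[i] = "delE746-A750"
        elif name == "other-del19":
            out[i] = _OTHER_DEL19[rng.integers(len(_OTHER_DEL19))]
        elif name == "L858R":
            if rng.random() < cfg.complex_fraction_l858r:
                out[i] = _COMPLEX_L858R[rng.integers(len(_COMPLEX_L858R))]
            else:
                out[i] = "L858R"
        elif name == "other":
            out[i] = _OTHER_MUTANTS[rng.integers(len(_OTHER_MUTANTS))]
        else:
            out[i] = "wild"
    return out


def _cognate_stain(rng, n: int, fn_rate: float):
    """Carrier staining of its cognate antibody: strong, minus IHC misses."""
    miss = rng.random(n) < fn_rate
    intensity = np.where(rng.random(n) < 0.45, 2, 3)
    percent = _percent(rng, 6.0, 2.0, n)
    intensity[miss] = 0
    percent[miss] = 0.0
    return intensity.astype(int), percent


def _cross_reactive_stain(rng, total_q: np.ndarray, strength: float):
    """Nonspecific staining of non-carriers, driven by total-EGFR level."""
    n = len(total_q)
    latent = strength * (total_q / 300.0) * rng.exponential(1.0, size=n)
    intensity = np.minimum(_cut_latent(latent), 3)
    percent = _percent(rng, 2.0, 3.0, n)
    percent[intensity == 0] = 0.0
    return intensity, percent


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a per-patient staining + genotype table.

    Deterministic given ``config`` (including its seed).  Rows are in
    random enrolment order; the ``n_low_tumor_content`` extra rows are
    interleaved among the rest.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients + cfg.n_low_tumor_content

    classes = rng.choice(len(GENOTYPE_CLASSES), size=n, p=cfg.genotype_probs)
    genotype = _genotype_strings(rng, classes, cfg)
    class_names = np.array(GENOTYPE_CLASSES, dtype=object)[classes]
    is_mut = class_names != "wild"

    p_female = np.where(is_mut, cfg.female_prob_mutant, cfg.female_prob_wild)
    sex = np.where(rng.random(n) < p_female, "female", "male")
    p_nonsmoker = np.where(is_mut, cfg.nonsmoker_prob_mutant, cfg.nonsmoker_prob_wild)
    smoking = np.where(rng.random(n) < p_nonsmoker, "never", "ever")

    # total EGFR expression: mutants trend higher
    mu = np.where(is_mut, cfg.total_latent_mean_mutant, cfg.total_latent_mean_wild)
    total_intensity = _cut_latent(rng.normal(mu, 1.0))
    total_percent = _percent(rng, 3.0, 1.5, n)
    total_percent[total_intensity == 0] = 0.0
    total_q = total_intensity * total_percent

    kappa = dict(cfg.marker_cross_base)
    fn = dict(cfg.false_negative_rate)

    # L858R antibody: carriers are every tumor whose genotype contains L858R
    l858r_carrier = class_names == "L858R"
    l_int = np.zeros(n, dtype=int)
    l_pct = np.zeros(n)
    l_int[l858r_carrier], l_pct[l858r_carrier] = _cognate_stain(
        rng, int(l858r_carrier.sum()), fn["l858r"]
    )
    nc = ~l858r_carrier
    l_int[nc], l_pct[nc] = _cross_reactive_stain(
        rng, total_q[nc], cfg.cross_reactivity * kappa["l858r"]
    )

    # E746-A750 antibody: cognate carriers, plus occasional cross-staining
    # of other exon-19 deletions (the L747-T751 phenomenon)
    del_carrier = class_names == "E746-A750"
    d_int = np.zeros(n, dtype=int)
    d_pct = np.zeros(n)
    d_int[del_carrier], d_pct[del_carrier] = _cognate_stain(
        rng, int(del_carrier.sum()), fn["del19"]
    )
    nc = ~del_carrier
    d_int[nc], d_pct[nc] = _cross_reactive_stain(
        rng, total_q[nc], cfg.cross_reactivity * kappa["del19"]
    )
    other_del = class_names == "other-del19"
    cross = other_del & (rng.random(n) < cfg.del19_antibody_cross_rate)
    if cross.any():
        d_int[cross] = 2
        d_pct[cross] = _percent(rng, 5.0, 3.0, int(cross.sum()))

    panck_intensity = np.where(rng.random(n) < 0.3, 2, 3)
    panck_percent = _percent(rng, 8.0, 2.0, n)

    tumor_content = np.round(rng.uniform(60.0, 95.0, size=n), 1)
    if cfg.n_low_tumor_content:
        low_idx = rng.choice(n, size=cfg.n_low_tumor_content, replace=False)
        tumor_content[low_idx] = np.round(rng.uniform(20.0, 59.0, size=cfg.n_low_tumor_content), 1)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "genotype": genotype,
            "tumor_content": tumor_content,
            "sex": sex,
            "smoking": smoking,
            "l858r_intensity": l_int,
            "l858r_percent": l_pct,
            "del19_intensity": d_int,
            "del19_percent": d_pct,
            "total_egfr_intensity": total_intensity,
            "total_egfr_percent": total_percent,
            "panck_intensity": panck_intensity,
            "panck_percent": panck_percent,
        }
    )


def _censoring_horizon(rate: float, censor_rate: float) -> float:
    """Uniform(0, tau) horizon giving the requested censoring fraction.

    For C ~ U(0, tau) independent of T ~ Exp(rate),
    P(censored) = P(C < T) = (1 - exp(-rate*tau)) / (rate*tau).
    """
    if censor_rate <= 0:
        return np.inf

    def frac(tau):
        return (1.0 - np.exp(-rate * tau)) / (rate * tau) - censor_rate

    return brentq(frac, 1e-9, 1e9)


def simulate_outcomes(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Append recurrence, TKI treatment, response and PFS columns.

    IHC status drives the outcome model: if the cohort already carries an
    ``ihc_positive`` column it is used, otherwise the legacy 1+/>10% rule
    on either mutation-specific antibody is applied.  Response is Bernoulli
    by IHC status; PFS is exponential with the per-group medians under
    independent Uniform(0, tau) censoring with tau solved to give the
    configured censoring fraction.  Non-treated patients get missing
    outcome fields.
    """
    cfg = config
    rng = np.random.default_rng((cfg.seed + 1_000_003) % 2**31)
    df = cohort.copy()
    n = len(df)
    if "ihc_positive" in df.columns:
        ihc_pos = df["ihc_positive"].astype(bool).to_numpy()
    else:
        ihc_pos = np.zeros(n, dtype=bool)
        for m in ("l858r", "del19"):
            ihc_pos |= (df[f"{m}_intensity"].to_numpy() >= 1) & (
                df[f"{m}_percent"].to_numpy() > 10.0
            )
        df["ihc_positive"] = ihc_pos.astype(int)

    recurrence = rng.random(n) < cfg.recurrence_rate
    tki = recurrence & (rng.random(n) < cfg.tki_fraction)
    df["recurrence"] = recurrence.astype(int)
    df["tki_treated"] = tki.astype(int)

    line = np.where(
        rng.random(n) < 7 / 37, "first", rng.choice(["second", "third", "later"], size=n, p=np.array([12.0, 14.0, 4.0]) / 30.0)
    )
    ecog24 = rng.random(n) < cfg.ecog_ps24_rate

    p_resp = np.where(ihc_pos, cfg.response_probs[0], cfg.response_probs[1])
    responder = rng.random(n) < p_resp
    resp_cat = np.where(
        responder,
        np.where(rng.random(n) < 0.1, "CR", "PR"),
        np.where(rng.random(n) < 4 / 15, "SD", "PD"),
    )

    median = np.where(ihc_pos, cfg.pfs_medians[0], cfg.pfs_medians[1])
    rate = np.log(2.0) / median
    if cfg.ecog_hazard_ratio is not None:
        rate = rate * np.where(ecog24, cfg.ecog_hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        horizons = {r: _censoring_horizon(r, cfg.censor_rate) for r in np.unique(rate)}
        tau = np.array([horizons[r] for r in rate])
        c = rng.uniform(0.0, tau)
        event = t_event <= c
        time = np.minimum(t_event, c)
    else:
        event = np.ones(n, dtype=bool)
        time = t_event
    time = np.maximum(np.round(time, 2), 0.01)

    df["treatment_line"] = np.where(tki, line, "")
    df["ecog_ps"] = np.where(tki, np.where(ecog24, "2-4", "0-1"), "")
    df["response"] = np.where(tki, resp_cat, "")
    df["pfs_months"] = np.where(tki, time, np.nan)
    df["pfs_event"] = np.where(tki, event.astype(float), np.nan)
    return df
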