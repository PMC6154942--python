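"""Synthetic cohort, OTU table and phylogeny generation.

The generator emulates the statistical structure of a large South-China
population survey of gut microbiota and metabolic syndrome (MetS): roughly
20% MetS prevalence diagnosed from five components, economic-status strata
with correlated lifestyle variables, OTU counts whose composition carries
planted, phylogenetically clustered positive and negative phenotype effects,
and confounding of OTU abundance by age, gender, Bristol stool scale and
geographic region.

Diagnostics are drawn from a one-factor Gaussian model: a latent metabolic
risk score (loaded on age, sedentary time and spending) drives all five
components, whose marginal exceedance rates are set per gender. OTU counts
are Dirichlet-multinomial around a log-linear composition; planted phenotype
effects redistribute a fixed share of the community among responsive taxa so
that non-planted OTUs stay null in relative abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from scipy import stats as _sps

from .io import FACTOR_ORDER, OtuTable

__all__ = [
    "CohortConfig",
    "OtuConfig",
    "GroundTruthEffect",
    "MissingDataError",
    "diagnose_mets",
    "mets_components",
    "generate_cohort",
    "assign_taxonomy",
    "plant_effects",
    "generate_otu_table",
    "generate_tree",
]

DIAGNOSTICS = ("waist", "sbp", "dbp", "tg", "hdl", "fbg")

#: diagnostic thresholds (HDL is a lower bound; waist is gender specific)
THRESHOLDS = {
    "waist_male": 90.0,
    "waist_female": 85.0,
    "sbp": 130.0,
    "dbp": 85.0,
    "tg": 1.7,
    "hdl": 1.04,
    "fbg": 6.1,
}


class MissingDataError(ValueError):
    """A required measurement is absent."""


@dataclass
class CohortConfig:
    """Marginal distributions and couplings of the synthetic survey cohort.

    ``component_prevalence`` gives the target threshold-exceedance fraction of
    each diagnostic per gender (female, male); means are derived from these
    unless ``diagnostic_mean`` overrides them. ``risk_loading`` is the shared
    variance fraction each diagnostic loads on the latent metabolic risk
    score; it sets the component co-occurrence and hence the MetS rate.
    """

    male_prop: float = 0.449
    age_mean: float = 52.7
    age_sd: float = 14.6
    age_min: float = 18.0
    component_prevalence: dict = field(
        default_factory=lambda: {
            "waist": (0.253, 0.219),
            "sbp": (0.449, 0.503),
            "dbp": (0.203, 0.296),
            "tg": (0.191, 0.270),
            "hdl": (0.210, 0.358),
            "fbg": (0.165, 0.189),
        }
    )
    diagnostic_sd: dict = field(
        default_factory=lambda: {
            "waist": 9.0,
            "sbp": 20.0,
            "dbp": 11.0,
            "tg": 0.8,
            "hdl": 0.33,
            "fbg": 1.1,
        }
    )
    #: optional explicit means, overriding the prevalence-derived ones
    diagnostic_mean: dict | None = None
    #: shared-risk variance fraction per component (calibrated once so the
    #: realized MetS rate sits near 20% under the default marginals)
    risk_loading: float = 0.30
    #: extra SBP-DBP shared variance beyond the common risk factor
    bp_loading: float = 0.25
    age_risk_weight: float = 0.25
    sedentary_risk_weight: float = 0.25
    spending_risk_weight: float = 0.15
    sedentary_spending_rho: float = 0.3
    income_spending_rho: float = 0.85
    spending_log_mean: float = 8.8
    spending_log_sd: float = 0.7
    income_log_mean: float = 9.2
    income_log_sd: float = 0.7
    #: low/moderate/high spending-group proportions (survey ratio 1170/2394/1099)
    spending_group_props: tuple = (0.251, 0.513, 0.236)
    sedentary_mean: float = 4.0
    sedentary_sd: float = 2.0
    diet_spending_rho: dict = field(
        default_factory=lambda: {
            "diet_veg": 0.25,
            "diet_fruit": 0.25,
            "diet_grain": -0.25,
            "diet_meat": 0.0,
        }
    )
    diet_mean: dict = field(
        default_factory=lambda: {
            "diet_veg": 14.0,
            "diet_fruit": 7.0,
            "diet_grain": 14.0,
            "diet_meat": 10.0,
        }
    )
    diet_sd: float = 4.0
    smoking_logit_base: float = -2.6
    smoking_logit_male: float = 2.2
    smoking_logit_spending: float = -0.3
    bristol_sd: float = 1.2
    n_regions: int = 14
    min_components: int = 3


def diagnose_mets(
    gender: str,
    waist: float,
    sbp: float,
    dbp: float,
    tg: float,
    hdl: float,
    fbg: float,
    min_components: int = 3,
) -> dict:
    """Score one sample's five MetS components and the combined diagnosis.

    Components: central obesity (waist >= 90 cm male / >= 85 cm female),
    elevated blood pressure (SBP >= 130 or DBP >= 85 mmHg), TG >= 1.7 mmol/L,
    HDL < 1.04 mmol/L, FBG >= 6.1 mmol/L. All upper thresholds are inclusive;
    HDL is a strict lower bound. MetS is present when at least
    ``min_components`` (harmonised criteria: three) of the five are present.
    """
    values = {"waist": waist, "sbp": sbp, "dbp": dbp, "tg": tg, "hdl": hdl, "fbg": fbg}
    for name, value in values.items():
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingDataError(f"measurement {name!r} is missing")
        if value <= 0:
            raise ValueError(f"measurement {name!r} must be positive, got {value}")
    if gender not in ("female", "male"):
        raise ValueError(f"gender must be 'female' or 'male', got {gender!r}")
    waist_thr = THRESHOLDS["waist_male"] if gender == "male" else THRESHOLDS["waist_female"]
    flags = {
        "waist_flag": waist >= waist_thr,
        "bp_flag": sbp >= THRESHOLDS["sbp"] or dbp >= THRESHOLDS["dbp"],
        "tg_flag": tg >= THRESHOLDS["tg"],
        "hdl_flag": hdl < THRESHOLDS["hdl"],
        "fbg_flag": fbg >= THRESHOLDS["fbg"],
    }
    flags["mets"] = sum(flags.values()) >= min_components
    return flags


def mets_components(cohort: pd.DataFrame, min_components: int = 3) -> pd.DataFrame:
    """Vectorised component flags for a cohort table (adds sbp/dbp flags)."""
    for col in ("gender",) + DIAGNOSTICS:
        if col not in cohort.columns:
            raise MissingDataError(f"cohort column {col!r} is missing")
    male = (cohort["gender"] == "male").to_numpy()
    waist_thr = np.where(male, THRESHOLDS["waist_male"], THRESHOLDS["waist_female"])
    out = pd.DataFrame(index=cohort.index)
    out["waist_flag"] = cohort["waist"].to_numpy() >= waist_thr
    out["sbp_flag"] = cohort["sbp"] >= THRESHOLDS["sbp"]
    out["dbp_flag"] = cohort["dbp"] >= THRESHOLDS["dbp"]
    out["bp_flag"] = out["sbp_flag"] | out["dbp_flag"]
    out["tg_flag"] = cohort["tg"] >= THRESHOLDS["tg"]
    out["hdl_flag"] = cohort["hdl"] < THRESHOLDS["hdl"]
    out["fbg_flag"] = cohort["fbg"] >= THRESHOLDS["fbg"]
    comp = out[["waist_flag", "bp_flag", "tg_flag", "hdl_flag", "fbg_flag"]]
    out["mets"] = comp.sum(axis=1) >= min_components
    return out


def _validate_config(config: CohortConfig) -> None:
    for name, sd in config.diagnostic_sd.items():
        if sd < 0:
            raise ValueError(f"invalid config: negative SD for {name!r}")
    if config.age_sd < 0 or config.sedentary_sd < 0 or config.diet_sd < 0:
        raise ValueError("invalid config: negative SD")
    props = config.spending_group_props
    if len(props) != 3 or abs(sum(props) - 1.0) > 1e-6:
        raise ValueError("invalid config: spending_group_props must sum to 1")


def generate_cohort(
    n: int, config: CohortConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a synthetic survey cohort of ``n`` participants.

    Returns a DataFrame indexed by sample_id with demographics, the six MetS
    diagnostics, component flags, the MetS diagnosis, economics (income,
    spending, spending_group), lifestyle (sedentary hours/day, four diet
    frequencies, smoking), Bristol stool scale and sampling region.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    config = config or CohortConfig()
    _validate_config(config)
    rng = np.random.default_rng(seed)

    gender = np.where(rng.random(n) < config.male_prop, "male", "female")
    male = gender == "male"
    age_z = rng.standard_normal(n)
    age = np.maximum(config.age_min, config.age_mean + config.age_sd * age_z)

    # economics & lifestyle latents (Gaussian copula)
    spend_z = rng.standard_normal(n)
    rho = config.sedentary_spending_rho
    sed_z = rho * spend_z + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    spending = np.exp(config.spending_log_mean + config.spending_log_sd * spend_z)
    r_inc = config.income_spending_rho
    income = np.exp(
        config.income_log_mean
        + config.income_log_sd
        * (r_inc * spend_z + math.sqrt(max(0.0, 1 - r_inc**2)) * rng.standard_normal(n))
    )
    sedentary = np.clip(config.sedentary_mean + config.sedentary_sd * sed_z, 0.25, 16.0)

    # latent metabolic risk: loads on age, sedentary time and spending
    a, b, c = (
        config.age_risk_weight,
        config.sedentary_risk_weight,
        config.spending_risk_weight,
    )
    explained = a**2 + b**2 + c**2 + 2 * b * c * rho
    if explained >= 1.0:
        raise ValueError("invalid config: risk weights explain more than unit variance")
    risk = (
        a * age_z + b * sed_z + c * spend_z + math.sqrt(1 - explained) * rng.standard_normal(n)
    )

    lam = config.risk_loading
    bp_extra = config.bp_loading
    if not (0 <= lam < 1) or not (0 <= bp_extra < 1 - lam):
        raise ValueError("invalid config: loadings must satisfy 0 <= lambda + bp < 1")
    bp_shared = rng.standard_normal(n)

    values = {}
    for name in DIAGNOSTICS:
        extra = bp_extra if name in ("sbp", "dbp") else 0.0
        x = (
            math.sqrt(lam) * risk
            + math.sqrt(extra) * bp_shared
            + math.sqrt(1 - lam - extra) * rng.standard_normal(n)
        )
        sd = config.diagnostic_sd[name]
        if config.diagnostic_mean is not None and name in config.diagnostic_mean:
            mean = np.full(n, float(config.diagnostic_mean[name]))
        else:
            p_f, p_m = config.component_prevalence[name]
            if name == "waist":
                thr = np.where(male, THRESHOLDS["waist_male"], THRESHOLDS["waist_female"])
            elif name == "hdl":
                thr = THRESHOLDS["hdl"]
            else:
                thr = THRESHOLDS[name]
            p = np.where(male, p_m, p_f)
            if name == "hdl":
                # HDL is a lower threshold: P(value < thr) = p
                mean = thr - sd * _sps.norm.ppf(p)
            else:
                mean = thr - sd * _sps.norm.ppf(1 - p)
        sign = -1.0 if name == "hdl" else 1.0
        # low HDL is the disorder: risk pushes HDL down
        values[name] = np.maximum(0.05, mean + sd * sign * x)

    diet = {}
    for col, rho_d in config.diet_spending_rho.items():
        lat = rho_d * spend_z + math.sqrt(max(0.0, 1 - rho_d**2)) * rng.standard_normal(n)
        diet[col] = np.maximum(0.0, config.diet_mean[col] + config.diet_sd * lat)

    logit = (
        config.smoking_logit_base
        + config.smoking_logit_male * male
        + config.smoking_logit_spending * spend_z
    )
    smoking = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    bristol = np.clip(np.rint(4.0 + config.bristol_sd * rng.standard_normal(n)), 1, 7).astype(int)
    region = rng.integers(0, config.n_regions, size=n)

    edges = np.quantile(spending, np.cumsum(config.spending_group_props)[:2])
    group = np.where(
        spending <= edges[0], "low", np.where(spending <= edges[1], "moderate", "high")
    )

    cohort = pd.DataFrame(
        {
            "age": np.round(age, 1),
            "gender": gender,
            **{k: np.round(values[k], 3) for k in DIAGNOSTICS},
            "income": np.round(income, 0),
            "spending": np.round(spending, 0),
            "spending_group": group,
            "sedentary": np.round(sedentary, 2),
            **{k: np.round(v, 1) for k, v in diet.items()},
            "smoking": smoking,
            "bristol": bristol,
            "region": [f"R{r:02d}" for r in region],
        },
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id"),
    )
    flags = mets_components(cohort, config.min_components)
    return pd.concat([cohort, flags], axis=1)


# --------------------------------------------------------------------------
# taxonomy and planted effects

# synthetic community composition: (phylum, class, order, family,
# association-direction prior, fraction of OTUs)
_FAMILIES = [
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", -1, 0.10),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", -1, 0.09),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", -1, 0.05),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", -1, 0.16),
    ("Firmicutes", "Clostridia", "Clostridiales", "Christensenellaceae", -1, 0.02),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", +1, 0.16),
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", +1, 0.05),
    ("Firmicutes", "Clostridia", "Clostridiales", "Veillonellaceae", +1, 0.05),
    ("Firmicutes", "Clostridia", "Clostridiales", "Peptostreptococcaceae", +1, 0.03),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", +1, 0.08),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Alcaligenaceae", +1, 0.06),
    ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", +1, 0.04),
    ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", +1, 0.03),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae", -1, 0.02),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", +1, 0.02),
    ("Tenericutes", "Mollicutes", "RF39", "", -1, 0.02),
    ("Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", -1, 0.02),
]


def assign_taxonomy(n_otus: int, seed: int = 0) -> pd.Series:
    """Greengenes-style 7-rank labels over a realistic family mixture."""
    rng = np.random.default_rng(seed)
    probs = np.array([f[5] for f in _FAMILIES])
    probs = probs / probs.sum()
    picks = rng.choice(len(_FAMILIES), size=n_otus, p=probs)
    labels = []
    for i, k in enumerate(picks):
        phylum, cls, order, family, _, _ = _FAMILIES[k]
        genus = f"g{k}" if family else ""
        labels.append(
            f"k__Bacteria;p__{phylum};c__{cls};o__{order};f__{family};g__{genus};s__"
        )
    return pd.Series(labels, index=[f"OTU{i:05d}" for i in range(n_otus)], name="taxonomy")


_FAMILY_DIRECTION = {f[3]: f[4] for f in _FAMILIES if f[3]}
_FAMILY_DIRECTION["RF39-order"] = -1


@dataclass(frozen=True)
class GroundTruthEffect:
    """Planted OTU-factor effect: log-composition shift per SD of the factor."""

    otu_id: str
    factor: str
    effect: float

    @property
    def direction(self) -> int:
        return 1 if self.effect >= 0 else -1


def _family_of(label: str) -> str:
    for part in label.split(";"):
        part = part.strip()
        if part.startswith("f__") and len(part) > 3:
            return part[3:]
    if "o__RF39" in label:
        return "RF39-order"
    return ""


def plant_effects(
    taxonomy: pd.Series,
    n_signal: int,
    effect_range: tuple[float, float] = (0.3, 0.6),
    family_consistency: float = 0.9,
    factors_per_otu: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> list[GroundTruthEffect]:
    """Plant phenotype effects clustered by taxon.

    Each of ``n_signal`` OTUs receives a disorder direction drawn from its
    family's prior (probability ``family_consistency`` of following the
    family), a MetS effect, and effects on a random subset of diagnostic
    factors, all direction-coherent. The HDL effect sign is flipped relative
    to the disorder direction because low HDL is the disorder.
    """
    if n_signal > len(taxonomy):
        raise ValueError("n_signal exceeds number of OTUs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(taxonomy.index.to_numpy(), size=n_signal, replace=False)
    lo, hi = effect_range
    diag_pool = ["waist", "sbp", "dbp", "tg", "hdl", "fbg"]
    effects: list[GroundTruthEffect] = []
    for otu in chosen:
        fam_dir = _FAMILY_DIRECTION.get(_family_of(taxonomy.loc[otu]), 1)
        direction = fam_dir if rng.random() < family_consistency else -fam_dir
        n_extra = rng.integers(factors_per_otu[0], factors_per_otu[1] + 1) - 1
        picked = list(rng.choice(diag_pool, size=min(n_extra, len(diag_pool)), replace=False))
        for factor in ["mets"] + picked:
            magnitude = rng.uniform(lo, hi)
            sign = -direction if factor == "hdl" else direction
            effects.append(GroundTruthEffect(otu, factor, sign * magnitude))
    return effects


@dataclass
class OtuConfig:
    """Shape of the synthetic OTU count table.

    ``baseline_log_sd`` sets the heavy tail of baseline abundances (and hence
    how many OTUs clear a prevalence filter); ``concentration`` is the
    Dirichlet-multinomial precision (smaller = more overdispersion).
    Confounder effects default to half the strong planted effect size so
    de-confounding is exercised without washing out the signal.
    """

    baseline_log_sd: float = 2.0
    concentration: float = 100.0
    confounder_frac: float = 0.2
    confounder_effect_sd: float = 0.15
    region_effect_sd: float = 0.15
    #: planted OTUs get baselines at or above this community quantile
    signal_baseline_quantile: float = 0.85
    #: extra baseline mass for disorder-positive planted OTUs, so dysbiosis
    #: concentrates abundance (lower diversity in MetS)
    positive_extra_boost: float = 0.75
    #: leak of (standardised log) spending into the MetS-effect channel;
    #: negative values emulate slightly less dysbiotic microbiota at higher
    #: economic status
    index_spending_coupling: float = -0.06
    #: SD of a per-sample latent that moves the whole planted disorder
    #: profile coherently (phenotype-independent dysbiosis variation); this
    #: correlated noise bounds how well any abundance-aggregating index can
    #: track the phenotype, as in real communities
    profile_noise_sd: float = 0.0


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def factor_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Standardised factor columns (binary component flags, MetS, log economics)."""
    cols = {}
    flag_map = {
        "waist": "waist_flag",
        "sbp": "sbp_flag",
        "dbp": "dbp_flag",
        "tg": "tg_flag",
        "hdl": "hdl_flag",
        "fbg": "fbg_flag",
        "mets": "mets",
    }
    flags = (
        mets_components(cohort)
        if not all(c in cohort.columns for c in flag_map.values())
        else cohort
    )
    for factor, col in flag_map.items():
        cols[factor] = _standardize(flags[col].to_numpy().astype(float))
    for factor in ("income", "spending"):
        cols[factor] = _standardize(np.log(cohort[factor].to_numpy().astype(float)))
    return pd.DataFrame(cols, index=cohort.index)


def generate_otu_table(
    cohort: pd.DataFrame,
    effects: list[GroundTruthEffect],
    n_otus: int = 1000,
    depth: int = 10000,
    seed: int = 0,
    config: OtuConfig | None = None,
    taxonomy: pd.Series | None = None,
) -> OtuTable:
    """Draw Dirichlet-multinomial OTU counts with planted phenotype effects.

    Planted effects shift log-composition per SD of the standardised factor,
    but redistribute abundance only within the planted OTU set (each sample's
    planted-set share is held at its baseline value), so non-planted OTUs are
    genuinely null in relative abundance. Confounder effects (age, gender,
    Bristol, region) apply community-wide. Every sample sums exactly to
    ``depth``.
    """
    if depth < 100:
        raise ValueError("depth must be >= 100")
    if n_otus < 10:
        raise ValueError("n_otus must be >= 10")
    config = config or OtuConfig()
    for eff in effects:
        if eff.factor not in FACTOR_ORDER:
            raise ValueError(f"invalid config: effect references unknown factor {eff.factor!r}")
    rng = np.random.default_rng(seed)
    if taxonomy is None:
        taxonomy = assign_taxonomy(n_otus, seed=seed)
    if len(taxonomy) != n_otus:
        raise ValueError("taxonomy length must equal n_otus")
    otu_ids = list(taxonomy.index)
    otu_pos = {o: i for i, o in enumerate(otu_ids)}
    for eff in effects:
        if eff.otu_id not in otu_pos:
            raise ValueError(f"invalid config: effect references unknown OTU {eff.otu_id!r}")

    n = len(cohort)
    baseline = config.baseline_log_sd * rng.standard_normal(n_otus)

    # effect matrix E: OTUs x factors
    factors = factor_matrix(cohort)
    E = np.zeros((n_otus, factors.shape[1]))
    f_pos = {f: j for j, f in enumerate(factors.columns)}
    for eff in effects:
        E[otu_pos[eff.otu_id], f_pos[eff.factor]] += eff.effect
    planted = np.flatnonzero(np.abs(E).sum(axis=1) > 0)

    if planted.size:
        floor = np.quantile(baseline, config.signal_baseline_quantile)
        baseline[planted] = np.maximum(baseline[planted], floor)
        mets_dir = np.sign(E[:, f_pos["mets"]])
        baseline[planted] += config.positive_extra_boost * (mets_dir[planted] > 0)

    # community-wide confounder effects
    conf_shift = np.zeros((n, n_otus))
    conf_cols = {
        "age": _standardize(cohort["age"].to_numpy()),
        "gender": _standardize((cohort["gender"] == "male").to_numpy().astype(float)),
        "bristol": _standardize(cohort["bristol"].to_numpy().astype(float)),
    }
    for z in conf_cols.values():
        mask = rng.random(n_otus) < config.confounder_frac
        coef = np.where(
            mask, rng.choice([-1.0, 1.0], n_otus) * config.confounder_effect_sd, 0.0
        )
        conf_shift += np.outer(z, coef)
    regions = pd.Categorical(cohort["region"])
    region_offsets = config.region_effect_sd * rng.standard_normal(
        (len(regions.categories), n_otus)
    )
    conf_shift += region_offsets[regions.codes]

    # baseline + confounder composition (softmax over all OTUs)
    logq = baseline[None, :] + conf_shift
    logq -= logq.max(axis=1, keepdims=True)
    q = np.exp(logq)
    q /= q.sum(axis=1, keepdims=True)

    comp = q
    if planted.size:
        # planted factor shifts; the spending leak moves each planted OTU
        # along its disorder profile per SD of log spending, scaled to one
        # effective channel (divide by sqrt of the OTU's factor count so the
        # leak is commensurate with a single factor's contribution)
        shift = factors.to_numpy() @ E.T  # n x n_otus
        k = np.maximum((E != 0).sum(axis=1), 1)
        profile = E.sum(axis=1) / np.sqrt(k)
        if config.index_spending_coupling != 0.0:
            spend_z = factors["spending"].to_numpy()
            shift += config.index_spending_coupling * np.outer(spend_z, profile)
        if config.profile_noise_sd > 0.0:
            g = rng.standard_normal(n)
            shift += config.profile_noise_sd * np.outer(g, profile)
        directions = np.sign(E.sum(axis=1)[planted])
        if (directions > 0).any() and (directions < 0).any():
            # redistribute within the planted set at fixed per-sample share:
            # enriched taxa grow at the expense of depleted ones, so
            # non-planted OTUs stay exactly null in relative abundance
            share = q[:, planted].sum(axis=1, keepdims=True)
            v = q[:, planted] * np.exp(shift[:, planted])
            v *= share / v.sum(axis=1, keepdims=True)
            comp = q.copy()
            comp[:, planted] = v
        else:
            # a one-sided planted set has no within-set counterweight; the
            # whole community absorbs the (compositional) complement
            logp = np.log(q)
            logp[:, planted] += shift[:, planted]
            logp -= logp.max(axis=1, keepdims=True)
            comp = np.exp(logp)
            comp /= comp.sum(axis=1, keepdims=True)

    alpha = comp * config.concentration
    gam = rng.gamma(np.maximum(alpha, 1e-12))
    probs = gam / gam.sum(axis=1, keepdims=True)
    counts = rng.multinomial(depth, probs)

    df = pd.DataFrame(counts, index=cohort.index, columns=otu_ids)
    return OtuTable(df, taxonomy)


def generate_tree(otu_ids, seed: int = 0) -> skbio.TreeNode:
    """Random rooted bifurcating tree over ``otu_ids`` with positive lengths."""
    otu_ids = list(otu_ids)
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 ids")
    if len(set(otu_ids)) != len(otu_ids):
        raise ValueError("duplicate ids")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in otu_ids:
        tip = skbio.TreeNode(name=name)
        tip.length = float(0.05 + rng.exponential(1.0))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(children=[left, right])
        parent.length = float(0.05 + rng.exponential(1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root
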