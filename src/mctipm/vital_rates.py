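"""Vital-rate regressions, model selection and the genotype-frequency model.

Seven vital rates are fitted as GLMMs with a clonal random intercept:
interval-scale survival (logit), somatic growth in mm/day (identity),
egg-carrying probability (logit), neonate-release probability given eggs
(logit), clutch size (log), neonate female probability (logit, binomial in
the clutch) and neonate size in mm (identity).  Candidate fixed-effect
structures come from the M1..M5 ladder in :mod:`mctipm.structures` and are
compared by ELPD leave-one-out cross-validation approximated with
Pareto-smoothed importance sampling over posterior draws.

The genotype-frequency model is a no-intercept logistic regression of the
probability that a destructively sampled individual is Southern:
logit p = day*b1 + u_aquarium + day*T*b2, anchored at p = 0.5 on day 0.
Combined with total census counts it partitions density into sympatric and
allopatric components for use as regression covariates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from . import glmm
from .standardize import DEFAULT_TEMPERATURE_SCALE, size_to_z
from .structures import (
    FAMILIES,
    RATE_NAMES,
    STRUCTURE_LABELS,
    design_matrix,
    structure_terms,
)
from .truth import TrueParameters


@dataclass
class InferenceConfig:
    n_draws: int = 1000
    seed: int = 0
    #: rstanarm-style prior autoscaling: each fixed effect gets a
    #: Normal(0, (2.5 / sd(column))^2) prior, so raw-count density
    #: covariates receive the same weakly informative regularization as
    #: standardized ones.  The intercept keeps a flat-ish Normal(0, 10^2).
    autoscale_priors: bool = True
    prior_scale: float = 2.5


def _prior_sds(X: np.ndarray, inference: "InferenceConfig") -> np.ndarray | float:
    if not inference.autoscale_priors:
        return glmm.PRIOR_SD_BETA
    sds = X.std(axis=0)
    out = np.where(sds > 0, inference.prior_scale / np.maximum(sds, 1e-12),
                   glmm.PRIOR_SD_BETA)
    return np.minimum(out, glmm.PRIOR_SD_BETA)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class VitalRateModel:
    """One fitted (or truth-specified) vital-rate regression."""

    rate: str
    family: str
    terms: tuple[str, ...]
    coef: np.ndarray
    clone_sd: float = 0.0
    residual_sd: float | None = None
    draws: np.ndarray | None = None              # (n_draws, p) fixed effects
    residual_sd_draws: np.ndarray | None = None  # (n_draws,) gaussian only

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.terms) != self.coef.shape[0]:
            raise ValueError("terms/coef length mismatch")
        if self.family == "gaussian" and self.residual_sd is None:
            raise ValueError("gaussian model needs residual_sd")
        if self.draws is not None:
            if not np.all(np.isfinite(self.draws)):
                raise ValueError("non-finite values in draw store")

    @property
    def n_draws(self) -> int:
        return 0 if self.draws is None else self.draws.shape[0]

    def _beta(self, draw: int | None) -> np.ndarray:
        if draw is None:
            return self.coef
        if self.draws is None:
            raise ValueError(f"model for {self.rate!r} has no draw store")
        return self.draws[draw]

    def sigma(self, draw: int | None = None) -> float | None:
        if self.family != "gaussian":
            return None
        if draw is None or self.residual_sd_draws is None:
            return self.residual_sd
        return float(self.residual_sd_draws[draw])

    def linpred(self, cov: pd.DataFrame, draw: int | None = None) -> np.ndarray:
        """Link-scale prediction: exact dot product of coefficients and design row."""
        X = design_matrix(self.terms, cov)
        return X @ self._beta(draw)

    def predict(self, cov: pd.DataFrame, draw: int | None = None) -> np.ndarray:
        eta = self.linpred(cov, draw)
        if self.family == "binomial":
            return expit(eta)
        if self.family == "poisson":
            return np.exp(eta)
        return eta

    def affine_in_density(self, z: np.ndarray, T: float, L: float, sex: float,
                          draw: int | None = None):
        """Decompose eta(z, S, A) = base(z) + kS*S + kA*A at fixed T, L, sex.

        Valid because no ladder structure interacts density with body size;
        used by the kernel builder to avoid re-evaluating size terms while
        scanning densities.
        """
        beta = self._beta(draw)
        scalars = {"T": T, "L": L, "sex": sex}
        base = np.zeros_like(z, dtype=float)
        kS = 0.0
        kA = 0.0
        for term, b in zip(self.terms, beta):
            factors = [] if term == "1" else term.split(":")
            dens = [f for f in factors if f in ("S", "A")]
            w = b
            vec = None
            for f in factors:
                if f in ("S", "A"):
                    continue
                if f == "z":
                    vec = z if vec is None else vec * z
                else:
                    w *= scalars[f]
            if dens:
                if vec is not None:
                    raise ValueError(f"term {term!r} mixes size and density")
                if dens == ["S"]:
                    kS += w
                elif dens == ["A"]:
                    kA += w
                else:
                    raise ValueError(f"term {term!r} mixes S and A")
            else:
                base = base + (w if vec is None else w * vec)
        return base, kS, kA

    @classmethod
    def from_truth(cls, truth: TrueParameters, rate: str) -> "VitalRateModel":
        rt = truth.rates[rate]
        terms = tuple(rt.coef)
        return cls(
            rate=rate,
            family=FAMILIES[rate],
            terms=terms,
            coef=np.array([rt.coef[t] for t in terms]),
            clone_sd=rt.clone_sd,
            residual_sd=rt.residual_sd,
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "family": self.family,
            "terms": list(self.terms),
            "coef": self.coef.tolist(),
            "clone_sd": self.clone_sd,
            "residual_sd": self.residual_sd,
        }

    @classmethod
    def from_dict(cls, d: dict, draws=None, residual_sd_draws=None):
        return cls(
            rate=d["rate"], family=d["family"], terms=tuple(d["terms"]),
            coef=np.asarray(d["coef"], dtype=float),
            clone_sd=float(d.get("clone_sd", 0.0)),
            residual_sd=d.get("residual_sd"),
            draws=draws, residual_sd_draws=residual_sd_draws,
        )


class ModelSet:
    """The seven fitted rate models plus per-rate latitude-swap flags.

    A swapped rate is evaluated with the latitude indicator flipped, i.e.
    each latitude uses the *other* latitude's full prediction function for
    that rate (all latitude main effects and interactions included), while
    sympatric/allopatric densities keep their own-vs-other meaning.
    """

    def __init__(self, models: dict[str, VitalRateModel], swapped=()):
        missing = set(RATE_NAMES) - set(models)
        if missing:
            raise ValueError(f"missing rate models: {sorted(missing)}")
        unknown = set(swapped) - set(RATE_NAMES)
        if unknown:
            raise ValueError(
                f"unknown rate(s) {sorted(unknown)}; valid: {list(RATE_NAMES)}")
        self.models = dict(models)
        self.swapped = frozenset(swapped)

    def __getitem__(self, rate: str) -> VitalRateModel:
        return self.models[rate]

    def effective_latitude(self, rate: str, latitude_indicator: float) -> float:
        if rate in self.swapped:
            return 1.0 - latitude_indicator
        return latitude_indicator

    def with_swapped(self, rate: str) -> "ModelSet":
        if rate not in RATE_NAMES:
            raise ValueError(
                f"unknown rate {rate!r}; valid: {list(RATE_NAMES)}")
        new = set(self.swapped) ^ {rate}
        return ModelSet(self.models, swapped=new)

    def min_draws(self) -> int:
        return min(m.n_draws for m in self.models.values())

    @classmethod
    def from_truth(cls, truth: TrueParameters) -> "ModelSet":
        return cls({r: VitalRateModel.from_truth(truth, r) for r in RATE_NAMES})


# ---------------------------------------------------------------------------
# response extraction
# ---------------------------------------------------------------------------

def rate_frame(prepared: pd.DataFrame, rate: str) -> pd.DataFrame:
    """Select the observation rows and response for one vital rate.

    Expects a prepared frame with covariate columns z, T, S, A, L, sex,
    clone plus the raw observation columns; returns the subset with `y`
    (and `trials` for female probability).
    """
    df = prepared
    if rate == "survival":
        out = df[df["survived"].notna()].copy()
        out["y"] = out["survived"].astype(float)
    elif rate == "growth":
        out = df[(df["survived"] == 1) & df["size_t1_mm"].notna()].copy()
        out["y"] = (out["size_t1_mm"] - out["size_t_mm"]) / out["interval_days"]
    elif rate == "egg_prob":
        out = df[(df["sex"] == 0.0) & df["carried_eggs"].notna()].copy()
        out["y"] = out["carried_eggs"].astype(float)
    elif rate == "release_prob":
        out = df[df["carried_eggs"] == 1].copy()
        out["y"] = out["released"].astype(float)
    elif rate == "clutch_size":
        out = df[df["released"] == 1].copy()
        out["y"] = out["clutch_size"].astype(float)
    elif rate == "female_prob":
        out = df[(df["released"] == 1) & (df["clutch_size"] > 0)].copy()
        out["y"] = out["n_female"].astype(float)
        out["trials"] = out["clutch_size"].astype(float)
    elif rate == "neonate_size":
        out = df[df["neonate_size_mm"].notna()].copy()
        out["y"] = out["neonate_size_mm"].astype(float)
    else:
        raise ValueError(f"unknown rate {rate!r}")
    return out


def fit_vital_rate(
    frame: pd.DataFrame,
    rate: str,
    structure: str = "M5",
    inference: InferenceConfig | None = None,
) -> VitalRateModel:
    """Fit one vital-rate GLMM and return it with its posterior draw store.

    `frame` must carry covariate columns (z, T, S, A, L, sex for survival/
    growth), a `clone` column and the response `y` (plus `trials` for
    female probability); :func:`rate_frame` builds it from prepared
    individual records.
    """
    inference = inference or InferenceConfig()
    terms = structure_terms(structure, rate)
    missing = [c for c in ("y", "clone") if c not in frame.columns]
    if missing:
        raise KeyError(f"frame for rate {rate!r} lacks columns {missing}")
    X = design_matrix(terms, frame)
    family = FAMILIES[rate]
    trials = frame["trials"].to_numpy(float) if rate == "female_prob" else None
    try:
        fit = glmm.fit_glmm_laplace(
            X, frame["y"].to_numpy(float), family=family,
            groups=frame["clone"].to_numpy(), trials=trials,
            n_draws=inference.n_draws, seed=inference.seed,
            prior_sd_beta=_prior_sds(X, inference),
        )
    except glmm.DegenerateFitError as err:
        raise glmm.DegenerateFitError(f"rate {rate!r}: {err}") from err
    model = VitalRateModel(
        rate=rate, family=family, terms=terms, coef=fit.beta,
        clone_sd=fit.sigma_group, residual_sd=fit.sigma_resid,
        draws=fit.beta_draws() if inference.n_draws else None,
        residual_sd_draws=fit.sigma_resid_draws(),
    )
    model._laplace = fit  # retained for model selection diagnostics
    return model


# ---------------------------------------------------------------------------
# model selection (ELPD-LOO via Pareto-smoothed importance sampling)
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionTable:
    rate: str
    table: pd.DataFrame  # columns: label, n_params, elpd, se, selected, error

    @property
    def selected(self) -> str:
        return self.table.loc[self.table["selected"], "label"].iloc[0]


def _elpd_loo(loglik: np.ndarray) -> tuple[float, float]:
    """ELPD-LOO and its SE from a (draws, n_obs) conditional log-lik matrix."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, _ = az.psislw(-loglik.T)  # psislw wants (n_obs, n_samples)
    elpd_i = logsumexp(lw + loglik.T, axis=1)
    n = loglik.shape[1]
    return float(elpd_i.sum()), float(np.sqrt(n * np.var(elpd_i)))


def select_model(
    frame: pd.DataFrame,
    rate: str,
    candidate_structures=STRUCTURE_LABELS,
    inference: InferenceConfig | None = None,
) -> ModelSelectionTable:
    """Fit every candidate structure and rank by ELPD-LOO.

    Selection takes the maximal ELPD; ties (within 1e-9) break toward the
    structure with fewer parameters, then toward the earlier-listed one.
    Candidates that fail to fit are marked unavailable and skipped.
    """
    candidates = list(candidate_structures)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate structures")
    rows = []
    for label in candidates:
        terms = structure_terms(label, rate)
        try:
            model = fit_vital_rate(frame, rate, structure=label,
                                   inference=inference)
            elpd, se = _elpd_loo(model._laplace.loglik_matrix())
            rows.append({"label": label, "n_params": len(terms),
                         "elpd": elpd, "se": se, "error": ""})
        except Exception as err:  # candidate unavailable; selection proceeds
            rows.append({"label": label, "n_params": len(terms),
                         "elpd": -np.inf, "se": np.nan, "error": str(err)})
    tab = pd.DataFrame(rows)
    ok = tab["elpd"] > -np.inf
    if not ok.any():
        raise RuntimeError(f"no candidate structure could be fitted for {rate!r}")
    best = tab.loc[ok, "elpd"].max()
    contenders = tab.index[ok & (tab["elpd"] >= best - 1e-9)]
    winner = min(contenders, key=lambda i: (tab.loc[i, "n_params"], i))
    tab["selected"] = tab.index == winner
    return ModelSelectionTable(rate=rate, table=tab)


# ---------------------------------------------------------------------------
# genotype-frequency model and density partitioning
# ---------------------------------------------------------------------------

@dataclass
class FrequencyModel:
    """No-intercept logistic model of Southern sampling probability."""

    beta_day: float
    beta_day_temp: float
    aquarium_sd: float
    aquarium_effects: dict[str, float]
    draws: np.ndarray | None = None  # (n_draws, 2): [beta_day, beta_day_temp]

    def linpred(self, day, temperature_std, aquarium=None,
                draw: int | None = None):
        if draw is None:
            b1, b2 = self.beta_day, self.beta_day_temp
        else:
            b1, b2 = self.draws[draw]
        u = self.aquarium_effects.get(aquarium, 0.0) if aquarium else 0.0
        day = np.asarray(day, dtype=float)
        return day * b1 + u + day * np.asarray(temperature_std, float) * b2

    def p_south(self, day, temperature_std, aquarium=None,
                draw: int | None = None):
        return expit(self.linpred(day, temperature_std, aquarium, draw))


def fit_genotype_frequencies(
    samples: pd.DataFrame,
    inference: InferenceConfig | None = None,
) -> FrequencyModel:
    """Fit the frequency model to destructive genotype samples.

    `samples` needs columns aquarium, day (> 0), temperature_std and
    latitude_sampled ("S"/"N").  With samples from a single latitude the
    fit proceeds under its priors but a separation warning is issued.
    """
    inference = inference or InferenceConfig()
    if samples["aquarium"].nunique() < 2:
        raise ValueError("need samples from at least 2 aquaria")
    if (samples["day"] <= 0).any():
        raise ValueError("frequency samples must have day > 0")
    y = (samples["latitude_sampled"] == "S").to_numpy(float)
    if y.min() == y.max():
        warnings.warn("all genotype samples are from one latitude; "
                      "frequency fit is prior-dominated (separation)",
                      stacklevel=2)
    day = samples["day"].to_numpy(float)
    temp = samples["temperature_std"].to_numpy(float)
    X = np.column_stack([day, day * temp])  # deliberately no intercept
    fit = glmm.fit_glmm_laplace(
        X, y, family="binomial", groups=samples["aquarium"].to_numpy(),
        n_draws=inference.n_draws, seed=inference.seed,
        prior_sd_beta=_prior_sds(X, inference),
        allow_degenerate=True,  # separation already warned about above
    )
    effects = dict(zip(fit.group_labels, fit.u))
    return FrequencyModel(
        beta_day=float(fit.beta[0]), beta_day_temp=float(fit.beta[1]),
        aquarium_sd=fit.sigma_group, aquarium_effects=effects,
        draws=fit.beta_draws(),
    )


def partition_densities(census_count: float, freq_model: FrequencyModel | None,
                        day: float, temperature_std: float,
                        aquarium: str | None, composition: str):
    """Split a census count into (Southern, Northern) densities.

    `composition` is "S" or "N" for single-latitude aquaria (the absent
    latitude gets 0) and "SN" for inter-latitudinal pairs, where the
    fitted frequency model supplies the predicted Southern share.  The two
    components always sum exactly to the census count.
    """
    if census_count < 0:
        raise ValueError("census count must be >= 0")
    if composition == "S":
        return float(census_count), 0.0
    if composition == "N":
        return 0.0, float(census_count)
    if composition != "SN":
        raise ValueError(f"unknown composition {composition!r}")
    if freq_model is None:
        raise ValueError("mixed-latitude aquaria need a frequency model")
    p = float(freq_model.p_south(day, temperature_std, aquarium))
    south = census_count * p
    return south, census_count - south


# ---------------------------------------------------------------------------
# preparing individual records for regression
# ---------------------------------------------------------------------------

def prepare_records(
    individuals: pd.DataFrame,
    census: pd.DataFrame,
    design,
    freq_model: FrequencyModel | None = None,
    temperature_scale=DEFAULT_TEMPERATURE_SCALE,
) -> pd.DataFrame:
    """Attach regression covariates to raw individual observation rows.

    Adds z (standardized size), T (standardized temperature), S and A
    (sympatric/allopatric densities from the census at interval start,
    partitioned with the frequency model in mixed-latitude aquaria), the
    latitude indicator L, numeric sex and the clone label.
    """
    aq_info = {a.id: a for a in design.aquaria}
    counts = census.set_index(["aquarium", "day"])["count"]
    df = individuals.copy()
    df["z"] = size_to_z(df["size_t_mm"])
    df["T"] = temperature_scale.to_std(
        df["aquarium"].map(lambda a: aq_info[a].temperature_c))
    df["L"] = (df["latitude"] == "S").astype(float)
    df["sex"] = (df["sex"] == "M").astype(float)
    df["clone"] = df["genotype"]

    S_col, A_col = [], []
    for row in df.itertuples():
        aq = aq_info[row.aquarium]
        total = float(counts.loc[(row.aquarium, row.day)])
        lats = set(aq.latitudes)
        comp = "SN" if lats == {"S", "N"} else lats.pop()
        south, north = partition_densities(
            total, freq_model, row.day, row.T, row.aquarium, comp)
        own_south = row.latitude == "S"
        S_col.append(south if own_south else north)
        A_col.append(north if own_south else south)
    df["S"] = S_col
    df["A"] = A_col
    return df


def fit_all_rates(prepared: pd.DataFrame, structure: str = "select",
                  inference: InferenceConfig | None = None,
                  candidates=STRUCTURE_LABELS) -> ModelSet:
    """Fit all seven vital rates; returns a ModelSet.

    With ``structure="select"`` (default) the structure of each rate is
    chosen by ELPD leave-one-out over `candidates` before the final fit;
    otherwise the given ladder label is used for every rate.
    """
    inference = inference or InferenceConfig()
    models = {}
    for i, rate in enumerate(RATE_NAMES):
        cfg = replace(inference, seed=inference.seed + i)
        frame = rate_frame(prepared, rate)
        if structure == "select":
            label = select_model(frame, rate, candidates, cfg).selected
        else:
            label = structure
        models[rate] = fit_vital_rate(frame, rate, structure=label,
                                      inference=cfg)
    return ModelSet(models)


# ---------------------------------------------------------------------------
# serialization of fitted model sets
# ---------------------------------------------------------------------------

def save_models(models: ModelSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rate, m in models.models.items():
        with open(directory / f"{rate}.json", "w") as fh:
            json.dump(m.to_dict(), fh, indent=1)
        if m.draws is not None:
            cols = list(m.terms)
            frame = pd.DataFrame(m.draws, columns=cols)
            if m.residual_sd_draws is not None:
                frame["residual_sd"] = m.residual_sd_draws
            frame.to_csv(directory / f"{rate}_draws.csv", index=False)


def load_models(directory) -> ModelSet:
    directory = Path(directory)
    models = {}
    for rate in RATE_NAMES:
        with open(directory / f"{rate}.json") as fh:
            spec = json.load(fh)
        draws = resid_draws = None
        draws_path = directory / f"{rate}_draws.csv"
        if draws_path.exists():
            frame = pd.read_csv(draws_path)
            if "residual_sd" in frame.columns:
                resid_draws = frame.pop("residual_sd").to_numpy(float)
            draws = frame.to_numpy(float)
        models[rate] = VitalRateModel.from_dict(spec, draws=draws,
                                                residual_sd_draws=resid_draws)
    return ModelSet(models)
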