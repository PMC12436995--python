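"""Forward simulation of the competition experiment with known truth.

Two layers are provided:

* :func:`simulate_experiment` — a daily-step individual-based simulation of
  every aquarium in a design.  Vital rates are evaluated on the response
  scale each day at the individual's current state (standardized size,
  temperature, same-latitude count S, other-latitude count A, latitude,
  sex).  Interval-level observation rows for the temporarily isolated
  individuals, population censuses, and destructive genotype samples are
  emitted on the census schedule.

* :func:`sample_rate_records` / :func:`sample_frequency_data` — direct
  samplers that draw i.i.d. observation rows from a single vital-rate GLMM
  (or from the genotype-frequency model) at realistic covariate ranges.
  These are the work-horses of the coefficient-recovery suites, where the
  generating law of one regression must be matched exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import ExperimentDesign
from .standardize import (
    DEFAULT_TEMPERATURE_SCALE,
    SIZE_MAX_MM,
    SIZE_MIN_MM,
    size_to_z,
)
from .structures import FAMILIES, RATE_NAMES, SEXED_RATES
from .truth import TrueParameters

DEFAULT_CENSUS_DAYS = (0, 3, 7, 10, 14, 17, 21, 24, 28)
DESTRUCTIVE_FROM_DAY = 14
INTERVAL_MEAN_DAYS = 3.5

RECORD_COLUMNS = [
    "aquarium", "genotype", "latitude", "day", "interval_days", "sex",
    "size_t_mm", "survived", "size_t1_mm", "carried_eggs", "released",
    "clutch_size", "n_female", "n_male", "neonate_size_mm",
]


def _eta(rate_coef: dict[str, float], cov: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorized linear predictor for one rate over individuals."""
    n = len(cov["z"])
    eta = np.zeros(n)
    for term, beta in rate_coef.items():
        if beta == 0.0:
            continue
        if term == "1":
            eta += beta
            continue
        col = np.full(n, beta)
        for factor in term.split(":"):
            col = col * cov[factor]
        eta += col
    return eta


def draw_clone_offsets(truth: TrueParameters, genotype_ids, rng) -> dict:
    """One random intercept per genotype per vital rate."""
    offsets = {}
    for rate in RATE_NAMES:
        sd = truth.rates[rate].clone_sd
        offsets[rate] = {
            g: (rng.normal(0.0, sd) if sd > 0 else 0.0) for g in genotype_ids
        }
    return offsets


@dataclass
class _Population:
    """Mutable per-aquarium state (parallel arrays over live individuals)."""
    size_mm: np.ndarray
    sex: np.ndarray        # 0 female, 1 male
    genotype: np.ndarray   # object array of genotype ids
    latitude: np.ndarray   # "S"/"N"
    isolated_until: np.ndarray  # day until which daily dynamics are frozen
    remove_at: np.ndarray       # day of destructive sampling (-1: never)


def _covariates(pop: _Population, idx, t_std: float) -> dict:
    lat = pop.latitude[idx]
    south = (lat == "S").astype(float)
    n_south = float(np.sum(pop.latitude == "S"))
    n_north = float(len(pop.latitude) - n_south)
    S = np.where(south == 1.0, n_south, n_north)
    A = np.where(south == 1.0, n_north, n_south)
    return {
        "z": size_to_z(pop.size_mm[idx]),
        "T": np.full(len(idx), t_std),
        "S": S,
        "A": A,
        "L": south,
        "sex": pop.sex[idx].astype(float),
    }


def simulate_experiment(
    design: ExperimentDesign,
    truth: TrueParameters,
    n_days: int = 28,
    census_days=DEFAULT_CENSUS_DAYS,
    n_isolated_per_aquarium: int = 2,
    seed: int | None = None,
    temperature_scale=DEFAULT_TEMPERATURE_SCALE,
):
    """Simulate every aquarium; return (records, census, genotype_samples).

    Survival is applied daily as the 3.5th root of the interval-scale
    probability; somatic growth adds a mm/day increment with daily Gaussian
    noise; clutch release is a daily Bernoulli event with probability
    pe*pr/3.5 producing a Poisson clutch whose neonates are sexed
    binomially and sized from the neonate-size model.  Isolated
    individuals' interval observations (survival, per-day growth, egg
    carrying, release, clutch, neonate sex and size) are drawn directly
    from the truth GLMMs at interval-start covariates, and their own fate
    over the interval is forced to match the observation.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    census_days = sorted(int(d) for d in census_days)
    if census_days[0] != 0:
        raise ValueError("census schedule must start at day 0")
    clone_off = draw_clone_offsets(truth, [g.id for g in design.genotypes], rng)

    records: list[dict] = []
    census_rows: list[dict] = []
    sample_rows: list[dict] = []

    for aq in design.aquaria:
        t_std = float(temperature_scale.to_std(aq.temperature_c))
        pop = _init_population(aq, truth, clone_off, rng)
        next_census = {d: census_days[i + 1]
                       for i, d in enumerate(census_days[:-1])}

        for day in range(n_days + 1):
            if day in census_days:
                _record_census(census_rows, aq, day, pop)
                if day < n_days and day in next_census:
                    interval = next_census[day] - day
                    _isolate_and_observe(
                        records, sample_rows, aq, pop, truth, clone_off,
                        day, interval, t_std, n_isolated_per_aquarium, rng,
                    )
            if day < n_days:
                _daily_step(pop, truth, clone_off, day, t_std, rng)

    records_df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    census_df = pd.DataFrame(
        census_rows, columns=["aquarium", "day", "count", "count_south",
                              "count_north"])
    samples_df = pd.DataFrame(
        sample_rows, columns=["aquarium", "day", "latitude_sampled"])
    return records_df, census_df, samples_df


def _init_population(aq, truth, clone_off, rng) -> _Population:
    sizes, sexes, genos, lats = [], [], [], []
    neo = truth.rates["neonate_size"]
    for g_id, lat, n in zip(aq.genotypes, aq.latitudes, aq.founders):
        cov = {"z": 0.0, "T": 0.0, "S": 1.0, "A": 0.0,
               "L": 1.0 if lat == "S" else 0.0, "sex": 0.0}
        mu = neo.linpred(cov) + clone_off["neonate_size"][g_id]
        draw = rng.normal(mu, neo.residual_sd or 0.0, size=n)
        sizes.extend(np.clip(draw, SIZE_MIN_MM, SIZE_MAX_MM))
        sexes.extend([0] * n)  # female founders
        genos.extend([g_id] * n)
        lats.extend([lat] * n)
    n_tot = len(sizes)
    return _Population(
        size_mm=np.asarray(sizes, dtype=float),
        sex=np.asarray(sexes, dtype=int),
        genotype=np.asarray(genos, dtype=object),
        latitude=np.asarray(lats, dtype=object),
        isolated_until=np.full(n_tot, -1, dtype=int),
        remove_at=np.full(n_tot, -1, dtype=int),
    )


def _record_census(rows, aq, day, pop):
    south = int(np.sum(pop.latitude == "S"))
    rows.append({
        "aquarium": aq.id, "day": day, "count": len(pop.size_mm),
        "count_south": south, "count_north": len(pop.size_mm) - south,
    })


def _rate_off(clone_off, rate, genos):
    table = clone_off[rate]
    return np.asarray([table[g] for g in genos])


def _daily_step(pop, truth, clone_off, day, t_std, rng):
    n = len(pop.size_mm)
    if n == 0:
        return
    # destructive removal of sampled individuals
    keep = ~(pop.remove_at == day)
    if not keep.all():
        _filter(pop, keep)
        n = len(pop.size_mm)
        if n == 0:
            return
    free = pop.isolated_until <= day  # individuals with forced fates skip dynamics
    idx = np.arange(n)
    cov = _covariates(pop, idx, t_std)
    genos = pop.genotype

    # survival (interval-scale logit -> daily via 3.5th root)
    p_int = expit(_eta(truth.rates["survival"].coef, cov)
                  + _rate_off(clone_off, "survival", genos))
    p_day = p_int ** (1.0 / INTERVAL_MEAN_DAYS)
    alive = np.where(free, rng.random(n) < p_day, True)

    # somatic growth in mm/day with daily residual noise
    g_truth = truth.rates["growth"]
    inc = (_eta(g_truth.coef, cov) + _rate_off(clone_off, "growth", genos)
           + rng.normal(0.0, g_truth.residual_sd, size=n))
    new_size = np.clip(pop.size_mm + np.where(free, inc, 0.0),
                       SIZE_MIN_MM, SIZE_MAX_MM)

    # reproduction: daily clutch-release events for free females
    females = free & (pop.sex == 0) & alive
    pe = expit(_eta(truth.rates["egg_prob"].coef, cov)
               + _rate_off(clone_off, "egg_prob", genos))
    pr = expit(_eta(truth.rates["release_prob"].coef, cov)
               + _rate_off(clone_off, "release_prob", genos))
    q_day = np.clip(pe * pr / INTERVAL_MEAN_DAYS, 0.0, 1.0)
    releasing = females & (rng.random(n) < q_day)

    neo_sizes, neo_sex, neo_geno, neo_lat = [], [], [], []
    if releasing.any():
        lam = np.exp(_eta(truth.rates["clutch_size"].coef, cov)
                     + _rate_off(clone_off, "clutch_size", genos))
        pf = expit(_eta(truth.rates["female_prob"].coef, cov)
                   + _rate_off(clone_off, "female_prob", genos))
        phi = (_eta(truth.rates["neonate_size"].coef, cov)
               + _rate_off(clone_off, "neonate_size", genos))
        sd_phi = truth.rates["neonate_size"].residual_sd
        for i in np.flatnonzero(releasing):
            k = rng.poisson(lam[i])
            if k == 0:
                continue
            kf = rng.binomial(k, pf[i])
            sizes = np.clip(rng.normal(phi[i], sd_phi, size=k),
                            SIZE_MIN_MM, SIZE_MAX_MM)
            neo_sizes.extend(sizes)
            neo_sex.extend([0] * kf + [1] * (k - kf))
            neo_geno.extend([pop.genotype[i]] * k)
            neo_lat.extend([pop.latitude[i]] * k)

    _filter(pop, alive, new_size)
    if neo_sizes:
        _append(pop, neo_sizes, neo_sex, neo_geno, neo_lat)


def _filter(pop, mask, new_size=None):
    pop.size_mm = (new_size if new_size is not None else pop.size_mm)[mask]
    pop.sex = pop.sex[mask]
    pop.genotype = pop.genotype[mask]
    pop.latitude = pop.latitude[mask]
    pop.isolated_until = pop.isolated_until[mask]
    pop.remove_at = pop.remove_at[mask]


def _append(pop, sizes, sexes, genos, lats):
    k = len(sizes)
    pop.size_mm = np.concatenate([pop.size_mm, np.asarray(sizes, dtype=float)])
    pop.sex = np.concatenate([pop.sex, np.asarray(sexes, dtype=int)])
    pop.genotype = np.concatenate([pop.genotype, np.asarray(genos, dtype=object)])
    pop.latitude = np.concatenate([pop.latitude, np.asarray(lats, dtype=object)])
    pop.isolated_until = np.concatenate([pop.isolated_until,
                                         np.full(k, -1, dtype=int)])
    pop.remove_at = np.concatenate([pop.remove_at, np.full(k, -1, dtype=int)])


def _isolate_and_observe(records, sample_rows, aq, pop, truth, clone_off,
                         day, interval, t_std, n_isolated, rng):
    n = len(pop.size_mm)
    if n == 0:
        return
    chosen = rng.choice(n, size=min(n_isolated, n), replace=False)
    cov = _covariates(pop, chosen, t_std)
    genos = pop.genotype[chosen]

    p_surv = expit(_eta(truth.rates["survival"].coef, cov)
                   + _rate_off(clone_off, "survival", genos))
    survived = rng.random(len(chosen)) < p_surv
    g_truth = truth.rates["growth"]
    growth_day = (_eta(g_truth.coef, cov)
                  + _rate_off(clone_off, "growth", genos)
                  + rng.normal(0.0, g_truth.residual_sd, size=len(chosen)))
    pe = expit(_eta(truth.rates["egg_prob"].coef, cov)
               + _rate_off(clone_off, "egg_prob", genos))
    pr = expit(_eta(truth.rates["release_prob"].coef, cov)
               + _rate_off(clone_off, "release_prob", genos))
    lam = np.exp(_eta(truth.rates["clutch_size"].coef, cov)
                 + _rate_off(clone_off, "clutch_size", genos))
    pf = expit(_eta(truth.rates["female_prob"].coef, cov)
               + _rate_off(clone_off, "female_prob", genos))
    phi = (_eta(truth.rates["neonate_size"].coef, cov)
           + _rate_off(clone_off, "neonate_size", genos))

    for k, i in enumerate(chosen):
        is_female = pop.sex[i] == 0
        row = {
            "aquarium": aq.id,
            "genotype": pop.genotype[i],
            "latitude": pop.latitude[i],
            "day": day,
            "interval_days": interval,
            "sex": "F" if is_female else "M",
            "size_t_mm": round(float(pop.size_mm[i]), 6),
            "survived": int(survived[k]),
            "size_t1_mm": np.nan,
            "carried_eggs": np.nan,
            "released": np.nan,
            "clutch_size": np.nan,
            "n_female": np.nan,
            "n_male": np.nan,
            "neonate_size_mm": np.nan,
        }
        if survived[k]:
            z1 = np.clip(pop.size_mm[i] + interval * growth_day[k],
                         SIZE_MIN_MM, SIZE_MAX_MM)
            row["size_t1_mm"] = round(float(z1), 6)
        if is_female:
            carried = int(rng.random() < pe[k])
            row["carried_eggs"] = carried
            if carried:
                released = int(rng.random() < pr[k])
                row["released"] = released
                if released:
                    clutch = int(rng.poisson(lam[k]))
                    row["clutch_size"] = clutch
                    n_f = int(rng.binomial(clutch, pf[k])) if clutch else 0
                    row["n_female"] = n_f
                    row["n_male"] = clutch - n_f
                    if clutch:
                        sizes = np.clip(
                            rng.normal(phi[k],
                                       truth.rates["neonate_size"].residual_sd,
                                       size=clutch),
                            SIZE_MIN_MM, SIZE_MAX_MM)
                        row["neonate_size_mm"] = round(float(sizes.mean()), 6)
        records.append(row)

        # force the individual's fate to match the observation
        end = day + interval
        pop.isolated_until[i] = end
        if not survived[k]:
            pop.remove_at[i] = end
        else:
            pop.size_mm[i] = row["size_t1_mm"]
            if end >= DESTRUCTIVE_FROM_DAY:
                pop.remove_at[i] = end
                sample_rows.append({
                    "aquarium": aq.id, "day": end,
                    "latitude_sampled": pop.latitude[i],
                })


# ---------------------------------------------------------------------------
# direct samplers for recovery suites
# ---------------------------------------------------------------------------

def sample_rate_records(
    truth: TrueParameters,
    rate: str,
    n: int,
    seed: int,
    temperatures_c=(14.0, 18.0, 22.0, 26.0),
    density_max: float = 450.0,
    monoculture_prob: float = 0.4,
    n_genotypes: int = 12,
    temperature_scale=DEFAULT_TEMPERATURE_SCALE,
) -> pd.DataFrame:
    """Draw `n` i.i.d. rows from one vital-rate GLMM at realistic covariates.

    Returns a frame with the regression covariates (z, T, S, A, L, sex),
    the clone label, the response `y` and, for female probability, the
    binomial `trials` (clutch size drawn from the clutch-size truth).
    """
    if rate not in RATE_NAMES:
        raise ValueError(f"unknown rate {rate!r}")
    rng = np.random.default_rng(seed)
    rt = truth.rates[rate]

    z_lo, z_hi = (-1.0, 2.0) if rate in (
        "release_prob", "clutch_size", "female_prob", "neonate_size"
    ) else (-2.3, 2.0)
    z = rng.uniform(z_lo, z_hi, n)
    t_std = temperature_scale.to_std(rng.choice(temperatures_c, n))
    S = rng.uniform(1.0, density_max, n)
    A = np.where(rng.random(n) < monoculture_prob, 0.0,
                 rng.uniform(1.0, density_max, n))
    clone_idx = rng.integers(0, n_genotypes, n)
    L = (clone_idx < n_genotypes // 2).astype(float)  # first half Southern
    sex = (rng.random(n) < 0.3).astype(float) if rate in SEXED_RATES else np.zeros(n)

    clone_eff = (rng.normal(0.0, rt.clone_sd, n_genotypes)
                 if rt.clone_sd > 0 else np.zeros(n_genotypes))
    cov = {"z": z, "T": t_std, "S": S, "A": A, "L": L, "sex": sex}
    eta = _eta(rt.coef, cov) + clone_eff[clone_idx]

    out = pd.DataFrame({**cov, "clone": [f"C{j}" for j in clone_idx]})
    family = FAMILIES[rate]
    if rate == "female_prob":
        lam = np.exp(_eta(truth.rates["clutch_size"].coef, cov))
        trials = np.maximum(rng.poisson(lam), 1)
        out["trials"] = trials
        out["y"] = rng.binomial(trials, expit(eta))
    elif family == "binomial":
        out["y"] = rng.binomial(1, expit(eta))
    elif family == "poisson":
        out["y"] = rng.poisson(np.exp(eta))
    else:
        out["y"] = rng.normal(eta, rt.residual_sd)
    return out


def sample_frequency_data(
    frequency_truth,
    n: int = 241,
    n_aquaria: int = 36,
    days=(17, 21, 24, 28),
    temperatures_c=(18.0, 22.0, 26.0),
    seed: int = 0,
    temperature_scale=DEFAULT_TEMPERATURE_SCALE,
) -> pd.DataFrame:
    """Draw destructive genotype samples from the frequency-model truth."""
    rng = np.random.default_rng(seed)
    aq_temp = temperature_scale.to_std(
        np.resize(np.asarray(temperatures_c, dtype=float), n_aquaria))
    u = rng.normal(0.0, frequency_truth.aquarium_sd, n_aquaria)
    aq = rng.integers(0, n_aquaria, n)
    day = rng.choice(days, n).astype(float)
    eta = (day * frequency_truth.beta_day + u[aq]
           + day * aq_temp[aq] * frequency_truth.beta_day_temp)
    south = rng.random(n) < expit(eta)
    return pd.DataFrame({
        "aquarium": [f"P{j}" for j in aq],
        "day": day.astype(int),
        "temperature_std": aq_temp[aq],
        "latitude_sampled": np.where(south, "S", "N"),
    })


# ---------------------------------------------------------------------------
# CSV interfaces (empty string encodes structurally missing cells)
# ---------------------------------------------------------------------------

def write_records_csv(records: pd.DataFrame, path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False, na_rep="")


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_census_csv(census: pd.DataFrame, path) -> None:
    census[["aquarium", "day", "count"]].to_csv(path, index=False)


def write_samples_csv(samples: pd.DataFrame, path) -> None:
    samples[["aquarium", "day", "latitude_sampled"]].to_csv(path, index=False)


def records_to_csv_bytes(records: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    write_records_csv(records, buf)
    return buf.getvalue().encode()
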