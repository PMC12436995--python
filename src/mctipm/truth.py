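"""Ground-truth parameterizations for the synthetic experiment generator.

A :class:`TrueParameters` object specifies, for each of the seven vital
rates, the generating GLMM: fixed-effect coefficients on the link scale
(logit for probabilities, log for clutch size, identity for somatic growth
in mm/day and neonate size in mm), a clonal random-intercept SD, and a
residual SD for the Gaussian rates.  It also holds the generating
parameters of the genotype-frequency model (day slope, day x temperature
slope, aquarium random-effect SD).

The default parameterization encodes the qualitative biology the analysis
is designed to detect:

* negative sympatric-density effects on somatic growth, egg-carrying
  probability, clutch size and neonate female probability;
* negative allopatric-density effects on growth and clutch size;
* positive sym- and allopatric effects on neonate size (crowding produces
  fewer, larger neonates);
* temperature-intensified competition (negative T:S and T:A interactions
  in reproduction-related rates), hence lower carrying capacity when warm;
* a latitude x temperature x allopatric-density interaction in neonate
  female probability that reverses which latitude suffers more male
  production from cross-latitude crowding as temperature rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .structures import FAMILIES, RATE_NAMES


@dataclass(frozen=True)
class RateTruth:
    """Generating parameters of one vital-rate GLMM (link scale)."""

    coef: dict[str, float]
    clone_sd: float = 0.0
    residual_sd: float | None = None

    def linpred(self, covariates: dict[str, float]) -> float:
        eta = 0.0
        for term, beta in self.coef.items():
            if term == "1":
                eta += beta
                continue
            prod = beta
            for factor in term.split(":"):
                prod *= covariates[factor]
            eta += prod
        return eta


@dataclass(frozen=True)
class FrequencyTruth:
    """Generating parameters of the genotype-frequency model (no intercept)."""

    beta_day: float = 0.01
    beta_day_temp: float = 0.03
    aquarium_sd: float = 0.5


@dataclass(frozen=True)
class TrueParameters:
    rates: dict[str, RateTruth]
    frequency: FrequencyTruth = field(default_factory=FrequencyTruth)

    def __post_init__(self):
        missing = set(RATE_NAMES) - set(self.rates)
        if missing:
            raise ValueError(f"truth missing rates: {sorted(missing)}")
        for name, rt in self.rates.items():
            if FAMILIES[name] == "gaussian" and rt.residual_sd is None:
                raise ValueError(f"gaussian rate {name!r} needs residual_sd")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        out = {"rates": {}, "frequency": vars(self.frequency).copy()}
        for name, rt in self.rates.items():
            out["rates"][name] = {
                "coef": dict(rt.coef),
                "clone_sd": rt.clone_sd,
                "residual_sd": rt.residual_sd,
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParameters":
        rates = {
            name: RateTruth(
                coef=dict(spec["coef"]),
                clone_sd=float(spec.get("clone_sd", 0.0)),
                residual_sd=spec.get("residual_sd"),
            )
            for name, spec in d["rates"].items()
        }
        return cls(rates=rates, frequency=FrequencyTruth(**d.get("frequency", {})))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TrueParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_truth() -> TrueParameters:
    """Default generating parameters (see module docstring for rationale)."""
    rates = {
        "survival": RateTruth(
            coef={
                "1": 2.2, "z": 0.5, "T": -0.25, "S": -0.0003, "A": -0.0002,
                "L": 0.0, "sex": -0.3, "T:S": -0.0001, "T:A": -0.00005,
            },
            clone_sd=0.15,
        ),
        "growth": RateTruth(
            coef={
                "1": 0.16, "z": -0.05, "T": 0.012, "S": -0.00008,
                "A": -0.00005, "L": 0.004, "sex": -0.01,
                "T:S": -0.00003, "T:A": -0.00002,
            },
            clone_sd=0.006,
            residual_sd=0.035,
        ),
        "egg_prob": RateTruth(
            coef={
                "1": 1.7, "z": 2.2, "T": 0.15, "S": -0.0012, "A": -0.00054,
                "L": 0.15, "L:T": 0.6, "T:S": -0.0003, "T:A": -0.00015,
            },
            clone_sd=0.2,
        ),
        "release_prob": RateTruth(
            coef={
                "1": 2.0, "z": 0.3, "T": 0.3, "S": -0.001, "A": -0.0006,
                "L": 0.0,
            },
            clone_sd=0.2,
        ),
        "clutch_size": RateTruth(
            coef={
                "1": 2.3, "z": 0.45, "T": 0.08, "S": -0.018, "A": -0.0081,
                "L": 0.07, "L:T": 0.35, "T:S": -0.0014, "T:A": -0.00063,
            },
            clone_sd=0.1,
        ),
        "female_prob": RateTruth(
            coef={
                "1": 3.3, "z": 0.1, "T": -0.1, "S": -0.0045, "A": -0.0045,
                "L": 0.0, "L:A": -0.003, "T:A": -0.00525, "T:L:A": 0.00975,
            },
            clone_sd=0.2,
        ),
        "neonate_size": RateTruth(
            coef={
                "1": 0.62, "z": 0.05, "T": -0.015, "S": 0.0003, "A": 0.0002,
                "L": 0.01,
            },
            clone_sd=0.01,
            residual_sd=0.055,
        ),
    }
    return TrueParameters(rates=rates)


def _strip_latitude(rt: RateTruth) -> RateTruth:
    coef = {t: (0.0 if "L" in t.split(":") else b) for t, b in rt.coef.items()}
    return replace(rt, coef=coef)


def identical_latitudes_truth() -> TrueParameters:
    """Default truth with every latitude-dependent term zeroed."""
    base = default_truth()
    return TrueParameters(
        rates={name: _strip_latitude(rt) for name, rt in base.rates.items()},
        frequency=FrequencyTruth(beta_day=0.0, beta_day_temp=0.0,
                                 aquarium_sd=base.frequency.aquarium_sd),
    )


def female_prob_latitude_truth() -> TrueParameters:
    """Latitudes identical except neonate female probability.

    Only the female-probability rate carries latitude terms, via the
    L:A and T:L:A interactions of the default truth.  Used to probe the
    decomposition machinery: the entire between-latitude difference must
    be attributed to this single rate, with a temperature-dependent sign.
    """
    sym = identical_latitudes_truth()
    fp = default_truth().rates["female_prob"]
    rates = dict(sym.rates)
    rates["female_prob"] = fp
    return TrueParameters(rates=rates, frequency=sym.frequency)
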