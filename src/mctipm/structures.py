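"""Fixed-effect structures for the seven vital-rate regressions.

Candidate structures form a nested ladder from a purely additive model to a
model with three-way latitude x temperature x density interactions:

* M1: intercept + z + T + S + A + L (+ sex for survival and somatic growth)
* M2: M1 + T:S + T:A
* M3: M2 + L:S + L:A
* M4: M3 + L:T
* M5: M4 + T:L:S + T:L:A   (14, or 15 with sex, fixed effects)

Covariate coding: z standardized body size, T standardized temperature,
S/A sympatric/allopatric densities as raw counts, L an indicator that is 1
for Southern and 0 for Northern lineages, sex an indicator that is 1 for
males.  Interaction columns are plain products of these codes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RATE_NAMES = (
    "survival",
    "growth",
    "egg_prob",
    "release_prob",
    "clutch_size",
    "female_prob",
    "neonate_size",
)

#: rates whose regressions include a sex effect (reproduction is female-only)
SEXED_RATES = ("survival", "growth")

FAMILIES = {
    "survival": "binomial",
    "growth": "gaussian",
    "egg_prob": "binomial",
    "release_prob": "binomial",
    "clutch_size": "poisson",
    "female_prob": "binomial",
    "neonate_size": "gaussian",
}

_BASE_TERMS = ("1", "z", "T", "S", "A", "L")
_LADDER_EXTRAS = {
    "M1": (),
    "M2": ("T:S", "T:A"),
    "M3": ("T:S", "T:A", "L:S", "L:A"),
    "M4": ("T:S", "T:A", "L:S", "L:A", "L:T"),
    "M5": ("T:S", "T:A", "L:S", "L:A", "L:T", "T:L:S", "T:L:A"),
}

STRUCTURE_LABELS = tuple(_LADDER_EXTRAS)


def structure_terms(label: str, rate: str) -> tuple[str, ...]:
    """Ordered fixed-effect terms for ladder structure `label` and a rate."""
    if label not in _LADDER_EXTRAS:
        raise ValueError(f"unknown structure {label!r}; choose from {STRUCTURE_LABELS}")
    if rate not in RATE_NAMES:
        raise ValueError(f"unknown rate {rate!r}; choose from {RATE_NAMES}")
    terms = list(_BASE_TERMS)
    if rate in SEXED_RATES:
        terms.append("sex")
    terms.extend(_LADDER_EXTRAS[label])
    return tuple(terms)


def term_column(term: str, df: pd.DataFrame) -> np.ndarray:
    """Evaluate one term (e.g. ``"T:L:A"``) on a covariate frame."""
    n = len(df)
    if term == "1":
        return np.ones(n)
    col = np.ones(n)
    for factor in term.split(":"):
        if factor not in df.columns:
            raise KeyError(f"covariate column {factor!r} missing for term {term!r}")
        col = col * df[factor].to_numpy(dtype=float)
    return col


def design_matrix(terms, df: pd.DataFrame) -> np.ndarray:
    """Stack term columns into an (n, p) design matrix."""
    return np.column_stack([term_column(t, df) for t in terms])
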