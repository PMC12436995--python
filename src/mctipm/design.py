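"""Experimental design generation: genotype catalogue and aquarium layout.

The design mirrors a two-latitude competition experiment: every genotype
is grown alone (12 founders) at each monoculture temperature, and every
unordered genotype pair is grown once (6 + 6 founders) at a competition
temperature, pairs being stratified randomly across the competition
temperatures.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

MONO_FOUNDERS = 12
PAIR_FOUNDERS = 6  # per genotype in a two-genotype aquarium


class InvalidDesignError(ValueError):
    pass


@dataclass(frozen=True)
class Genotype:
    id: str
    latitude: str  # "S" or "N"
    pond: str


@dataclass(frozen=True)
class AquariumSpec:
    id: str
    temperature_c: float
    genotypes: tuple[str, ...]          # 1 (monoculture) or 2 (pair)
    latitudes: tuple[str, ...]          # parallel to `genotypes`
    founders: tuple[int, ...]           # per genotype

    @property
    def is_monoculture(self) -> bool:
        return len(self.genotypes) == 1

    @property
    def is_interlatitudinal(self) -> bool:
        return len(set(self.latitudes)) == 2


@dataclass(frozen=True)
class ExperimentDesign:
    genotypes: tuple[Genotype, ...]
    aquaria: tuple[AquariumSpec, ...]
    seed: int = 0

    def counts(self) -> dict[str, int]:
        mono = sum(a.is_monoculture for a in self.aquaria)
        pairs = [a for a in self.aquaria if not a.is_monoculture]
        inter = sum(a.is_interlatitudinal for a in pairs)
        return {
            "n_aquaria": len(self.aquaria),
            "n_monoculture": mono,
            "n_competition": len(pairs),
            "n_interlatitudinal": inter,
            "n_intralatitudinal": len(pairs) - inter,
        }

    def latitude_of(self, genotype_id: str) -> str:
        for g in self.genotypes:
            if g.id == genotype_id:
                return g.latitude
        raise KeyError(genotype_id)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genotypes": [vars(g).copy() for g in self.genotypes],
            "aquaria": [
                {
                    "id": a.id,
                    "temperature_c": a.temperature_c,
                    "genotypes": list(a.genotypes),
                    "latitudes": list(a.latitudes),
                    "founders": list(a.founders),
                }
                for a in self.aquaria
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            genotypes=tuple(Genotype(**g) for g in d["genotypes"]),
            aquaria=tuple(
                AquariumSpec(
                    id=a["id"],
                    temperature_c=float(a["temperature_c"]),
                    genotypes=tuple(a["genotypes"]),
                    latitudes=tuple(a["latitudes"]),
                    founders=tuple(int(f) for f in a["founders"]),
                )
                for a in d["aquaria"]
            ),
            seed=int(d.get("seed", 0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def make_catalogue(n_ponds_per_latitude: int,
                   n_genotypes_per_pond: int) -> tuple[Genotype, ...]:
    genotypes = []
    for lat in ("S", "N"):
        idx = 1
        for pond in range(1, n_ponds_per_latitude + 1):
            for _ in range(n_genotypes_per_pond):
                genotypes.append(
                    Genotype(id=f"{lat}{idx}", latitude=lat, pond=f"{lat}P{pond}")
                )
                idx += 1
    return tuple(genotypes)


def generate_design(
    n_ponds_per_latitude: int = 2,
    n_genotypes_per_pond: int = 3,
    mono_temperatures=(14.0, 18.0, 22.0, 26.0),
    competition_temperatures=(18.0, 22.0, 26.0),
    seed: int = 0,
) -> ExperimentDesign:
    """Build the aquarium layout.

    Monocultures: every genotype at every monoculture temperature with 12
    founders.  Competition: every unordered genotype pair once, 6 + 6
    founders, stratified randomly (seeded) across the competition
    temperatures.  The reference layout (2 ponds/latitude, 3
    genotypes/pond, 4 mono and 3 competition temperatures) yields 48
    monocultures + 66 pairs = 114 aquaria, the pairs splitting into 36
    inter- and 30 intra-latitudinal combinations.
    """
    if n_ponds_per_latitude < 1 or n_genotypes_per_pond < 1:
        raise InvalidDesignError("empty genotype catalogue")
    if not len(mono_temperatures) or not len(competition_temperatures):
        raise InvalidDesignError("temperature lists must be non-empty")

    catalogue = make_catalogue(n_ponds_per_latitude, n_genotypes_per_pond)
    rng = np.random.default_rng(seed)
    aquaria: list[AquariumSpec] = []

    for temp in mono_temperatures:
        for g in catalogue:
            aquaria.append(
                AquariumSpec(
                    id=f"M_{g.id}_{temp:g}C",
                    temperature_c=float(temp),
                    genotypes=(g.id,),
                    latitudes=(g.latitude,),
                    founders=(MONO_FOUNDERS,),
                )
            )

    pairs = list(itertools.combinations(catalogue, 2))
    order = rng.permutation(len(pairs))
    temps = np.asarray(competition_temperatures, dtype=float)
    # balanced stratification: temperature block sizes differ by at most 1
    assignment = np.resize(temps, len(pairs))
    for k, pair_idx in enumerate(order):
        g1, g2 = pairs[pair_idx]
        temp = float(assignment[k])
        aquaria.append(
            AquariumSpec(
                id=f"P_{g1.id}x{g2.id}_{temp:g}C",
                temperature_c=temp,
                genotypes=(g1.id, g2.id),
                latitudes=(g1.latitude, g2.latitude),
                founders=(PAIR_FOUNDERS, PAIR_FOUNDERS),
            )
        )

    return ExperimentDesign(genotypes=catalogue, aquaria=tuple(aquaria), seed=seed)
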