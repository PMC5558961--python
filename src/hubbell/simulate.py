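"""Sequential urn sampler for neutral local communities.

Generates the artificial communities used as the null datasets of the exact
neutrality test.  The scheme is the two-stage genealogy construction whose
stationary sampling distribution is the Etienne formula: individuals arrive
one at a time; individual j founds a new immigrant lineage with probability
I / (I + j - 1), otherwise it copies a uniformly chosen earlier individual.
Each new immigrant lineage draws its species from a Chinese-restaurant
process over lineages with concentration theta (a-th lineage starts a new
species with probability theta / (theta + a - 1), else adopts the species of
a uniformly chosen earlier lineage).  With I = +inf every individual is an
immigrant and the sampler reduces to the plain Ewens/CRP scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .otu_io import AbundanceConfiguration, Treatment

__all__ = ["SimulationSpec", "simulate_local_community", "simulate_batch"]


@dataclass
class SimulationSpec:
    """Batch description: parameters (theta, I, J), replicate count and seed."""

    theta: float
    I: float  # +inf means no dispersal limitation (m = 1)
    J: int
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if not self.I > 0:
            raise ValueError(f"I must be positive, got {self.I}")
        if self.J < 1:
            raise ValueError(f"J must be >= 1, got {self.J}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")


def simulate_local_community(
    theta: float,
    I: float,
    J: int,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> AbundanceConfiguration:
    """Draw one neutral local community of J individuals at (theta, I)."""
    if theta <= 0 or not I > 0 or J < 1:
        raise ValueError("need theta > 0, I > 0, J >= 1")
    pure_ewens = math.isinf(I)

    species_of_ind = np.empty(J, dtype=np.int64)   # species label per individual
    species_of_lineage: list[int] = []             # species label per immigrant lineage
    n_species = 0

    # pre-draw the per-individual uniforms; ancestors are drawn lazily because
    # their range depends on the current count
    u_immigrant = rng.random(J)
    u_new_species = rng.random(J)

    for j in range(J):
        immigrant = True if pure_ewens or j == 0 else (
            u_immigrant[j] < I / (I + j)
        )
        if immigrant:
            a = len(species_of_lineage)  # lineages before this one
            if a == 0 or u_new_species[j] < theta / (theta + a):
                sp = n_species
                n_species += 1
            else:
                sp = species_of_lineage[int(rng.integers(a))]
            species_of_lineage.append(sp)
            species_of_ind[j] = sp
        else:
            species_of_ind[j] = species_of_ind[int(rng.integers(j))]

    abundances = np.bincount(species_of_ind, minlength=n_species)
    return AbundanceConfiguration(
        sample_id=sample_id, abundances=abundances, treatment=Treatment.OTHER
    )


def simulate_batch(spec: SimulationSpec) -> list[AbundanceConfiguration]:
    """Simulate ``spec.n_reps`` independent communities.

    Each replicate gets its own RNG stream derived from (seed, replicate
    index), so results are reproducible and independent of execution order.
    """
    out = []
    for rep in range(spec.n_reps):
        rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, rep])
        out.append(
            simulate_local_community(
                spec.theta, spec.I, spec.J, rng, sample_id=f"sim{rep}"
            )
        )
    return out
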