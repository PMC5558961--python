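"""Study-shaped synthetic fixtures: a mixture of neutral and niche communities.

Generates OTU tables shaped like a 61-sample subgingival plaque study —
three treatments (Healthy n=17, BoP n=22, NonBoP n=22), per-sample read
depths of a few hundred to a few thousand, richness in the tens to low
hundreds — in which a known fraction of samples is assembled neutrally (urn
sampler at a drawn (theta, m)) and the rest by a niche-structured generator
(lognormal or geometric relative abundances, multinomially sampled).  A
truth table records each sample's generator and parameters so downstream
tests can score the neutrality test against ground truth.

Defaults: read depths uniform on 500-4000 (the study range runs to ~10000;
``paper_scale`` lifts the cap), theta centred near 15 for healthy and 27 for
periodontitis samples (mirroring the observed healthy-vs-disease diversity
contrast), m in 0.8-0.9999, and a neutral fraction of 0.25, near the
observed ~23% neutrality passing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .otu_io import AbundanceConfiguration, OTUTable, Treatment
from .simulate import simulate_local_community

__all__ = ["FixtureSpec", "make_fixture", "niche_community", "write_fixture"]

_METACOMMUNITY_OTUS = 673  # OTU pool size matching the study's global table


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study."""

    n_per_treatment: dict[Treatment, int] = field(
        default_factory=lambda: {
            Treatment.HEALTHY: 17,
            Treatment.BOP: 22,
            Treatment.NON_BOP: 22,
        }
    )
    J_range: tuple[int, int] = (500, 4000)
    theta_by_treatment: dict[Treatment, tuple[float, float]] = field(
        default_factory=lambda: {
            Treatment.HEALTHY: (15.0, 5.0),
            Treatment.BOP: (27.0, 6.0),
            Treatment.NON_BOP: (27.0, 6.0),
        }
    )
    m_range: tuple[float, float] = (0.8, 0.9999)
    neutral_fraction: float = 0.25
    niche_model: Literal["lognormal", "geometric"] = "lognormal"
    lognormal_sigma: float = 2.0
    geometric_ratio: float = 0.3
    S_range: tuple[int, int] = (30, 165)  # niche-community richness pool
    seed: int = 0
    paper_scale: bool = False  # lift the read-depth cap to the study maximum

    def __post_init__(self) -> None:
        if not 0 <= self.neutral_fraction <= 1:
            raise ValueError("neutral_fraction must be in [0, 1]")
        if self.J_range[0] > self.J_range[1] or self.J_range[0] < 1:
            raise ValueError("invalid J_range")
        if self.paper_scale:
            self.J_range = (min(self.J_range[0], 591), 10130)


def niche_community(
    model: Literal["lognormal", "geometric"],
    params: dict,
    J: int,
    rng: np.random.Generator,
    sample_id: str = "niche",
) -> AbundanceConfiguration:
    """Draw a niche-structured community of J reads.

    lognormal: S* latent relative abundances exp(sigma * Z), normalised, then
    J reads multinomially sampled and zero species dropped.  geometric:
    relative abundances proportional to r^(i-1) for i = 1..S*.
    """
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    S_star = int(params.get("S_star", 50))
    if model == "lognormal":
        sigma = float(params.get("sigma", 2.0))
        w = np.exp(sigma * rng.standard_normal(S_star))
    elif model == "geometric":
        r = float(params.get("ratio", 0.3))
        w = r ** np.arange(S_star, dtype=float)
    else:
        raise ValueError(f"unknown niche model {model!r}")
    p = w / w.sum()
    counts = rng.multinomial(J, p)
    return AbundanceConfiguration.from_counts(sample_id, counts)


def make_fixture(
    spec: FixtureSpec,
) -> tuple[OTUTable, dict[str, Treatment], pd.DataFrame]:
    """Generate (OTU table, treatment map, truth table) for one synthetic study.

    Deterministic under ``spec.seed``.  The truth table has one row per
    sample: generator ("neutral" or the niche model), true theta and m for
    neutral samples, J and S actually realised.
    """
    rng = np.random.default_rng(int(spec.seed) & 0x7FFFFFFF)
    # metacommunity OTU pool with lognormal weights, used only to map each
    # sample's anonymous species onto shared OTU column labels
    pool_w = np.exp(1.5 * rng.standard_normal(_METACOMMUNITY_OTUS))
    pool_w /= pool_w.sum()

    prefix = {Treatment.HEALTHY: "H", Treatment.BOP: "PB", Treatment.NON_BOP: "PnB"}
    configs: list[AbundanceConfiguration] = []
    truth_rows: list[dict] = []
    treatments: dict[str, Treatment] = {}

    for trt, n in spec.n_per_treatment.items():
        for i in range(n):
            sid = f"{i + 1}{prefix.get(trt, trt.value)}"
            J = int(rng.integers(spec.J_range[0], spec.J_range[1] + 1))
            neutral = bool(rng.random() < spec.neutral_fraction)
            if neutral:
                mu, sd = spec.theta_by_treatment[trt]
                theta = max(0.5, float(rng.normal(mu, sd)))
                m = float(rng.uniform(*spec.m_range))
                I = m * (J - 1) / (1.0 - m)
                cfg = simulate_local_community(theta, I, J, rng, sample_id=sid)
                row = dict(sample_id=sid, generator="neutral",
                           true_theta=theta, true_m=m)
            else:
                S_star = int(rng.integers(spec.S_range[0], spec.S_range[1] + 1))
                params = (
                    {"S_star": S_star, "sigma": spec.lognormal_sigma}
                    if spec.niche_model == "lognormal"
                    else {"S_star": S_star, "ratio": spec.geometric_ratio}
                )
                cfg = niche_community(spec.niche_model, params, J, rng, sample_id=sid)
                row = dict(sample_id=sid, generator=spec.niche_model,
                           true_theta=np.nan, true_m=np.nan)
            cfg.treatment = trt
            configs.append(cfg)
            treatments[sid] = trt
            row.update(treatment=trt.value, J=cfg.J, S=cfg.S)
            truth_rows.append(row)

    table = _configs_to_table(configs, pool_w, rng)
    truth = pd.DataFrame(truth_rows)[
        ["sample_id", "treatment", "generator", "true_theta", "true_m", "J", "S"]
    ]
    return table, treatments, truth


def _configs_to_table(
    configs: list[AbundanceConfiguration],
    pool_w: np.ndarray,
    rng: np.random.Generator,
) -> OTUTable:
    """Assign each sample's species to shared OTU columns (weighted, no
    replacement within a sample) and assemble the counts matrix."""
    n_otus = len(pool_w)
    counts = np.zeros((len(configs), n_otus), dtype=np.int64)
    for row, cfg in enumerate(configs):
        if cfg.S > n_otus:
            raise ValueError("sample richer than the OTU pool")
        otus = rng.choice(n_otus, size=cfg.S, replace=False, p=pool_w)
        counts[row, otus] = cfg.abundances
    keep = counts.sum(axis=0) > 0
    taxon_ids = [f"Otu{i + 1:04d}" for i in range(n_otus)]
    return OTUTable(
        sample_ids=[c.sample_id for c in configs],
        taxon_ids=[t for t, k in zip(taxon_ids, keep) if k],
        counts=counts[:, keep],
    )


def write_fixture(
    spec: FixtureSpec,
    outdir: str | Path,
) -> tuple[Path, Path, Path]:
    """Materialise a fixture as mothur-shared + treatment TSV + truth TSV."""
    from .otu_io import write_otu_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, treatments, truth = make_fixture(spec)
    shared = outdir / "fixture.shared"
    tmap = outdir / "treatments.tsv"
    tfile = outdir / "truth.tsv"
    write_otu_table(table, shared, format="shared")
    with open(tmap, "w") as fh:
        fh.write("sample_id\ttreatment\n")
        for sid, trt in treatments.items():
            fh.write(f"{sid}\t{trt.value}\n")
    truth.to_csv(tfile, sep="\t", index=False)
    return shared, tmap, tfile
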