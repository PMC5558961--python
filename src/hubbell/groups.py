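"""Treatment-level statistics: passing-rate contingency tests and theta ANOVA.

Per-treatment neutrality passing rates are compared pairwise with Fisher's
exact probability test (two-sided, point-probability rule), and the fitted
fundamental biodiversity numbers are compared across treatments with one-way
ANOVA followed by Bonferroni-adjusted pairwise pooled-variance t-tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .etienne import EtienneFit
from .ewens import EwensFit
from .neutrality import NeutralityVerdict
from .otu_io import Treatment

logger = logging.getLogger(__name__)

__all__ = [
    "FourfoldTable",
    "TreatmentSummary",
    "GroupComparison",
    "fisher_exact_2x2",
    "passing_rate_table",
    "theta_group_comparison",
]


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 contingency table: rows = treatments, cols = (pass, fail)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero fourfold table")


def fisher_exact_2x2(t: FourfoldTable) -> float:
    """Two-sided Fisher exact p by the point-probability rule.

    With margins fixed, the first cell follows a hypergeometric distribution;
    the p-value sums the probabilities of every table whose point probability
    does not exceed that of the observed table (relative tolerance 1e-7 on
    the comparison).  This is the rule used by R's fisher.test, and yields
    p = 1 exactly when the observed cell is the hypergeometric mode.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n1, n2, k = a + b, c + d, a + c  # row margins, first-column margin
    N = n1 + n2
    dist = stats.hypergeom(N, n1, k)
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass
class TreatmentSummary:
    """Per-treatment neutrality passing counts and theta summary."""

    treatment: Treatment
    n_samples: int
    n_pass: int
    mean_theta: float
    sd_theta: float

    @property
    def pass_rate(self) -> float:
        return self.n_pass / self.n_samples


def passing_rate_table(
    verdicts: Sequence[NeutralityVerdict],
    treatments: Mapping[str, Treatment],
) -> tuple[list[TreatmentSummary], dict[tuple[str, str], float]]:
    """Per-treatment pass counts/rates and all pairwise Fisher p-values.

    Samples mapped to OTHER (or missing from the map) are excluded from the
    group comparison but counted nowhere else silently: a warning is logged.
    """
    groups: dict[Treatment, list[NeutralityVerdict]] = {}
    for v in verdicts:
        trt = treatments.get(v.sample_id, Treatment.OTHER)
        if trt is Treatment.OTHER:
            logger.warning("sample %r has no treatment; excluded from group stats",
                           v.sample_id)
            continue
        groups.setdefault(trt, []).append(v)

    thetas = {
        trt: np.array([v.theta for v in vs if math.isfinite(v.theta)])
        for trt, vs in groups.items()
    }
    summaries = [
        TreatmentSummary(
            treatment=trt,
            n_samples=len(vs),
            n_pass=sum(v.passes for v in vs),
            mean_theta=float(np.mean(thetas[trt])) if thetas[trt].size else float("nan"),
            sd_theta=float(np.std(thetas[trt], ddof=1)) if thetas[trt].size > 1 else float("nan"),
        )
        for trt, vs in groups.items()
    ]
    summaries.sort(key=lambda s: s.treatment.value)

    pairwise: dict[tuple[str, str], float] = {}
    for s1, s2 in combinations(summaries, 2):
        if s1.n_samples == 0 or s2.n_samples == 0:
            logger.warning("empty treatment in pair (%s, %s); skipped",
                           s1.treatment.value, s2.treatment.value)
            continue
        table = FourfoldTable(
            a=s1.n_pass, b=s1.n_samples - s1.n_pass,
            c=s2.n_pass, d=s2.n_samples - s2.n_pass,
        )
        pairwise[(s1.treatment.value, s2.treatment.value)] = fisher_exact_2x2(table)
    return summaries, pairwise


@dataclass
class GroupComparison:
    """One-way ANOVA of theta across treatments plus Bonferroni pairwise tests."""

    anova_F: float
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni-adjusted
    group_means: dict[str, float]
    group_ns: dict[str, int]


def theta_group_comparison(
    fits: Sequence[EtienneFit | EwensFit],
    treatments: Mapping[str, Treatment],
) -> GroupComparison:
    """Compare mean theta across treatments.

    Uses one-way fixed-effects ANOVA on the raw theta values, then pairwise
    two-sample pooled-variance t-tests with the p-values multiplied by the
    number of pairs (Bonferroni) and capped at 1.  Fits with non-finite theta
    (degenerate boundary estimates) are excluded with a warning; a pair is
    skipped when either group has fewer than 2 usable samples.
    """
    groups: dict[Treatment, list[float]] = {}
    for f in fits:
        trt = treatments.get(f.sample_id, Treatment.OTHER)
        if trt is Treatment.OTHER:
            continue
        if not math.isfinite(f.theta) or f.theta <= 0:
            logger.warning("sample %r: degenerate theta, excluded from ANOVA",
                           f.sample_id)
            continue
        groups.setdefault(trt, []).append(f.theta)

    usable = {t: np.array(v) for t, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 treatments with >= 2 samples each")
    names = sorted(usable, key=lambda t: t.value)
    arrays = [usable[t] for t in names]
    if np.ptp(np.concatenate(arrays)) == 0:
        F, p = 0.0, 1.0  # identical values everywhere: no between-group signal
    else:
        F, p = stats.f_oneway(*arrays)

    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for t1, t2 in combinations(names, 2):
        _, raw = stats.ttest_ind(usable[t1], usable[t2], equal_var=True)
        pairwise[(t1.value, t2.value)] = min(1.0, float(raw) * n_pairs)
    return GroupComparison(
        anova_F=float(F),
        anova_p=float(p),
        pairwise_p=pairwise,
        group_means={t.value: float(np.mean(usable[t])) for t in names},
        group_ns={t.value: int(usable[t].size) for t in names},
    )
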