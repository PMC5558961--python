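"""Reading OTU tables and turning them into per-sample abundance configurations.

Two input dialects are supported: the mothur ``.shared`` format (tab-separated
with ``label``/``Group``/``numOtus`` columns, samples as rows) and plain TSV
with a header row of taxon ids (samples as rows by default, columns with
``samples_in="cols"``).  Downstream likelihood code never sees the table
itself, only :class:`AbundanceConfiguration` objects: one sample's species
abundance distribution with its derived summaries (J, S, frequency-of-
frequencies phi).
"""

from __future__ import annotations

import enum
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Treatment",
    "OTUTable",
    "AbundanceConfiguration",
    "OTUParseError",
    "read_otu_table",
    "write_otu_table",
    "read_treatment_map",
    "to_configurations",
    "rank_abundance",
    "write_configurations",
    "write_rank_abundance",
]


class Treatment(enum.Enum):
    """Clinical treatment group of a subgingival plaque sample.

    ``BOP`` = periodontitis site with bleeding on probing, ``NON_BOP`` =
    periodontitis site without bleeding, ``HEALTHY`` = control.  Labels not
    recognised map to ``OTHER``; such samples are still individually testable
    but are excluded from group-level statistics.
    """

    HEALTHY = "Healthy"
    BOP = "BoP"
    NON_BOP = "NonBoP"
    OTHER = "Other"

    @classmethod
    def parse(cls, label: str) -> "Treatment":
        key = str(label).strip().lower().replace("-", "").replace("_", "").replace(" ", "")
        aliases = {
            "healthy": cls.HEALTHY,
            "control": cls.HEALTHY,
            "h": cls.HEALTHY,
            "bop": cls.BOP,
            "pb": cls.BOP,
            "nonbop": cls.NON_BOP,
            "nobop": cls.NON_BOP,
            "pnb": cls.NON_BOP,
        }
        return aliases.get(key, cls.OTHER)


class OTUParseError(ValueError):
    """Raised when an OTU table or treatment map cannot be parsed."""


@dataclass
class OTUTable:
    """Counts matrix (samples x taxa) with row/column identifiers."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # int matrix, shape (n_samples, n_taxa)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts in OTU table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class AbundanceConfiguration:
    """One sample's species abundance distribution.

    ``abundances`` holds the positive per-species counts sorted descending
    (n_1 >= n_2 >= ... >= n_S >= 1); ``J`` is the number of reads
    (individuals), ``S`` the number of species, and ``phi`` the frequency of
    frequencies: phi[a] = number of species observed with abundance exactly a.
    Invariants sum(a * phi[a]) == J and sum(phi.values()) == S hold by
    construction.
    """

    sample_id: str
    abundances: np.ndarray
    treatment: Treatment = Treatment.OTHER
    J: int = field(init=False)
    S: int = field(init=False)
    phi: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=np.int64)
        if ab.size == 0:
            raise ValueError(f"sample {self.sample_id!r}: empty abundance vector")
        if (ab < 1).any():
            raise ValueError(f"sample {self.sample_id!r}: abundances must be >= 1")
        self.abundances = np.sort(ab)[::-1]
        self.J = int(self.abundances.sum())
        self.S = int(self.abundances.size)
        self.phi = dict(sorted(Counter(self.abundances.tolist()).items()))

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        counts: Iterable[int],
        treatment: Treatment = Treatment.OTHER,
    ) -> "AbundanceConfiguration":
        """Build from raw per-taxon counts, dropping zeros."""
        arr = np.asarray(list(counts), dtype=np.int64)
        if (arr < 0).any():
            raise ValueError(f"sample {sample_id!r}: negative counts")
        return cls(sample_id=sample_id, abundances=arr[arr > 0], treatment=treatment)


# ---------------------------------------------------------------------------
# readers / writers


def read_otu_table(
    path: str | Path,
    format: str = "tsv",
    samples_in: str = "rows",
) -> OTUTable:
    """Read an OTU table from ``path``.

    format="shared"
        mothur shared file: tab-separated, columns label / Group / numOtus
        followed by one column per OTU; sample ids come from the Group column.
    format="tsv"
        plain TSV with a header row of taxon ids and a leading id column;
        ``samples_in`` selects whether samples are rows (default) or columns.
    """
    path = Path(path)
    if format not in ("shared", "tsv"):
        raise ValueError(f"unknown OTU table format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise OTUParseError(f"{path}: cannot parse as TSV: {exc}") from exc

    if format == "shared":
        expected = ["label", "Group", "numOtus"]
        lowered = [c.lower() for c in df.columns[:3]]
        if lowered != [c.lower() for c in expected]:
            raise OTUParseError(
                f"{path}: line 1: mothur shared header must start with "
                f"label/Group/numOtus, got {list(df.columns[:3])}"
            )
        sample_ids = df.iloc[:, 1].astype(str).tolist()
        taxon_ids = list(df.columns[3:])
        body = df.iloc[:, 3:]
    else:
        sample_ids = df.iloc[:, 0].astype(str).tolist()
        taxon_ids = list(df.columns[1:])
        body = df.iloc[:, 1:]

    counts = _parse_count_block(body, path)
    if samples_in == "cols" and format == "tsv":
        counts = counts.T
        sample_ids, taxon_ids = taxon_ids, sample_ids
    elif samples_in not in ("rows", "cols"):
        raise ValueError(f"samples_in must be 'rows' or 'cols', got {samples_in!r}")

    try:
        return OTUTable(sample_ids=sample_ids, taxon_ids=taxon_ids, counts=counts)
    except ValueError as exc:
        raise OTUParseError(f"{path}: {exc}") from exc


def _parse_count_block(body: pd.DataFrame, path: Path) -> np.ndarray:
    try:
        counts = body.to_numpy(dtype=np.int64)
    except (TypeError, ValueError):
        # locate the offending line for the error message
        for i, (_, row) in enumerate(body.iterrows()):
            for val in row:
                try:
                    int(val)
                except (TypeError, ValueError):
                    raise OTUParseError(
                        f"{path}: line {i + 2}: non-integer count {val!r}"
                    ) from None
        raise OTUParseError(f"{path}: malformed count block")
    if (counts < 0).any():
        bad = int(np.argwhere((counts < 0).any(axis=1))[0, 0])
        raise OTUParseError(f"{path}: line {bad + 2}: negative count")
    return counts


def write_otu_table(table: OTUTable, path: str | Path, format: str = "tsv") -> None:
    """Write ``table`` in the named dialect (inverse of :func:`read_otu_table`)."""
    path = Path(path)
    df = table.to_frame()
    if format == "shared":
        out = pd.DataFrame(
            {
                "label": ["0.03"] * table.n_samples,
                "Group": table.sample_ids,
                "numOtus": [table.n_taxa] * table.n_samples,
            }
        )
        out = pd.concat([out.reset_index(drop=True), df.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)
    elif format == "tsv":
        df.to_csv(path, sep="\t", index_label="sample_id")
    else:
        raise ValueError(f"unknown OTU table format {format!r}")


def read_treatment_map(path: str | Path) -> dict[str, Treatment]:
    """Read a 2-column TSV ``sample_id<TAB>treatment`` into a mapping."""
    path = Path(path)
    out: dict[str, Treatment] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise OTUParseError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            if lineno == 1 and parts[0].strip().lower() in ("sample_id", "sample"):
                continue
            out[parts[0].strip()] = Treatment.parse(parts[1])
    return out


# ---------------------------------------------------------------------------
# configurations


def to_configurations(
    table: OTUTable,
    treatments: Mapping[str, Treatment] | None = None,
) -> list[AbundanceConfiguration]:
    """Convert each table row into an :class:`AbundanceConfiguration`.

    Zero-count taxa are dropped per sample (the sampling formulas are defined
    on present species only); samples with no positive counts are excluded
    with a warning.  Samples missing from ``treatments`` are labeled OTHER.
    """
    treatments = treatments or {}
    configs: list[AbundanceConfiguration] = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        if not (row > 0).any():
            logger.warning("sample %r has no positive counts; excluded", sid)
            continue
        trt = treatments.get(sid, Treatment.OTHER)
        if isinstance(trt, str):
            trt = Treatment.parse(trt)
        configs.append(AbundanceConfiguration.from_counts(sid, row, treatment=trt))
    return configs


def rank_abundance(config: AbundanceConfiguration) -> list[tuple[int, float]]:
    """Rank-abundance curve: (rank, ln abundance) for ranks 1..S.

    Values are nonincreasing; rank ties between equal abundances are resolved
    by the descending sort, which is stable, so output is deterministic.
    """
    return [(r + 1, math.log(int(n))) for r, n in enumerate(config.abundances)]


def write_configurations(configs: Sequence[AbundanceConfiguration], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "treatment": c.treatment.value,
            "J": c.J,
            "S": c.S,
            "abundances": ",".join(str(int(a)) for a in c.abundances),
        }
        for c in configs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_rank_abundance(configs: Sequence[AbundanceConfiguration], path: str | Path) -> None:
    rows = []
    for c in configs:
        for rank, ln_n in rank_abundance(c):
            rows.append({"sample_id": c.sample_id, "rank": rank, "ln_abundance": ln_n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
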