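"""Count-table and metadata IO, relative-abundance normalization, rarefaction,
and Good's coverage.

The root object of every analysis stage is a genus-by-sample table of
nonnegative integer read counts (:class:`CountTable`).  Two plain-text layouts
are supported: a simple TSV with samples in rows and taxa in columns, and the
mothur "shared" wide layout (``label``/``Group``/``numOtus`` columns followed
by one column per taxon).  Downstream statistics operate on per-sample
proportions on the percent scale (:class:`RelativeAbundanceTable`), the unit
in which genus medians are conventionally reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "RelativeAbundanceTable",
    "SampleMetadata",
    "CoverageResult",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "to_relative",
    "rarefy",
    "goods_coverage",
]

DIETS = ("LD", "WD")
GAVAGES = ("PBS", "FMT")
GROUP_LABELS = ("LD", "WD", "LD-wdFMT", "WD-ldFMT", "AL")
TIMEPOINTS = ("baseline", "DOS", "POD4", "POD7")
AL_STATUSES = ("yes", "no", "unknown")


@dataclass
class CountTable:
    """Integer taxon-by-sample counts.

    ``data`` is a samples × taxa DataFrame with unique string indices; all
    entries must be nonnegative integers and every sample must have at least
    one read.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise ValueError(
                "counts must be nonnegative integers; offending cell "
                f"(sample={df.index[bad[0]]!r}, taxon={df.columns[bad[1]]!r}, "
                f"value={arr[bad[0], bad[1]]!r})"
            )
        self.data = df.astype(np.int64)
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total reads: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class RelativeAbundanceTable:
    """Per-sample proportions on the percent scale (rows sum to 100)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1).to_numpy()
        if not np.allclose(sums, 100.0, rtol=1e-9):
            raise ValueError("each sample's abundances must sum to 100")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Per-sample study annotations: diet arm, gavage treatment, leak outcome.

    ``al_status`` is "unknown" only for mice that did not survive to necropsy;
    those animals are excluded from any leak analysis.
    """

    sample_id: str
    diet: str
    gavage: str
    group_label: str
    al_status: str
    timepoint: str
    survived: bool
    mouse_id: str = ""
    body_weight: float | None = None

    def __post_init__(self) -> None:
        if self.diet not in DIETS:
            raise ValueError(f"unknown diet {self.diet!r}")
        if self.gavage not in GAVAGES:
            raise ValueError(f"unknown gavage {self.gavage!r}")
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.al_status not in AL_STATUSES:
            raise ValueError(f"unknown AL status {self.al_status!r}")
        expected = expected_group_label(self.diet, self.gavage)
        if self.group_label not in (expected, "AL"):
            raise ValueError(
                f"group label {self.group_label!r} inconsistent with "
                f"diet={self.diet} gavage={self.gavage} (expected {expected})"
            )
        if self.al_status == "unknown" and self.survived:
            raise ValueError(
                f"sample {self.sample_id}: AL status may be unknown only for "
                "non-survivors"
            )


def expected_group_label(diet: str, gavage: str) -> str:
    """Treatment-group label implied by diet arm and gavage content.

    FMT is always reciprocal: LD-fed mice receive WD slurry and vice versa.
    """
    if gavage == "PBS":
        return diet
    return "LD-wdFMT" if diet == "LD" else "WD-ldFMT"


@dataclass
class CoverageResult:
    """Good's coverage C = 1 − singletons/reads for one sample."""

    sample_id: str
    coverage: float


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path, format: Literal["tsv", "mothur_shared"] = "tsv") -> CountTable:
    """Read a count table from ``path``.

    ``tsv``: first column sample id, remaining columns one per taxon.
    ``mothur_shared``: mothur wide layout with ``label``, ``Group`` and
    ``numOtus`` columns preceding the taxon columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mothur_shared":
        raw = pd.read_csv(path, sep="\t")
        required = {"label", "Group", "numOtus"}
        missing = required - set(raw.columns)
        if missing:
            raise ValueError(f"not a mothur shared file; missing columns {sorted(missing)}")
        df = raw.drop(columns=["label", "numOtus"]).set_index("Group")
        df.index.name = None
    else:
        raise ValueError(f"unknown format {format!r}")
    df.index = df.index.astype(str)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0) or np.any(arr != np.floor(arr)):
        # locate the first offending cell for the error message
        for i, sid in enumerate(df.index):
            for j, tid in enumerate(df.columns):
                v = df.iat[i, j]
                try:
                    ok = float(v) >= 0 and float(v) == int(float(v))
                except (TypeError, ValueError):
                    ok = False
                if not ok:
                    raise ValueError(
                        f"invalid count {v!r} at sample {sid!r}, taxon {tid!r} in {path}"
                    )
    return CountTable(df)


def write_counts(table: CountTable, path: str | Path,
                 format: Literal["tsv", "mothur_shared"] = "tsv",
                 label: str = "0.01") -> None:
    """Write ``table`` so that :func:`read_counts` round-trips bit-exactly."""
    path = Path(path)
    if format == "tsv":
        out = table.data.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")
    elif format == "mothur_shared":
        out = table.data.copy()
        out.insert(0, "numOtus", len(table.taxon_ids))
        out.insert(0, "Group", table.sample_ids)
        out.insert(0, "label", label)
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


_META_COLUMNS = [
    "sample_id", "mouse_id", "diet", "gavage", "group_label",
    "al_status", "timepoint", "survived", "body_weight",
]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mouse_id": str})
    records = []
    for row in df.itertuples(index=False):
        weight = getattr(row, "body_weight", None)
        if weight is not None and pd.isna(weight):
            weight = None
        records.append(SampleMetadata(
            sample_id=str(row.sample_id),
            mouse_id=str(getattr(row, "mouse_id", "")),
            diet=row.diet,
            gavage=row.gavage,
            group_label=row.group_label,
            al_status=row.al_status,
            timepoint=row.timepoint,
            survived=bool(row.survived),
            body_weight=weight,
        ))
    return records


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = [{c: getattr(m, c) for c in _META_COLUMNS} for m in metadata]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def metadata_frame(metadata: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample id (convenience view)."""
    rows = [{c: getattr(m, c) for c in _META_COLUMNS} for m in metadata]
    return pd.DataFrame(rows, columns=_META_COLUMNS).set_index("sample_id")


# ---------------------------------------------------------------------------
# normalization / rarefaction / coverage


def to_relative(table: CountTable) -> RelativeAbundanceTable:
    """Row-normalize counts to percent (each sample sums to 100)."""
    totals = table.totals
    if (totals == 0).any():
        raise ValueError(
            f"zero-total samples: {totals.index[totals == 0].tolist()}"
        )
    rel = table.data.div(totals, axis=0) * 100.0
    return RelativeAbundanceTable(rel)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    A single multivariate-hypergeometric draw per sample (mothur-style
    ``sub.sample``), not an average over draws.  Samples with fewer than
    ``depth`` reads are dropped with a warning.  Identical seeds give
    identical output.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.totals
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep, sort=False).tolist()
    if dropped:
        msg = f"rarefy: dropped {len(dropped)} samples below depth {depth}: {dropped}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if len(keep) == 0:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rows = {}
    for sid in keep:
        counts = table.data.loc[sid].to_numpy()
        if counts.sum() == depth:
            rows[sid] = counts
        else:
            rows[sid] = rng.multivariate_hypergeometric(counts, depth)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.taxon_ids)
    return CountTable(out.loc[keep])


def goods_coverage(table: CountTable) -> list[CoverageResult]:
    """Good's coverage C = 1 − F1/N per sample (F1 = singleton taxa)."""
    results = []
    for sid in table.sample_ids:
        counts = table.data.loc[sid].to_numpy()
        n = counts.sum()
        f1 = int((counts == 1).sum())
        results.append(CoverageResult(sample_id=sid, coverage=1.0 - f1 / n))
    return results
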