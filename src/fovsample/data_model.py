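"""Domain types and delimited-text I/O for per-field biomarker score tables.

The universal interchange format is a long (tidy) table of per-FOV scores
keyed by subject, region of interest (ROI) and field of view (FOV).  Scores
are quantitative-immunofluorescence (AQUA) scores: fluorescence intensity
per unit masked area, normalized to exposure time, hence nonnegative reals
on an arbitrary scale.

ROI labels are optional: some cohorts never recorded which ROI a field came
from.  A table either carries ROI labels for all of a subject's rows or for
none of them — partial labelling within a subject is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "FovScoreTable",
    "IndexArraySet",
    "SubjectSummary",
    "read_fov_table",
    "write_fov_table",
    "read_index_arrays",
    "write_index_arrays",
    "summarize_subjects",
]

#: canonical column names of the long format
CANONICAL_COLUMNS = ("subject_id", "roi_id", "fov_id", "score")


@dataclass
class FovScoreTable:
    """Long-format per-FOV score table.

    Wraps a :class:`pandas.DataFrame` with columns ``subject_id``,
    ``roi_id`` (nullable), ``fov_id`` and ``score``.  Construct through
    :meth:`from_frame` (or the readers) so invariants are checked.

    Attributes
    ----------
    df : pandas.DataFrame
        Validated long-format records.
    meta : dict
        Free-form provenance (e.g. a generator's truncation fraction).
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "FovScoreTable":
        """Validate a raw frame and return a table.

        Raises
        ------
        ValidationError
            On duplicate (subject, roi, fov) keys, non-finite or negative
            scores, missing scores, or ROI labels present for only part of
            a subject's rows.
        """
        missing = [c for c in ("subject_id", "fov_id", "score") if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")
        out = df.copy()
        if "roi_id" not in out.columns:
            out["roi_id"] = pd.NA
        out = out[list(CANONICAL_COLUMNS)]

        if out["score"].isna().any():
            bad = out.index[out["score"].isna()][0]
            raise ValidationError(f"missing score at row {bad}; rows with missing scores are rejected")
        out["score"] = pd.to_numeric(out["score"], errors="raise").astype(float)
        if not np.isfinite(out["score"]).all():
            raise ValidationError("scores must be finite")
        if (out["score"] < 0).any():
            bad = out.loc[out["score"] < 0].iloc[0]
            raise ValidationError(
                f"negative score {bad['score']!r} for subject {bad['subject_id']!r}; AQUA scores are nonnegative"
            )

        for col in ("subject_id", "fov_id"):
            if out[col].isna().any():
                raise ValidationError(f"column {col!r} contains missing values")
            out[col] = out[col].astype(str)

        # ROI labels: all-or-none per subject
        roi_na = out["roi_id"].isna()
        partially = out.groupby("subject_id", sort=False)["roi_id"].agg(lambda s: s.isna().any() and s.notna().any())
        if partially.any():
            subj = partially.index[partially][0]
            raise ValidationError(f"subject {subj!r} has ROI labels on only some rows; must be all or none")
        if not roi_na.all():
            out.loc[~roi_na, "roi_id"] = out.loc[~roi_na, "roi_id"].astype(str)

        key = out["subject_id"] + "\x1f" + out["roi_id"].fillna("").astype(str) + "\x1f" + out["fov_id"]
        dup = key.duplicated()
        if dup.any():
            first = out.loc[dup].iloc[0]
            raise ValidationError(
                "duplicate (subject, roi, fov) key: "
                f"({first['subject_id']!r}, {first['roi_id']!r}, {first['fov_id']!r})"
            )
        return cls(out.reset_index(drop=True), meta=dict(meta or {}))

    # -- basic views ---------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> list[str]:
        """Subject ids in first-appearance order."""
        return list(dict.fromkeys(self.df["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def has_roi(self) -> bool:
        """True when ROI labels are recorded (for every row)."""
        return bool(self.df["roi_id"].notna().all()) and self.n_records > 0

    def scores_by_subject(self) -> dict[str, np.ndarray]:
        """All of a subject's FOV scores pooled across ROIs, per subject."""
        return {s: g["score"].to_numpy() for s, g in self.df.groupby("subject_id", sort=False)}


@dataclass
class SubjectSummary:
    """Per-subject whole-section summary: field count K, mean score and SD.

    ``mean_score`` is the whole-section average over all of the subject's
    FOVs — the quantity treated as the subject's "true" representative
    score.  ``sd_score`` is the sample SD of the FOV scores (0 when K=1).
    """

    subject_id: str
    k_fovs: int
    mean_score: float
    sd_score: float


def summarize_subjects(table: FovScoreTable) -> list[SubjectSummary]:
    """One summary per subject, pooling FOVs across ROIs.

    FOVs are the sampling unit regardless of which ROI they fell in, so the
    summary ignores ROI structure entirely.
    """
    out = []
    for subj, g in table.df.groupby("subject_id", sort=False):
        x = g["score"].to_numpy()
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        out.append(SubjectSummary(str(subj), int(len(x)), float(np.mean(x)), sd))
    return out


@dataclass
class IndexArraySet:
    """Matched per-run score vectors on a shared set of control cores.

    An index array is a control tissue microarray stained in every run;
    matched scores on its cores are what between-run transforms are learned
    from.  ``scores`` is a cores x runs frame indexed by ``core_ids``;
    missing cores (lost during staining) are NaN.
    """

    core_ids: list[str]
    scores: pd.DataFrame
    baseline_run: str

    def __post_init__(self) -> None:
        if self.baseline_run not in self.scores.columns:
            raise ValidationError(f"baseline run {self.baseline_run!r} not among runs {list(self.scores.columns)}")
        if len(self.scores) != len(self.core_ids):
            raise ValidationError("scores frame length does not match core_ids")

    @property
    def runs(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# Delimited-text I/O.  CSV vs TSV is sniffed from the header line unless a
# separator is forced.  A dialect maps canonical column names to the file's.
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    header = Path(path).open().readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_fov_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> FovScoreTable:
    """Read a long-format FOV score table from delimited text.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    dialect
        Optional mapping from canonical names (``subject_id``, ``roi_id``,
        ``fov_id``, ``score``) to the file's column names.
    sep
        Force a separator instead of sniffing it from the header.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"score file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path, sep))
    dialect = dict(dialect or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = dialect.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon != "roi_id":
            raise ConfigurationError(f"column {src!r} (for {canon!r}) not found in {path.name}")
    return FovScoreTable.from_frame(df.rename(columns=rename))


def write_fov_table(table: FovScoreTable, path: str | Path, sep: str = ",") -> None:
    """Write a table back to delimited text at full float precision."""
    df = table.df.copy()
    if not table.has_roi:
        df = df.drop(columns=["roi_id"])
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_index_arrays(
    path: str | Path,
    baseline_run: str | None = None,
    sep: str | None = None,
) -> IndexArraySet:
    """Read an index-array set: first column core ids, one column per run.

    ``baseline_run`` defaults to the first run column in file order.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"index-array file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path, sep))
    if df.shape[1] < 3:
        raise ValidationError("index-array file needs a core-id column and at least two runs")
    core_ids = df.iloc[:, 0].astype(str).tolist()
    scores = df.iloc[:, 1:].astype(float)
    scores.index = pd.Index(core_ids, name="core_id")
    return IndexArraySet(core_ids, scores, baseline_run or scores.columns[0])


def write_index_arrays(arrays: IndexArraySet, path: str | Path, sep: str = ",") -> None:
    arrays.scores.to_csv(path, sep=sep, index=True, index_label="core_id", float_format="%.17g")


def scores_matrix(arrays: IndexArraySet) -> pd.DataFrame:
    """Cores x runs matrix view (alias kept for readability at call sites)."""
    return arrays.scores


def subject_design(table: FovScoreTable) -> list[tuple[str, list[int]]]:
    """Per-subject list of FOV counts per ROI (one pooled pseudo-ROI if absent)."""
    out: list[tuple[str, list[int]]] = []
    for subj, g in table.df.groupby("subject_id", sort=False):
        if g["roi_id"].notna().all():
            counts = [int(n) for _, n in g.groupby("roi_id", sort=False).size().items()]
        else:
            counts = [int(len(g))]
        out.append((str(subj), counts))
    return out
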