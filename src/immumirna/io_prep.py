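"""Readers, writers and preprocessing for expression matrices, gene sets,
tumour purity and survival tables.

Expression tables are delimited text with features in rows: the first column
holds feature identifiers, the header row holds sample identifiers. Gene sets
use the standard GMT layout (name, description, members). Purity and survival
tables are two/three-column delimited files keyed by sample id.

The preprocessing chain mirrors common bulk RNA-seq practice: library-size
normalization of raw counts (RPM, or TPM when feature lengths are supplied),
a log2(x+1) transform, optional per-feature z-scoring, and removal of features
that are zero in more than a chosen fraction of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "PurityVector",
    "GeneSetCollection",
    "SurvivalData",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "read_purity_table",
    "write_purity_table",
    "read_survival_table",
    "write_survival_table",
    "rpm_normalize",
    "log2p1",
    "zscore_rows",
    "filter_zero_fraction",
    "align_samples",
]

VALID_STATES = ("counts", "rpm", "tpm", "log2", "zscore")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ExpressionMatrix:
    """A features × samples numeric table with a normalization-state tag.

    Parameters
    ----------
    values:
        DataFrame indexed by feature id with sample ids as columns.
    state:
        One of ``counts``, ``rpm``, ``tpm``, ``log2``, ``zscore``. The tag
        lets downstream steps assert their preconditions (e.g. the risk
        score expects z-scored input).
    """

    values: pd.DataFrame
    state: str

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(
                f"unknown state {self.state!r}; expected one of {VALID_STATES}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.state == "counts":
            if arr.size and np.nanmin(arr) < 0:
                raise ValueError("counts must be non-negative")
        elif arr.size and not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in state {self.state!r}")

    @property
    def feature_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.state)


@dataclass
class PurityVector:
    """Per-sample tumour purity (fraction of malignant cells) in [0, 1]."""

    purity: pd.Series

    def __post_init__(self) -> None:
        if self.purity.index.has_duplicates:
            raise ValueError("duplicate sample ids in purity vector")
        vals = self.purity.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("purity values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list:
        return self.purity.index.tolist()

    def subset_samples(self, sample_ids: Iterable) -> "PurityVector":
        return PurityVector(self.purity.loc[list(sample_ids)])


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (e.g. immune-associated pathways)."""

    sets: dict[str, frozenset]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SurvivalData:
    """Right-censored follow-up per sample: time > 0 and event ∈ {0, 1}."""

    time: pd.Series
    event: pd.Series

    def __post_init__(self) -> None:
        if not self.time.index.equals(self.event.index):
            raise ValueError("time and event must share the same sample index")
        if self.time.index.has_duplicates:
            raise ValueError("duplicate sample ids in survival data")
        t = self.time.to_numpy(dtype=float)
        e = self.event.to_numpy()
        if t.size and np.nanmin(t) <= 0:
            raise ValueError("follow-up times must be positive")
        if e.size and not np.isin(e, (0, 1)).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")

    @property
    def sample_ids(self) -> list:
        return self.time.index.tolist()

    def subset_samples(self, sample_ids: Iterable) -> "SurvivalData":
        ids = list(sample_ids)
        return SurvivalData(self.time.loc[ids], self.event.loc[ids])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path) -> pd.DataFrame:
    """Read a tab- or comma-delimited table with a header row."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def read_expression_table(path, state: str) -> ExpressionMatrix:
    """Read a delimited expression table (first column feature ids).

    Non-numeric cells, duplicate feature/sample ids or ragged rows raise
    :class:`ParseError` naming the offending row or column.
    """
    try:
        raw = _read_delimited(path)
    except Exception as exc:  # malformed beyond repair
        raise ParseError(f"{path}: could not parse table: {exc}") from exc
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected feature-id column plus ≥1 sample column")
    feature_col = raw.columns[0]
    features = raw[feature_col]
    dup = features[features.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"{path}: duplicate feature id(s): {dup}")
    body = raw.set_index(feature_col)
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        row = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[row]][0]
        raise ParseError(
            f"{path}: non-numeric cell at feature {row!r}, sample {col!r}: "
            f"{body.loc[row, col]!r}"
        )
    if numeric.isna().to_numpy().any():
        row = numeric.index[numeric.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row for feature {row!r}")
    numeric.index.name = "feature_id"
    return ExpressionMatrix(numeric.astype(float), state)


def write_expression_table(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=sep, float_format="%.10g")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members per line).

    The description column is ignored; duplicate members within a line are
    collapsed. Duplicate set names and lines with fewer than three fields
    are format errors.
    """
    sets: dict[str, frozenset] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs ≥3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name, members in collection:
            handle.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_purity_table(path) -> PurityVector:
    raw = _read_delimited(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected columns (sample_id, purity)")
    series = pd.Series(
        pd.to_numeric(raw.iloc[:, 1], errors="coerce").to_numpy(),
        index=raw.iloc[:, 0].to_numpy(),
        name="purity",
    )
    if series.isna().any():
        bad = series.index[series.isna()][0]
        raise ParseError(f"{path}: non-numeric purity for sample {bad!r}")
    return PurityVector(series)


def write_purity_table(purity: PurityVector, path, sep: str = "\t") -> None:
    frame = purity.purity.rename_axis("sample_id").reset_index()
    frame.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_survival_table(path) -> SurvivalData:
    raw = _read_delimited(path)
    if raw.shape[1] < 3:
        raise ParseError(f"{path}: expected columns (sample_id, time, event)")
    idx = raw.iloc[:, 0].to_numpy()
    time = pd.Series(pd.to_numeric(raw.iloc[:, 1], errors="coerce").to_numpy(), index=idx, name="time")
    event = pd.Series(pd.to_numeric(raw.iloc[:, 2], errors="coerce").to_numpy(), index=idx, name="event")
    if time.isna().any() or event.isna().any():
        raise ParseError(f"{path}: non-numeric time or event value")
    return SurvivalData(time, event.astype(int))


def write_survival_table(survival: SurvivalData, path, sep: str = "\t") -> None:
    frame = pd.DataFrame(
        {"sample_id": survival.time.index, "time": survival.time.to_numpy(),
         "event": survival.event.to_numpy()}
    )
    frame.to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# normalization / filtering
# ---------------------------------------------------------------------------


def rpm_normalize(
    counts: ExpressionMatrix,
    lengths_kb: pd.Series | Mapping | None = None,
) -> ExpressionMatrix:
    """Scale each sample column of a count matrix to sum 10^6.

    Without ``lengths_kb`` this is reads-per-million (RPM), the usual choice
    for miRNA counts. With per-feature lengths in kilobases the counts are
    first divided by length, giving transcripts-per-million (TPM) for mRNA.
    """
    if counts.state != "counts":
        raise ValueError(f"expected state 'counts', got {counts.state!r}")
    values = counts.values.astype(float)
    state = "rpm"
    if lengths_kb is not None:
        lengths = pd.Series(lengths_kb, dtype=float).reindex(values.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()].tolist()[:5]
            raise ValueError(f"missing feature length(s) for: {missing}")
        if (lengths <= 0).any():
            raise ValueError("feature lengths must be positive")
        values = values.div(lengths, axis=0)
        state = "tpm"
    totals = values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample column(s): {zero}")
    return ExpressionMatrix(values.div(totals, axis=1) * 1e6, state)


def log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x + 1); the +1 offset keeps exact zeros at zero."""
    if matrix.state not in ("rpm", "tpm"):
        raise ValueError(f"expected state 'rpm' or 'tpm', got {matrix.state!r}")
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), "log2")


def zscore_rows(matrix: ExpressionMatrix, allow_any_state: bool = False) -> ExpressionMatrix:
    """Standardize each feature row to mean 0, sd 1 (n−1 denominator).

    Constant rows cannot be standardized; they become all-zero and are
    reported through a ``UserWarning`` listing the feature ids.
    """
    if matrix.state != "log2" and not allow_any_state:
        raise ValueError(
            f"expected state 'log2' (pass allow_any_state=True to override), "
            f"got {matrix.state!r}"
        )
    values = matrix.values.astype(float)
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        warnings.warn(
            f"{len(constant)} constant feature row(s) set to zero: {constant[:5]}",
            UserWarning,
            stacklevel=2,
        )
    safe_sd = sd.replace(0, np.nan)
    out = values.sub(mu, axis=0).div(safe_sd, axis=0)
    out.loc[constant] = 0.0
    return ExpressionMatrix(out.fillna(0.0), "zscore")


def filter_zero_fraction(
    counts: ExpressionMatrix, max_zero_frac: float = 0.5
) -> ExpressionMatrix:
    """Drop features whose zero-count fraction strictly exceeds the threshold.

    The default reproduces the common "zero reads in >50% of samples" rule;
    a feature that is zero in exactly half the samples is kept.
    """
    if counts.state != "counts":
        raise ValueError(f"expected state 'counts', got {counts.state!r}")
    zero_frac = (counts.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    return ExpressionMatrix(counts.values.loc[keep], "counts")


def align_samples(*objects):
    """Subset expression/purity/survival objects to their shared samples.

    Returns the aligned objects (same order as the inputs) and the number of
    sample ids dropped from at least one input. Sample order follows the
    first object's ordering.
    """
    id_sets = []
    for obj in objects:
        id_sets.append(list(obj.sample_ids))
    common = set(id_sets[0])
    for ids in id_sets[1:]:
        common &= set(ids)
    if not common:
        raise ValueError("no shared sample ids across inputs")
    ordered = [s for s in id_sets[0] if s in common]
    dropped = len(set().union(*map(set, id_sets))) - len(common)
    aligned = tuple(obj.subset_samples(ordered) for obj in objects)
    return aligned, dropped
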