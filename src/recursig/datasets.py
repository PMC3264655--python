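"""Data containers and tab-delimited file formats.

The universal input record is :class:`SurvivalDataset`: a genes x samples
log-scale expression matrix aligned with per-sample recurrence-free survival
(time in months, binary event indicator) and clinical covariates (age,
gender, stage, optional batch label). Gene sets for pathway scans are read
from standard GMT files into a :class:`GeneSetCollection`.

Expression values are assumed to be already normalized and on a log scale;
no transformation is applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("sample_id", "time_months", "event", "age", "gender", "stage")


class FormatError(ValueError):
    """A file violated the declared tab-delimited contract."""


@dataclass
class SurvivalDataset:
    """Expression matrix plus aligned survival outcomes and covariates.

    ``expr`` is genes x samples. ``time`` is recurrence-free survival in
    months (strictly positive); ``event`` is 1 for an observed recurrence
    and 0 for a censored sample.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    expr: np.ndarray
    time: np.ndarray
    event: np.ndarray
    age: np.ndarray
    gender: np.ndarray
    stage: np.ndarray
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.expr = np.asarray(self.expr, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=object)
        self.stage = np.asarray(self.stage, dtype=object)
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
        self._validate()

    def _validate(self) -> None:
        g, n = self.expr.shape
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match expression rows")
        per_sample = [self.sample_ids, self.time, self.event, self.age,
                      self.gender, self.stage]
        if self.batch is not None:
            per_sample.append(self.batch)
        for arr in per_sample:
            if len(arr) != n:
                raise ValueError("per-sample array length does not match expression columns")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene identifiers are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample identifiers are not unique")
        if not np.all(np.isfinite(self.expr)):
            raise ValueError("expression matrix contains missing or non-finite values")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("survival times must be strictly positive and finite")
        ev = np.unique(self.event)
        if not np.all(np.isin(ev, [0, 1])):
            raise ValueError("event indicator must be coded 0/1")
        self.event = self.event.astype(int)

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:10]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "SurvivalDataset":
        idx = self.gene_index(genes)
        return replace(self, gene_ids=self.gene_ids[idx], expr=self.expr[idx])

    def subset_samples(self, idx: np.ndarray) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            expr=self.expr[:, idx],
            sample_ids=self.sample_ids[idx],
            time=self.time[idx],
            event=self.event[idx],
            age=self.age[idx],
            gender=self.gender[idx],
            stage=self.stage[idx],
            batch=None if self.batch is None else self.batch[idx],
        )

    def strata_labels(self) -> np.ndarray:
        """Gender x stage stratum label per sample."""
        return np.array([f"{g}|{s}" for g, s in zip(self.gender, self.stage)],
                        dtype=object)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) in file order."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_expression(path: str | Path, duplicates: str = "error",
                    missing: str = "error") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a genes x samples tab-delimited expression matrix.

    First row holds sample identifiers, first column gene identifiers, body
    numeric. ``duplicates`` is ``"error"`` (reject duplicated gene rows) or
    ``"max-variance"`` (keep the most variable row per identifier, for
    probe-level inputs). ``missing`` is ``"error"`` or ``"drop"`` (drop rows
    containing any missing value, with a logged count).
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise FormatError(f"duplicate sample identifiers: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sample_ids = np.array(df.columns, dtype=object)
    try:
        body = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, val in enumerate(df[col]):
                if pd.isna(val):
                    continue
                try:
                    float(val)
                except ValueError:
                    raise FormatError(
                        f"non-numeric cell at gene {df.index[i]!r}, sample {col!r}: {val!r}"
                    ) from None
        raise
    if body.isna().any().any():
        if missing == "drop":
            bad = body.isna().any(axis=1)
            logger.warning("dropping %d gene rows with missing values", int(bad.sum()))
            body = body.loc[~bad]
        else:
            i, j = np.argwhere(body.isna().values)[0]
            raise FormatError(
                f"missing value at gene {body.index[i]!r}, sample {body.columns[j]!r}"
            )
    if body.index.duplicated().any():
        if duplicates == "max-variance":
            body = (body.assign(_var=body.var(axis=1))
                        .sort_values("_var", ascending=False)
                        .drop(columns="_var"))
            body = body[~body.index.duplicated(keep="first")]
        else:
            dupes = sorted(set(body.index[body.index.duplicated()]))
            raise FormatError(f"duplicate gene identifiers: {dupes[:10]}")
    return (np.array(body.index, dtype=object), sample_ids, body.values.astype(float))


def write_expression(path: str | Path, gene_ids: Sequence[str],
                     sample_ids: Sequence[str], expr: np.ndarray) -> None:
    pd.DataFrame(expr, index=list(gene_ids), columns=list(sample_ids)).to_csv(
        path, sep="\t", lineterminator="\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-sample clinical table.

    Expected header: ``sample_id  time_months  event  age  gender  stage``
    with an optional trailing ``batch`` column. Times are months and must be
    strictly positive; events must be coded 0/1 (no silent recoding).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"clinical table missing columns: {missing_cols}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in clinical table")
    try:
        df["event"] = df["event"].astype(int)
    except ValueError:
        bad = sorted(set(df["event"]) - {"0", "1"})
        raise FormatError(
            f"event must be coded 0/1, found {bad}; recode the column explicitly"
        ) from None
    if not df["event"].isin([0, 1]).all():
        bad = sorted(set(df["event"]) - {0, 1})
        raise FormatError(f"event must be coded 0/1, found {bad}")
    df["time_months"] = df["time_months"].astype(float)
    if (df["time_months"] <= 0).any() or ~np.isfinite(df["time_months"]).all():
        bad = df.loc[df["time_months"] <= 0, "sample_id"].tolist()
        raise FormatError(f"non-positive survival time for samples {bad[:10]}")
    df["age"] = df["age"].astype(float)
    return df


def write_clinical(path: str | Path, dataset: SurvivalDataset) -> None:
    cols = {
        "sample_id": dataset.sample_ids,
        "time_months": dataset.time,
        "event": dataset.event,
        "age": dataset.age,
        "gender": dataset.gender,
        "stage": dataset.stage,
    }
    if dataset.batch is not None:
        cols["batch"] = dataset.batch
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, lineterminator="\n")


def assemble_dataset(expr_triple: tuple[np.ndarray, np.ndarray, np.ndarray],
                     clinical: pd.DataFrame) -> SurvivalDataset:
    """Join an expression triple with a clinical table on sample id.

    Samples are restricted to the intersection (expression column order);
    dropped samples are logged. Disjoint id sets are an error.
    """
    gene_ids, sample_ids, expr = expr_triple
    clin = clinical.set_index("sample_id")
    common = [s for s in sample_ids if s in clin.index]
    if not common:
        raise ValueError("expression and clinical tables share no sample identifiers")
    dropped = (len(sample_ids) - len(common)) + (len(clin) - len(common))
    if dropped:
        logger.warning("assemble_dataset: dropped %d samples outside the id intersection",
                       dropped)
    keep = np.array([s in clin.index for s in sample_ids])
    clin = clin.loc[list(np.asarray(sample_ids, dtype=object)[keep])]
    return SurvivalDataset(
        gene_ids=gene_ids,
        sample_ids=np.asarray(sample_ids, dtype=object)[keep],
        expr=expr[:, keep],
        time=clin["time_months"].values,
        event=clin["event"].values,
        age=clin["age"].values,
        gender=clin["gender"].values,
        stage=clin["stage"].values,
        batch=clin["batch"].values if "batch" in clin.columns else None,
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, members per line)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"duplicate gene set name {name!r} at line {lineno}")
            sets[name] = [g for g in fields[2:] if g]
            if not sets[name]:
                raise FormatError(f"gene set {name!r} at line {lineno} has no members")
    if not sets:
        raise FormatError(f"GMT file {path} contains no gene sets")
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
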