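"""Corpora and multitask label tables.

Two input formats are supported: plain text with one SMILES per line (the
pretraining corpus), and CSV tables with one SMILES column and one column
per property task, where a blank cell means the label is missing. Missing
labels are first-class: every record carries a boolean observed-mask and
losses/metrics only ever touch observed entries, which is what makes
concatenating many single-task datasets into one multitask table possible.

Each source dataset is split into train/validation/test at 8:1:1 before any
augmentation, so enumerated renderings of one molecule always share their
parent's split and never leak across splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MoleculeRecord",
    "TaskTable",
    "read_corpus",
    "write_corpus",
    "read_task_csv",
    "write_task_csv",
    "split_table",
    "concat_multitask",
]

SPLITS = ("train", "valid", "test")


@dataclass
class MoleculeRecord:
    """One molecule with per-task labels and an observed-mask."""

    smiles: str
    labels: np.ndarray          # float per task; ignored where not observed
    observed: np.ndarray        # bool per task
    split: str | None = None    # one of SPLITS once assigned
    source: str | None = None   # originating dataset name

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.labels.shape != self.observed.shape:
            raise ValueError("labels and observed must have equal length")


@dataclass
class TaskTable:
    """A multitask dataset: named tasks, their kinds, and records."""

    task_names: list[str]
    task_kinds: list[str]       # "classification" | "regression"
    records: list[MoleculeRecord] = field(default_factory=list)

    def __post_init__(self):
        if len(self.task_names) != len(self.task_kinds):
            raise ValueError("task_names and task_kinds must align")
        for kind in self.task_kinds:
            if kind not in ("classification", "regression"):
                raise ValueError(f"unknown task kind {kind!r}")
        for rec in self.records:
            if len(rec.labels) != len(self.task_names):
                raise ValueError("record label width does not match task count")

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "TaskTable":
        if split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
        return TaskTable(self.task_names, self.task_kinds,
                         [r for r in self.records if r.split == split])

    def n_observed(self) -> int:
        return int(sum(r.observed.sum() for r in self.records))


def read_corpus(path) -> list[str]:
    """Plain text, one SMILES per line; blank lines skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_corpus(path, smiles_list) -> None:
    with open(path, "w") as fh:
        for s in smiles_list:
            fh.write(s + "\n")


def read_task_csv(path, smiles_column: str = "smiles",
                  task_kinds: dict[str, str] | list[str] | str = "classification",
                  source: str | None = None) -> TaskTable:
    """Read a multitask CSV.

    Every column except ``smiles_column`` (and an optional ``split`` column)
    is a task. ``task_kinds`` maps task name -> kind, or gives one kind for
    all tasks, or lists kinds in column order, or is ``"infer"`` (a column
    whose observed values are all 0/1 is treated as classification,
    otherwise regression). Blank/NA cells become unobserved labels;
    classification cells must be 0/1 and regression cells finite —
    malformed cells raise with their row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if smiles_column not in df.columns:
        raise ValueError(f"missing SMILES column {smiles_column!r}")
    has_split = "split" in df.columns
    task_names = [c for c in df.columns if c not in (smiles_column, "split")]

    if task_kinds == "infer":
        kinds = []
        for name in task_names:
            vals = set()
            for cell in df[name]:
                cell = cell.strip()
                if cell and cell.upper() not in ("NA", "NAN"):
                    try:
                        vals.add(float(cell))
                    except ValueError:
                        pass  # reported with row/column below
            kinds.append("classification" if vals <= {0.0, 1.0} and vals
                         else "regression")
    elif isinstance(task_kinds, str):
        kinds = [task_kinds] * len(task_names)
    elif isinstance(task_kinds, dict):
        missing = [t for t in task_names if t not in task_kinds]
        if missing:
            raise ValueError(f"task_kinds missing entries for {missing}")
        kinds = [task_kinds[t] for t in task_names]
    else:
        kinds = list(task_kinds)
        if len(kinds) != len(task_names):
            raise ValueError("task_kinds list does not match task columns")

    records: list[MoleculeRecord] = []
    for row_idx, row in df.iterrows():
        smi = row[smiles_column].strip()
        if not smi:
            raise ValueError(f"row {row_idx}: missing SMILES")
        labels = np.zeros(len(task_names))
        observed = np.zeros(len(task_names), dtype=bool)
        for j, (name, kind) in enumerate(zip(task_names, kinds)):
            cell = row[name].strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                continue
            try:
                val = float(cell)
            except ValueError:
                raise ValueError(
                    f"row {row_idx}, column {name!r}: malformed cell {cell!r}"
                ) from None
            if kind == "classification" and val not in (0.0, 1.0):
                raise ValueError(
                    f"row {row_idx}, column {name!r}: classification label "
                    f"must be 0 or 1, got {cell!r}"
                )
            if not np.isfinite(val):
                raise ValueError(
                    f"row {row_idx}, column {name!r}: non-finite value {cell!r}"
                )
            labels[j] = val
            observed[j] = True
        split = row["split"].strip() if has_split else None
        if split == "":
            split = None
        records.append(MoleculeRecord(smi, labels, observed, split=split,
                                      source=source))
    return TaskTable(task_names, kinds, records)


def write_task_csv(path, table: TaskTable, smiles_column: str = "smiles") -> None:
    """Write a TaskTable as CSV; unobserved cells are left blank, the split
    assignment (if any) goes in an extra ``split`` column."""
    cols: dict[str, list] = {smiles_column: [r.smiles for r in table.records]}
    for j, name in enumerate(table.task_names):
        col = []
        for r in table.records:
            if r.observed[j]:
                v = r.labels[j]
                col.append(str(int(v)) if table.task_kinds[j] == "classification"
                           else repr(float(v)))
            else:
                col.append("")
        cols[name] = col
    if any(r.split for r in table.records):
        cols["split"] = [r.split or "" for r in table.records]
    pd.DataFrame(cols).to_csv(path, index=False)


def split_table(table: TaskTable, seed: int,
                fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
                ) -> TaskTable:
    """Assign train/valid/test at the given fractions within each source.

    Deterministic under ``seed``. Augmentation must happen after this call
    so enumerated variants inherit their parent's split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    by_source: dict = {}
    for i, rec in enumerate(table.records):
        by_source.setdefault(rec.source, []).append(i)
    new_records = [replace(r) for r in table.records]
    for source, idxs in by_source.items():
        n = len(idxs)
        if n < 3:
            raise ValueError(
                f"source {source!r} has {n} records; need >= 3 to split"
            )
        n_valid = int(round(n * fractions[1]))
        n_test = int(round(n * fractions[2]))
        n_valid, n_test = max(n_valid, 1), max(n_test, 1)
        perm = rng.permutation(n)
        shuffled = [idxs[p] for p in perm]
        for i in shuffled[: n - n_valid - n_test]:
            new_records[i].split = "train"
        for i in shuffled[n - n_valid - n_test: n - n_test]:
            new_records[i].split = "valid"
        for i in shuffled[n - n_test:]:
            new_records[i].split = "test"
    return TaskTable(table.task_names, table.task_kinds, new_records)


def concat_multitask(tables: list[TaskTable],
                     max_tasks: int | None = None) -> TaskTable:
    """Concatenate tables along the task axis.

    Task-name sets must be disjoint; a record from one table is unobserved
    for every task of the others. The total count of observed labels is
    conserved.
    """
    if not tables:
        raise ValueError("no tables to concatenate")
    names: list[str] = []
    kinds: list[str] = []
    for t in tables:
        for name in t.task_names:
            if name in names:
                raise ValueError(f"duplicate task name {name!r}")
        names.extend(t.task_names)
        kinds.extend(t.task_kinds)
    if max_tasks is not None and len(names) > max_tasks:
        raise ValueError(
            f"{len(names)} tasks exceed the configured task-token count "
            f"{max_tasks}"
        )
    total = len(names)
    records: list[MoleculeRecord] = []
    offset = 0
    for t in tables:
        w = t.n_tasks
        for r in t.records:
            labels = np.zeros(total)
            observed = np.zeros(total, dtype=bool)
            labels[offset: offset + w] = r.labels
            observed[offset: offset + w] = r.observed
            records.append(MoleculeRecord(r.smiles, labels, observed,
                                          split=r.split, source=r.source))
        offset += w
    return TaskTable(names, kinds, records)
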