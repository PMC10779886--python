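"""Descriptor tables, training-based preprocessing and sequential splits.

A :class:`DescriptorTable` holds one compound per row: a string ID, an
optional SMILES, a named numeric descriptor matrix and an optional Log(S)
target (log10 mol/L).  Preprocessing is always *fitted on the training rows
only* — variable removal, mean-centring and unit-SD scaling derive every
statistic from the training set and are then applied unchanged to test or
screening compounds, so no test information leaks into the model.

Train/test splits are sequential: with period ``p`` and 1-based offset
``o``, every row whose 1-based position is congruent to ``o`` modulo ``p``
goes to the test side.  Multiple offsets and nested rules (which move
designated members of an already-built test subset back to training) cover
the middle-set constructions used for curated data sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, SchemaError, TableIOError

#: Cell contents treated as missing in descriptor CSV files.
MISSING_MARKERS = ("", "NA", "NaN", "nan")


@dataclass
class DescriptorTable:
    """Compound IDs, optional SMILES, named descriptor matrix, optional target.

    Attributes
    ----------
    ids : list of str
        Unique compound identifiers, one per row.
    X : pandas.DataFrame
        Numeric descriptors; column names are the descriptor names.
    y : numpy.ndarray or None
        Experimental Log(S) in log10 mol/L, aligned with ``ids``.
    smiles : list of str or None
        Optional SMILES strings for bookkeeping (never parsed here).
    """

    ids: list[str]
    X: pd.DataFrame
    y: np.ndarray | None = None
    smiles: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(self.X) != n:
            raise SchemaError(f"X has {len(self.X)} rows but there are {n} ids")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if len(self.y) != n:
                raise SchemaError(f"y has {len(self.y)} rows but there are {n} ids")
        if self.smiles is not None and len(self.smiles) != n:
            raise SchemaError("smiles length does not match ids")
        if self.X.columns.duplicated().any():
            dup = self.X.columns[self.X.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate descriptor columns: {dup}")
        seen: set[str] = set()
        for cid in self.ids:
            if cid in seen:
                raise TableIOError(f"duplicate compound_id: {cid!r}")
            seen.add(cid)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, idx: Sequence[int]) -> "DescriptorTable":
        """Row subset (0-based positions), preserving order of ``idx``."""
        idx = list(idx)
        return DescriptorTable(
            ids=[self.ids[i] for i in idx],
            X=self.X.iloc[idx].reset_index(drop=True),
            y=None if self.y is None else self.y[idx],
            smiles=None if self.smiles is None else [self.smiles[i] for i in idx],
        )

    def equals(self, other: "DescriptorTable") -> bool:
        if self.ids != other.ids or self.smiles != other.smiles:
            return False
        if not self.X.equals(other.X):
            return False
        if (self.y is None) != (other.y is None):
            return False
        return self.y is None or np.array_equal(self.y, other.y, equal_nan=True)


@dataclass(frozen=True)
class PreprocessModel:
    """Training-derived column filter plus per-column centring/scaling.

    ``kept_columns`` excludes training columns with any missing or
    non-finite value or a single unique value.  ``scales`` are sample
    standard deviations (n−1 denominator), strictly positive.
    """

    kept_columns: list[str]
    means: np.ndarray
    scales: np.ndarray


@dataclass(frozen=True)
class SplitRule:
    """Sequential split: 1-based rows ≡ offset (mod period) become the test set.

    ``start_offsets`` allows several offsets per period (e.g. every ninth
    compound starting from the second, fourth, sixth and eighth).
    ``nested_rules`` are applied to the just-built test subset in its own
    1-based order; the rows they select are moved back to training.
    """

    period: int
    start_offsets: tuple[int, ...] = (1,)
    nested_rules: tuple["SplitRule", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.period < 2:
            raise ParameterError(f"period must be ≥ 2, got {self.period}")
        offs = tuple(int(o) for o in self.start_offsets)
        object.__setattr__(self, "start_offsets", offs)
        for o in offs:
            if not 1 <= o <= self.period:
                raise ParameterError(
                    f"start_offset {o} outside 1..{self.period}"
                )


def read_table(
    path: str | Path,
    id_column: str = "compound_id",
    target_column: str | None = "logS",
    smiles_column: str = "smiles",
) -> DescriptorTable:
    """Read a descriptor CSV into a :class:`DescriptorTable`.

    Row order is preserved exactly (sequential splits depend on it).  Empty
    cells and ``NA``/``NaN`` markers become missing values; ``Inf``/``-Inf``
    parse as infinities and are later removed by :func:`fit_preprocessor`.
    Non-numeric descriptor cells raise :class:`TableIOError` naming the row
    and column; so do duplicate compound IDs.
    """
    path = Path(path)
    if not path.exists():
        raise TableIOError(f"no such file: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in raw.columns:
        raise TableIOError(f"id column {id_column!r} not found in {path.name}")
    ids = raw[id_column].tolist()
    smiles = raw[smiles_column].tolist() if smiles_column in raw.columns else None
    if target_column is not None and target_column not in raw.columns:
        target_column = None

    desc_cols = [
        c for c in raw.columns if c not in {id_column, smiles_column, target_column}
    ]
    data: dict[str, np.ndarray] = {}
    for col in desc_cols:
        data[col] = _parse_numeric(raw[col], col, path.name)
    X = pd.DataFrame(data, columns=desc_cols)
    y = (
        _parse_numeric(raw[target_column], target_column, path.name)
        if target_column is not None
        else None
    )
    return DescriptorTable(ids=ids, X=X, y=y, smiles=smiles)


def _parse_numeric(series: pd.Series, col: str, fname: str) -> np.ndarray:
    out = np.empty(len(series), dtype=float)
    for i, cell in enumerate(series):
        text = cell.strip()
        if text in MISSING_MARKERS:
            out[i] = np.nan
            continue
        try:
            out[i] = float(text)
        except ValueError:
            raise TableIOError(
                f"{fname}: non-numeric value {cell!r} in column {col!r}, row {i + 2}"
            ) from None
    return out


def write_table(table: DescriptorTable, path: str | Path, target_column: str = "logS") -> None:
    """Write a :class:`DescriptorTable` to CSV (round-trips with :func:`read_table`)."""
    frame = pd.DataFrame({"compound_id": table.ids})
    if table.smiles is not None:
        frame["smiles"] = table.smiles
    if table.y is not None:
        frame[target_column] = table.y
    frame = pd.concat([frame, table.X.reset_index(drop=True)], axis=1)
    frame.to_csv(path, index=False)


def read_smi(path: str | Path) -> list[tuple[str, str | None]]:
    """Read a .smi file: one whitespace-separated ``SMILES [ID]`` per line."""
    entries: list[tuple[str, str | None]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        entries.append((parts[0], parts[1] if len(parts) > 1 else None))
    return entries


def fit_preprocessor(train: DescriptorTable) -> PreprocessModel:
    """Fit column removal + centring/scaling on the training rows only.

    Removes every descriptor with at least one missing or non-finite value
    on the training rows, and every descriptor with a single unique value
    (which includes zero-variance columns).  Scale is the sample standard
    deviation (n−1 denominator).
    """
    if len(train) < 2:
        raise DegenerateInputError("need ≥2 training rows to fit a preprocessor")
    kept: list[str] = []
    means: list[float] = []
    scales: list[float] = []
    for col in train.X.columns:
        values = train.X[col].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            continue
        if np.unique(values).size < 2:
            continue
        sd = float(values.std(ddof=1))
        if sd <= 0.0:
            continue
        kept.append(col)
        means.append(float(values.mean()))
        scales.append(sd)
    if not kept:
        raise DegenerateInputError("all descriptor columns were removed by preprocessing")
    return PreprocessModel(
        kept_columns=kept, means=np.asarray(means), scales=np.asarray(scales)
    )


def apply_preprocessor(model: PreprocessModel, table: DescriptorTable) -> np.ndarray:
    """Return ``(x − mean) / scale`` for the kept columns, training statistics only."""
    missing = [c for c in model.kept_columns if c not in table.X.columns]
    if missing:
        raise SchemaError(f"table lacks kept columns: {missing}")
    X = table.X[model.kept_columns].to_numpy(dtype=float)
    return (X - model.means) / model.scales


def sequential_split(
    table: DescriptorTable, rule: SplitRule
) -> tuple[np.ndarray, np.ndarray]:
    """Split rows by the sequential rule; returns 0-based (train_idx, test_idx).

    Test rows are those whose 1-based position is congruent to one of
    ``rule.start_offsets`` modulo ``rule.period``.  Nested rules then move
    the rows they select *within the test subset's own order* back to the
    training side.  Train and test always partition the table.
    """
    n = len(table)
    if n == 0:
        raise DegenerateInputError("cannot split an empty table")
    test_mask = np.zeros(n, dtype=bool)
    for pos in range(1, n + 1):
        r = pos % rule.period
        for off in rule.start_offsets:
            if r == off % rule.period:
                test_mask[pos - 1] = True
    test_idx = np.flatnonzero(test_mask)
    for nested in rule.nested_rules:
        if len(test_idx) == 0:
            break
        back = set()
        for sub_pos in range(1, len(test_idx) + 1):
            r = sub_pos % nested.period
            for off in nested.start_offsets:
                if r == off % nested.period:
                    back.add(sub_pos - 1)
        test_idx = np.array(
            [row for j, row in enumerate(test_idx) if j not in back], dtype=int
        )
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    train_idx = np.flatnonzero(~test_mask)
    if len(test_idx) == 0 or len(train_idx) == 0:
        raise DegenerateInputError(
            f"degenerate split: {len(train_idx)} train / {len(test_idx)} test rows"
        )
    return train_idx, test_idx
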