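"""2D molecular descriptor matrices with training-range bookkeeping.

The descriptor catalogue is RDKit's full 2D set (~210 descriptors), the
open equivalent of the commercial 2D descriptor blocks used in QSAR work.
A :class:`DescriptorMatrix` additionally carries per-feature (min, max)
ranges frozen on a designated training set; predictions whose features
fall outside these ranges are extrapolations of the model (the range-based
applicability domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")


class DescriptorError(ValueError):
    pass


def descriptor_names() -> list[str]:
    """Names of the full 2D descriptor catalogue, in fixed canonical order."""
    return [name for name, _ in Descriptors._descList]


@dataclass
class DescriptorMatrix:
    """Molecules x named 2D descriptors.

    ``ranges`` and ``medians`` are populated only on matrices designated as
    training data (via :meth:`freeze_training_stats`) and are copied onto
    matrices derived from them, so applicability checks and imputation
    always refer to the training distribution.
    """

    ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # shape (n_molecules, n_features), float, NaN = missing
    ranges: dict[str, tuple[float, float]] | None = None
    medians: dict[str, float] | None = None
    errors: list[tuple[str, str]] = field(default_factory=list)  # (id, message)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.feature_names)):
            raise DescriptorError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.ids)} molecules x {len(self.feature_names)} features"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.feature_names)

    def freeze_training_stats(self) -> None:
        """Record per-feature (min, max) and medians from this matrix."""
        with np.errstate(all="ignore"):
            mins = np.nanmin(self.values, axis=0)
            maxs = np.nanmax(self.values, axis=0)
            meds = np.nanmedian(self.values, axis=0)
        self.ranges = {n: (float(lo), float(hi)) for n, lo, hi in zip(self.feature_names, mins, maxs)}
        self.medians = {n: float(m) for n, m in zip(self.feature_names, meds)}

    def subset(self, feature_names: Sequence[str]) -> "DescriptorMatrix":
        idx = [self.feature_names.index(n) for n in feature_names]
        return DescriptorMatrix(
            ids=list(self.ids),
            feature_names=list(feature_names),
            values=self.values[:, idx],
            ranges=None if self.ranges is None else {n: self.ranges[n] for n in feature_names},
            medians=None if self.medians is None else {n: self.medians[n] for n in feature_names},
            errors=list(self.errors),
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "molecule_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            ids=[str(i) for i in df.index],
            feature_names=list(df.columns),
            values=df.to_numpy(dtype=float),
        )


def compute_descriptors(
    smiles: Sequence[str],
    *,
    ids: Sequence[str] | None = None,
    names: Sequence[str] | None = None,
) -> DescriptorMatrix:
    """Compute the 2D descriptor matrix for a list of SMILES.

    One row per input molecule in input order.  Invalid SMILES produce an
    all-NaN row plus an error entry; individual descriptor failures become
    NaN (missing) values.  The computation is a pure function of the
    (SMILES, descriptor set) pair.
    """
    all_names = descriptor_names()
    if names is None:
        names = all_names
    else:
        unknown = set(names) - set(all_names)
        if unknown:
            raise DescriptorError(f"unknown descriptors requested: {sorted(unknown)}")
        names = list(names)
    if ids is None:
        ids = [str(i) for i in range(len(smiles))]
    col = {n: j for j, n in enumerate(names)}
    values = np.full((len(smiles), len(names)), np.nan)
    errors: list[tuple[str, str]] = []
    for i, (mol_id, smi) in enumerate(zip(ids, smiles)):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            errors.append((str(mol_id), f"invalid SMILES: {smi!r}"))
            continue
        calc = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan, silent=True)
        for n, v in calc.items():
            j = col.get(n)
            if j is not None:
                values[i, j] = v
    values[~np.isfinite(values)] = np.nan
    return DescriptorMatrix(
        ids=[str(i) for i in ids], feature_names=list(names), values=values, errors=errors
    )


@dataclass
class CleaningReport:
    dropped_constant: list[str]
    dropped_missing: list[str]


def clean_descriptors(
    matrix: DescriptorMatrix, *, max_missing_fraction: float = 0.2
) -> tuple[DescriptorMatrix, CleaningReport]:
    """Drop constant and mostly-missing columns; impute the rest by median.

    Intended for training matrices: the surviving medians are frozen into
    the returned matrix (together with training ranges) so that test-set
    imputation reuses training statistics rather than leaking test values.
    """
    if len(matrix.ids) == 0:
        raise DescriptorError("cannot clean an empty descriptor matrix")
    vals = matrix.values
    missing_frac = np.mean(np.isnan(vals), axis=0)
    with np.errstate(all="ignore"):
        col_min = np.nanmin(np.where(np.isnan(vals), np.inf, vals), axis=0)
        col_max = np.nanmax(np.where(np.isnan(vals), -np.inf, vals), axis=0)
    all_missing = missing_frac >= 1.0
    constant = (col_min == col_max) & ~all_missing
    too_missing = (missing_frac > max_missing_fraction) & ~all_missing

    keep = ~(constant | too_missing | all_missing)
    if not keep.any():
        raise DescriptorError("descriptor cleaning removed every column")
    report = CleaningReport(
        dropped_constant=[n for n, c in zip(matrix.feature_names, constant) if c],
        dropped_missing=[
            n for n, m, a in zip(matrix.feature_names, too_missing, all_missing) if m or a
        ],
    )
    kept_names = [n for n, k in zip(matrix.feature_names, keep) if k]
    kept = vals[:, keep].copy()
    medians = np.nanmedian(kept, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(kept))
    kept[nan_rows, nan_cols] = medians[nan_cols]
    cleaned = DescriptorMatrix(
        ids=list(matrix.ids),
        feature_names=kept_names,
        values=kept,
        errors=list(matrix.errors),
    )
    cleaned.freeze_training_stats()
    return cleaned, report


def apply_training_stats(
    matrix: DescriptorMatrix, training: DescriptorMatrix
) -> DescriptorMatrix:
    """Project *matrix* onto the training feature set, imputing missing
    values with the training medians."""
    if training.medians is None or training.ranges is None:
        raise DescriptorError("training matrix has no frozen statistics")
    sub = matrix.subset(training.feature_names)
    meds = np.array([training.medians[n] for n in training.feature_names])
    vals = sub.values.copy()
    nan_rows, nan_cols = np.where(np.isnan(vals))
    vals[nan_rows, nan_cols] = meds[nan_cols]
    return DescriptorMatrix(
        ids=sub.ids,
        feature_names=sub.feature_names,
        values=vals,
        ranges=dict(training.ranges),
        medians=dict(training.medians),
        errors=sub.errors,
    )
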