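"""Relative quantification from qPCR Ct tables by the comparative-Ct method.

For each sample and target assay, replicate Cts are averaged, the internal
control assay's mean Ct is subtracted (dCt), the calibrator sample's dCt is
subtracted in turn (ddCt), and the relative quantity is 2^-ddCt — assuming
perfect doubling per cycle.  Applied to genomic DNA against a two-copy
calibrator this yields relative copy number (RCN = 1 means two copies); the
identical arithmetic on cDNA with an expression normaliser gives fold change.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GAIN, LOSS, NORMAL

DEFAULT_GAIN_CUT = 1.4
DEFAULT_LOSS_CUT = 0.6


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Per-sample ddCt chain output for one target assay."""

    sample: str
    assay: str
    delta_ct: float
    delta_delta_ct: float
    rcn: float
    cn_type: str

    def __post_init__(self) -> None:
        if self.rcn <= 0:
            raise ValueError("relative copy number must be positive")


def classify_type(
    rcn: float,
    gain_cut: float = DEFAULT_GAIN_CUT,
    loss_cut: float = DEFAULT_LOSS_CUT,
) -> str:
    """Type an RCN against the two-copy reference: gain, loss, or normal.

    Default cuts 1.4 / 0.6 sit near the midpoints between the two-copy RCN of
    1 and the ideal three-copy (1.5) and one-copy (0.5) values, widened for
    replicate noise; both are configurable.
    """
    if not (loss_cut < 1.0 < gain_cut):
        raise ValueError("cuts must satisfy loss_cut < 1 < gain_cut")
    if rcn <= 0:
        raise ValueError("RCN must be positive")
    if rcn >= gain_cut:
        return GAIN
    if rcn <= loss_cut:
        return LOSS
    return NORMAL


def _mean_cts(wells: pd.DataFrame) -> pd.Series:
    required = {"sample", "assay", "ct"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(wells["ct"])) or (wells["ct"] <= 0).any():
        raise ValueError("Ct values must be positive and finite")
    return wells.groupby(["sample", "assay"])["ct"].mean()


def relative_copy_number(
    wells: pd.DataFrame,
    calibrator: str,
    control_assay: str,
    gain_cut: float = DEFAULT_GAIN_CUT,
    loss_cut: float = DEFAULT_LOSS_CUT,
) -> list[CopyNumberEstimate]:
    """2^-ddCt relative copy number for every sample and target assay.

    Replicates are averaged before differencing.  Samples missing the control
    assay are skipped with a warning; the calibrator must carry both target
    and control measurements.
    """
    mean_ct = _mean_cts(wells)
    assays = wells["assay"].unique()
    targets = [a for a in assays if a != control_assay]
    if not targets:
        raise ValueError("no target assays in the well table")
    if (calibrator, control_assay) not in mean_ct.index:
        raise ValueError(f"calibrator {calibrator!r} lacks the control assay")
    out: list[CopyNumberEstimate] = []
    for assay in targets:
        if (calibrator, assay) not in mean_ct.index:
            raise ValueError(f"calibrator {calibrator!r} lacks target assay {assay!r}")
        cal_dct = mean_ct[(calibrator, assay)] - mean_ct[(calibrator, control_assay)]
        for sample in wells["sample"].unique():
            if (sample, assay) not in mean_ct.index:
                continue
            if (sample, control_assay) not in mean_ct.index:
                warnings.warn(f"sample {sample!r} lacks control assay; skipped", stacklevel=2)
                continue
            dct = mean_ct[(sample, assay)] - mean_ct[(sample, control_assay)]
            ddct = dct - cal_dct
            rcn = float(2.0 ** (-ddct))
            out.append(
                CopyNumberEstimate(
                    sample=str(sample),
                    assay=str(assay),
                    delta_ct=float(dct),
                    delta_delta_ct=float(ddct),
                    rcn=rcn,
                    cn_type=classify_type(rcn, gain_cut, loss_cut),
                )
            )
    return out


def expression_fold_change(
    wells: pd.DataFrame,
    calibrator: str,
    normalizer_assay: str,
) -> dict[str, float]:
    """2^-ddCt expression fold change per sample against the calibrator.

    Mathematically identical to :func:`relative_copy_number` with the
    expression normaliser as control; returned as sample -> fold change for
    the single target assay in the table.
    """
    est = relative_copy_number(wells, calibrator, normalizer_assay)
    assays = {e.assay for e in est}
    if len(assays) != 1:
        raise ValueError(f"expected exactly one target assay, found {sorted(assays)}")
    return {e.sample: e.rcn for e in est}


@dataclass(frozen=True)
class GroupContrast:
    """Welch t-test between the fold changes of two CNV-type groups."""

    type_a: str
    type_b: str
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float


def compare_groups(
    fold_changes: Mapping[str, float],
    types: Mapping[str, str],
    min_n: int = 2,
) -> list[GroupContrast]:
    """Pairwise two-sided Welch t-tests of fold change between CNV types.

    Types with fewer than ``min_n`` samples are skipped with a warning.  Two
    identical groups report t = 0, p = 1 (including the zero-variance case).
    """
    by_type: dict[str, list[float]] = {}
    for sample, fc in fold_changes.items():
        if sample not in types:
            raise ValueError(f"sample {sample!r} has no CNV type")
        by_type.setdefault(types[sample], []).append(fc)
    usable = []
    for t, vals in sorted(by_type.items()):
        if len(vals) < min_n:
            warnings.warn(f"type {t!r} has fewer than {min_n} samples; skipped", stacklevel=2)
        else:
            usable.append(t)
    out = []
    for ta, tb in itertools.combinations(usable, 2):
        a = np.asarray(by_type[ta], dtype=float)
        b = np.asarray(by_type[tb], dtype=float)
        if np.var(a) == 0 and np.var(b) == 0:
            tstat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            tstat, p = stats.ttest_ind(a, b, equal_var=False)
        out.append(GroupContrast(ta, tb, len(a), len(b), float(tstat), float(p)))
    return out
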