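"""Reduce masked connectivity matrices to per-subject hemispheric summaries.

For every subject and modality, the masked connectivity entries are averaged
within the three edge compartments (left, right, interhemispheric).  Patient
summaries are then relabelled relative to the lesioned hemisphere
(ipsilesional / contralesional); controls receive the mean of their left-
and right-hemispheric values as a "healthy" baseline for both.  Group-wise
outlier correction replaces values deviating more than a threshold (default
2.5) of standard deviations from the group mean by the most extreme
non-outlier value in the same direction (a nearest-rank winsorization).

The result is the 9-variable analysis table: {EW, FA, FC} x
{ipsilesional, contralesional, interhemispheric}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, EdgeMask
from .parcellation import (CODE_INTER, CODE_INTRA_LEFT, CODE_INTRA_RIGHT,
                           AtlasDefinition, compartment_codes)

GROUPS = ("control", "IDHmut", "IDHwt")
MODALITIES = ("EW", "FA", "FC")
ANALYSIS_COMPARTMENTS = ("ipsi", "contra", "inter")

#: column order of the written summary CSV
SUMMARY_COLUMNS = ["subject_id", "group", "age", "sex"] + [
    f"{m}_{c}" for m in MODALITIES for c in ANALYSIS_COMPARTMENTS]


class SummaryError(ValueError):
    """Raised when subject metadata or summary assembly is invalid."""


class EmptyCompartmentError(SummaryError):
    """A compartment has no contributing edges for some subject/modality."""


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and grouping for one subject."""

    subject_id: str
    group: str
    lesion_hemisphere: str
    age: float
    sex: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SummaryError(f"unknown group {self.group!r}")
        if self.lesion_hemisphere not in ("left", "right", "none"):
            raise SummaryError(
                f"unknown lesion hemisphere {self.lesion_hemisphere!r}")
        if (self.group == "control") != (self.lesion_hemisphere == "none"):
            raise SummaryError(
                f"subject {self.subject_id}: lesion_hemisphere must be 'none' "
                "exactly for controls")
        if not 18 <= self.age < 80:
            raise SummaryError(
                f"subject {self.subject_id}: age {self.age} outside [18, 80)")
        if self.sex not in ("m", "f"):
            raise SummaryError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class HemisphericMeans:
    """Compartment means plus the number of contributing edges in each."""

    left: float
    right: float
    inter: float
    n_left: int
    n_right: int
    n_inter: int


@dataclass(frozen=True)
class LesionMeans:
    """Compartment means relabelled relative to the lesioned hemisphere."""

    ipsi: float
    contra: float
    inter: float


def hemispheric_means(matrix: ConnectivityMatrix, mask: EdgeMask,
                      atlas: AtlasDefinition) -> HemisphericMeans:
    """Unweighted compartment means over masked-in, non-missing edges.

    Edges that are masked-in but missing for this subject (e.g. FA of a pair
    this subject has no streamline for) are omitted and the contributing-edge
    count reduced accordingly.  An empty compartment raises.
    """
    if matrix.n_regions != atlas.n_regions or mask.n_regions != atlas.n_regions:
        raise SummaryError("matrix, mask and atlas dimensions disagree")
    codes = compartment_codes(atlas)
    upper = np.triu(np.ones_like(mask.eligible), k=1).astype(bool)
    use = mask.eligible & upper & ~np.isnan(matrix.values)
    out = {}
    for name, code in (("left", CODE_INTRA_LEFT), ("right", CODE_INTRA_RIGHT),
                       ("inter", CODE_INTER)):
        sel = use & (codes == code)
        n = int(sel.sum())
        if n == 0:
            raise EmptyCompartmentError(
                f"subject {matrix.subject_id!r}: no contributing edges for "
                f"{matrix.modality} in compartment {name!r}")
        out[name] = float(matrix.values[sel].mean())
        out[f"n_{name}"] = n
    return HemisphericMeans(**out)


def relabel_lesion(means: HemisphericMeans,
                   subject: SubjectRecord) -> LesionMeans:
    """Map left/right means to ipsi-/contralesional for a patient."""
    if subject.group == "control":
        raise SummaryError("controls have no lesion; use control_baseline")
    if subject.lesion_hemisphere == "left":
        return LesionMeans(ipsi=means.left, contra=means.right,
                           inter=means.inter)
    return LesionMeans(ipsi=means.right, contra=means.left, inter=means.inter)


def control_baseline(means: HemisphericMeans) -> LesionMeans:
    """Healthy baseline: the left/right mean stands in for ipsi and contra."""
    baseline = (means.left + means.right) / 2.0
    return LesionMeans(ipsi=baseline, contra=baseline, inter=means.inter)


def outlier_correct(values, sd_threshold: float = 2.5):
    """Single-pass group-wise outlier replacement.

    Values deviating strictly more than ``sd_threshold`` sample standard
    deviations (n-1 denominator) from the group mean are replaced by the most
    extreme non-outlier value in the same direction.  Statistics come from
    the uncorrected data; no re-iteration.  Returns ``(corrected, flags)``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise SummaryError("outlier correction needs >= 3 values per group")
    flags = np.zeros(len(values), dtype=bool)
    sd = values.std(ddof=1)
    if sd == 0:
        return values.copy(), flags
    mean = values.mean()
    high = values > mean + sd_threshold * sd
    low = values < mean - sd_threshold * sd
    flags = high | low
    corrected = values.copy()
    if flags.any():
        keep = values[~flags]
        if high.any():
            corrected[high] = keep.max()
        if low.any():
            corrected[low] = keep.min()
    return corrected, flags


def assemble_cohort_table(subjects, subject_means,
                          sd_threshold: float = 2.5):
    """Build the outlier-corrected 9-variable cohort table.

    ``subject_means`` maps subject_id -> {modality: HemisphericMeans}.  The
    returned frame is ordered by subject_id and carries, besides the 9
    ipsi/contra/inter analysis columns, the raw left/right means (needed for
    the control-group coherence profiles, which the study reports on
    left/right rather than baseline-averaged variables).  Outlier correction
    is applied per group and per column; the second return value maps column
    name -> list of flagged subject_ids.
    """
    rows = []
    for subj in sorted(subjects, key=lambda s: s.subject_id):
        try:
            means = subject_means[subj.subject_id]
        except KeyError:
            raise SummaryError(f"no summary values for subject "
                               f"{subj.subject_id!r}") from None
        row = {"subject_id": subj.subject_id, "group": subj.group,
               "age": subj.age, "sex": subj.sex}
        for modality in MODALITIES:
            if modality not in means:
                raise SummaryError(
                    f"subject {subj.subject_id!r} lacks {modality} means")
            hm = means[modality]
            lm = (control_baseline(hm) if subj.group == "control"
                  else relabel_lesion(hm, subj))
            for comp in ANALYSIS_COMPARTMENTS:
                value = getattr(lm, comp)
                if value is None or np.isnan(value):
                    raise SummaryError(
                        f"subject {subj.subject_id!r}: missing value for "
                        f"{modality}_{comp}")
                row[f"{modality}_{comp}"] = value
            row[f"{modality}_left"] = hm.left
            row[f"{modality}_right"] = hm.right
        rows.append(row)
    table = pd.DataFrame(rows).reset_index(drop=True)
    value_columns = [c for c in table.columns
                     if c.split("_")[0] in MODALITIES]
    flags: dict[str, list[str]] = {}
    for column in value_columns:
        for group in table["group"].unique():
            sel = (table["group"] == group).to_numpy()
            if sel.sum() < 3:
                continue    # outlier statistics undefined for tiny groups
            corrected, flagged = outlier_correct(
                table.loc[sel, column].to_numpy(), sd_threshold)
            table.loc[sel, column] = corrected
            if flagged.any():
                flags.setdefault(column, []).extend(
                    table.loc[sel, "subject_id"].to_numpy()[flagged].tolist())
    return table, flags
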