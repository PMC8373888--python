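"""Per-subject connectivity matrices: edge weight, FA and functional.

Three modality-tagged symmetric matrices are built over the atlas regions:

* ``EW`` — normalized streamline count: the number of streamlines between a
  region pair divided by the mean number of streamlines touching either
  region, ``EW_ij = N_ij / ((S_i + S_j) / 2)`` with ``S_i = sum_k N_ik``.
  Always in [0, 1] because ``S_i >= N_ij`` and ``S_j >= N_ij``.
* ``FA`` — per-edge mean fractional anisotropy of the connecting
  streamlines; undefined (missing) where no streamline connects the pair.
* ``FC`` — Fisher-z-transformed zero-lag Pearson correlation between the
  regions' BOLD time series.

Analysis eligibility is decided once, from the control cohort: only edges
carrying at least one streamline in *every* control subject enter any
analysis (the edge mask); the mask is then applied uniformly to all
subjects and all three modalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Missing-value marker used throughout the connectivity containers.
MISSING = np.nan

MODALITIES = ("EW", "FA", "FC")

#: correlations are clamped to +/-(1 - CLAMP_EPS) before the Fisher transform
CLAMP_EPS = 1e-12


class MatrixValidationError(ValueError):
    """Raised when an input matrix violates its container invariants."""


def _check_square_symmetric(values: np.ndarray, what: str,
                            tol: float = 0.0) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MatrixValidationError(f"{what}: expected a square matrix, "
                                    f"got shape {values.shape}")
    finite = np.nan_to_num(values)
    if not np.allclose(finite, finite.T, atol=tol, rtol=0.0):
        raise MatrixValidationError(f"{what}: matrix is not symmetric")
    # nan pattern must be symmetric too
    if not np.array_equal(np.isnan(values), np.isnan(values).T):
        raise MatrixValidationError(f"{what}: missing pattern is asymmetric")


@dataclass(frozen=True)
class StreamlineCountMatrix:
    """Symmetric non-negative integer streamline counts, zero diagonal."""

    counts: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        _check_square_symmetric(counts, "streamline counts")
        if np.any(counts < 0):
            raise MatrixValidationError("streamline counts must be >= 0")
        if np.any(counts != np.round(counts)):
            raise MatrixValidationError("streamline counts must be integers")
        if np.any(np.diagonal(counts) != 0):
            raise MatrixValidationError("streamline counts diagonal must be 0")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        """Region strength S_i = total streamlines touching region i."""
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class FAEdgeMatrix:
    """Per-edge mean FA in [0, 1]; missing (NaN) where no streamline exists."""

    fa: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        fa = np.asarray(self.fa, dtype=float)
        _check_square_symmetric(fa, "FA edges")
        defined = ~np.isnan(fa)
        if np.any((fa[defined] < 0.0) | (fa[defined] > 1.0)):
            raise MatrixValidationError("FA values must lie in [0, 1]")
        object.__setattr__(self, "fa", fa)

    @property
    def n_regions(self) -> int:
        return self.fa.shape[0]


@dataclass(frozen=True)
class RoiTimeSeries:
    """T x R matrix of regional BOLD time series (rows are time points)."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise MatrixValidationError("time series must be a T x R matrix")
        if values.shape[0] < 3:
            raise MatrixValidationError(
                f"need at least 3 time points, got {values.shape[0]}")
        if not np.all(np.isfinite(values)):
            raise MatrixValidationError("time series contain non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Modality-tagged symmetric connectivity with NaN missing markers."""

    modality: str
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise MatrixValidationError(
                f"unknown modality {self.modality!r}; expected {MODALITIES}")
        values = np.asarray(self.values, dtype=float)
        _check_square_symmetric(values, f"{self.modality} connectivity",
                                tol=1e-12)
        if not np.all(np.isnan(np.diagonal(values))):
            raise MatrixValidationError("diagonal must be marked missing")
        object.__setattr__(self, "values", values)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EdgeMask:
    """Analysis-eligible edges: present in every provenance control subject."""

    eligible: np.ndarray
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        eligible = np.asarray(self.eligible, dtype=bool)
        _check_square_symmetric(eligible.astype(float), "edge mask")
        if np.any(np.diagonal(eligible)):
            raise MatrixValidationError("edge mask diagonal must be False")
        object.__setattr__(self, "eligible", eligible)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def n_regions(self) -> int:
        return self.eligible.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.eligible.sum()) // 2


def edge_weight_matrix(counts: StreamlineCountMatrix) -> ConnectivityMatrix:
    """Normalized streamline counts EW_ij = N_ij / ((S_i + S_j) / 2).

    Pairs where both regions are isolated (S_i + S_j = 0) get EW = 0 with a
    logged warning; the diagonal is marked missing.
    """
    n = counts.counts.astype(float)
    s = counts.strengths.astype(float)
    denom = (s[:, None] + s[None, :]) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ew = np.where(denom > 0, n / np.where(denom > 0, denom, 1.0), 0.0)
    isolated = s == 0
    if isolated.any():
        logger.warning(
            "subject %s: %d isolated region(s) (zero streamlines); their "
            "edge weights are set to 0", counts.subject_id, isolated.sum())
    np.fill_diagonal(ew, MISSING)
    return ConnectivityMatrix("EW", ew, counts.subject_id)


def fc_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Fisher-z functional connectivity from regional time series.

    Zero-lag Pearson correlation between every pair of regional series,
    clamped to +/-(1 - 1e-12) and Fisher z-transformed (atanh).  Regions with
    zero temporal variance yield missing rows/columns with a logged warning.
    """
    x = ts.values
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "subject %s: %d region(s) with constant signal; their functional "
            "connectivity is undefined", ts.subject_id, int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[degenerate, :] = MISSING
    r[:, degenerate] = MISSING
    limit = 1.0 - CLAMP_EPS
    n_clamped = int(np.sum(np.abs(r[~np.isnan(r)]) > limit))
    n_clamped -= x.shape[1] - int(degenerate.sum())  # diagonal ones
    if n_clamped > 0:
        logger.warning("subject %s: clamped %d near-perfect correlation(s) "
                       "before the Fisher transform", ts.subject_id, n_clamped)
    r = np.clip(r, -limit, limit)
    z = np.arctanh(r)
    np.fill_diagonal(z, MISSING)
    return ConnectivityMatrix("FC", z, ts.subject_id)


def fa_connectivity(fa: FAEdgeMatrix,
                    counts: StreamlineCountMatrix | None = None
                    ) -> ConnectivityMatrix:
    """Wrap a validated FA edge matrix as a connectivity matrix.

    If ``counts`` is supplied, FA must be defined exactly where at least one
    streamline connects the pair (off-diagonal), and missing elsewhere.
    """
    values = fa.fa.copy()
    np.fill_diagonal(values, MISSING)
    if counts is not None:
        if counts.n_regions != fa.n_regions:
            raise MatrixValidationError("FA and count dimensions differ")
        off = ~np.eye(fa.n_regions, dtype=bool)
        support = counts.counts > 0
        defined = ~np.isnan(values)
        if np.any(defined[off] != support[off]):
            raise MatrixValidationError(
                "FA must be defined exactly where streamline count > 0")
    return ConnectivityMatrix("FA", values, fa.subject_id)


def control_edge_mask(control_counts) -> EdgeMask:
    """Edges connected by >= 1 streamline in every control subject."""
    control_counts = list(control_counts)
    if not control_counts:
        raise MatrixValidationError("need at least one control subject")
    n_regions = control_counts[0].n_regions
    eligible = np.ones((n_regions, n_regions), dtype=bool)
    for c in control_counts:
        if c.n_regions != n_regions:
            raise MatrixValidationError(
                f"control {c.subject_id!r} has {c.n_regions} regions, "
                f"expected {n_regions}")
        eligible &= c.counts > 0
    np.fill_diagonal(eligible, False)
    return EdgeMask(eligible, tuple(c.subject_id for c in control_counts))


def restrict(matrix: ConnectivityMatrix, mask: EdgeMask) -> ConnectivityMatrix:
    """Mark entries outside the edge mask missing; mask-in entries unchanged."""
    if matrix.n_regions != mask.n_regions:
        raise MatrixValidationError(
            f"matrix has {matrix.n_regions} regions but mask has "
            f"{mask.n_regions}")
    values = np.where(mask.eligible, matrix.values, MISSING)
    return ConnectivityMatrix(matrix.modality, values, matrix.subject_id)
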