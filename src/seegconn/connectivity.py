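"""Pearson functional-connectivity matrices and per-patient scalar features.

Functional connectivity between two sampled brain areas is the Pearson
correlation coefficient of their (preprocessed) traces.  Each patient yields
one connectivity matrix per interictal segment; the segment matrices are
averaged elementwise, contacts are reduced to the 9-region temporal-lobe
parcellation, and the patient is summarised by two numbers — the mean and the
standard deviation of the off-diagonal entries — which serve as the (x, y)
coordinates for outcome classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import REGIONS, ChannelInfo, FlatChannelError

__all__ = [
    "ConnectivityMatrix",
    "PatientFeatures",
    "pearson_matrix",
    "average_matrices",
    "contacts_to_regions",
    "offdiagonal_features",
    "group_region_pair_means",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric labeled matrix of Pearson coefficients.

    Invariants, enforced on construction: unit diagonal, entries in [−1, 1],
    symmetry to 1e−12.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValueError("connectivity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12, rtol=0.0):
            raise ValueError("connectivity matrix diagonal must be 1")
        if v.min() < -1.0 - 1e-9 or v.max() > 1.0 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v
        self.labels = list(self.labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class PatientFeatures:
    """Per-patient connectivity summary and surgical outcome.

    ``outcome=True`` means seizure freedom one year after temporal lobectomy.
    """

    patient_id: str
    mean_connectivity: float
    sd_connectivity: float
    outcome: bool

    def __post_init__(self):
        if not -1.0 <= self.mean_connectivity <= 1.0:
            raise ValueError("mean_connectivity must lie in [-1, 1]")
        if self.sd_connectivity < 0.0:
            raise ValueError("sd_connectivity must be non-negative")


def pearson_matrix(
    segment_samples: np.ndarray, labels: Sequence[str]
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of a channels × samples segment.

    Entry (i, j) is the normalised covariance of traces i and j; the diagonal
    is 1 by definition and every entry lies in [−1, 1].

    Raises
    ------
    FlatChannelError
        Naming the zero-variance channel for which the coefficient is
        undefined.
    """
    x = np.asarray(segment_samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 channels")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples per channel")
    if len(labels) != x.shape[0]:
        raise ValueError("one label per channel required")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        names = ", ".join(str(labels[i]) for i in flat)
        raise FlatChannelError(f"zero-variance channel(s): {names}")
    c = np.corrcoef(x)
    return ConnectivityMatrix(list(labels), c)


def average_matrices(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise arithmetic mean of raw (signed) coefficients.

    All inputs must share labels; no Fisher z-transform is applied.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    ref = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != ref:
            raise ValueError(
                f"label mismatch: {sorted(set(ref) ^ set(m.labels))} "
                "not shared by all matrices"
            )
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(list(ref), mean)


def contacts_to_regions(
    contact_matrix: ConnectivityMatrix, channel_infos: Sequence[ChannelInfo]
) -> ConnectivityMatrix:
    """Reduce a contact-level matrix to the 9-region parcellation.

    Each distinct region pair gets the mean of all contact-level coefficients
    whose two contacts lie in those two regions; the region diagonal is set to
    1; regions with no contacts are absent from the output.  Region order
    follows the canonical parcellation order.
    """
    if len(channel_infos) != contact_matrix.n:
        raise ValueError("one ChannelInfo per matrix row required")
    region_of = [ci.region for ci in channel_infos]
    present = [r for r in REGIONS if r in region_of]
    idx = {r: [i for i, q in enumerate(region_of) if q == r] for r in present}
    k = len(present)
    out = np.eye(k)
    v = contact_matrix.values
    for a in range(k):
        for b in range(a + 1, k):
            block = v[np.ix_(idx[present[a]], idx[present[b]])]
            out[a, b] = out[b, a] = block.mean()
    return ConnectivityMatrix(present, out)


def offdiagonal_features(matrix: ConnectivityMatrix) -> tuple[float, float]:
    """Mean and SD of the off-diagonal entries (each unordered pair once).

    The SD uses the sample (n−1) denominator; a 2×2 matrix, with a single
    pair, has SD 0 by convention.
    """
    v = matrix.values
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least a 2×2 matrix")
    upper = v[np.triu_indices(n, k=1)]
    mean = float(upper.mean())
    sd = 0.0 if upper.size == 1 else float(upper.std(ddof=1))
    return mean, sd


def group_region_pair_means(
    region_matrices: Sequence[ConnectivityMatrix],
    outcomes: Sequence[bool],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Average each region pair across patients, separately per outcome group.

    Electrode coverage differs between patients, so each pair is averaged only
    over the patients in whom both regions were sampled.  Returns
    ``(positive_group, negative_group, presence_mask)`` as 9×9 region-labeled
    DataFrames: group entries are NaN where the pair was sampled in no patient
    of that group; the mask is True where the pair was sampled in at least one
    patient of either group.

    Raises
    ------
    ValueError
        If either outcome group is empty.
    """
    if len(region_matrices) != len(outcomes):
        raise ValueError("one outcome per matrix required")
    outcomes = [bool(o) for o in outcomes]
    if not any(outcomes) or all(outcomes):
        raise ValueError("both outcome groups must contain at least one patient")

    k = len(REGIONS)
    pos = {True: np.zeros((k, k)), False: np.zeros((k, k))}
    cnt = {True: np.zeros((k, k)), False: np.zeros((k, k))}
    ridx = {r: i for i, r in enumerate(REGIONS)}
    for m, outcome in zip(region_matrices, outcomes):
        ids = [ridx[r] for r in m.labels]
        sel = np.ix_(ids, ids)
        pos[outcome][sel] += m.values
        cnt[outcome][sel] += 1.0

    frames = {}
    for g in (True, False):
        with np.errstate(invalid="ignore"):
            mean = np.where(cnt[g] > 0, pos[g] / np.maximum(cnt[g], 1.0), np.nan)
        frames[g] = pd.DataFrame(mean, index=list(REGIONS), columns=list(REGIONS))
    mask = pd.DataFrame(
        (cnt[True] + cnt[False]) > 0, index=list(REGIONS), columns=list(REGIONS)
    )
    return frames[True], frames[False], mask
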