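"""Functional-connectome template construction and graph-distance utilities.

The analysis models tau spreading on a normative functional connectome:
subject-level region x region Fisher-Z correlation matrices are averaged
over a template cohort, thresholded to keep only the strongest connections
(30% edge density by default), and converted to a distance matrix in which
strongly connected region pairs are a short path apart.  Distances of
non-epicentre regions to a subject's tau epicentres are then the predictor
in the spreading regression.

Conventions
-----------
* Edge length of a retained connection is the inverse of its Fisher-Z
  weight, and inter-regional distance is the shortest-path length over
  those edges (Dijkstra).  Stronger connectivity therefore maps to shorter
  distance.  A one-hop variant (``multi_hop=False``) is available.
* Density thresholding ranks *signed* values: the largest positive
  correlations survive, ties at the cut are all retained.
* Distance of a region to an epicentre *set* is the arithmetic mean over
  the set by default (``agg="min"`` gives the nearest-epicentre variant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import InputError

logger = logging.getLogger(__name__)

#: r values are clipped to +/- this bound before the arctanh transform so
#: that Fisher-Z values stay finite even for (near-)identical time-series.
R_CLIP = 0.999


@dataclass
class FCMatrix:
    """Region x region matrix of Fisher-Z transformed correlations.

    Symmetric, zero diagonal, finite entries (clipping applied upstream).
    """

    values: np.ndarray
    region_ids: list = field(default_factory=list)
    subject_id: str | None = None

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class TemplateGraph:
    """Averaged FC matrix after density thresholding (edge weights >= 0 expected)."""

    values: np.ndarray
    density: float
    region_ids: list = field(default_factory=list)
    n_retained_pairs: int = 0

    def realized_density(self) -> float:
        """Fraction of off-diagonal pairs with a retained edge."""
        n = self.values.shape[0]
        total = n * (n - 1) // 2
        iu = np.triu_indices(n, k=1)
        return float(np.count_nonzero(self.values[iu])) / total


@dataclass
class DistanceConnectome:
    """Shortest-path distance matrix; unreachable pairs are NaN."""

    values: np.ndarray
    region_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.region_ids)


def fisher_z_matrix(
    timeseries: np.ndarray,
    region_ids: Sequence | None = None,
    subject_id: str | None = None,
) -> FCMatrix:
    """Compute the Fisher-Z correlation matrix of regional time-series.

    Parameters
    ----------
    timeseries : array, shape (n_regions, n_frames)
        One row per region.  At least 3 frames are required, and every
        region must have nonzero temporal variance.

    Returns
    -------
    FCMatrix
        Entry (i, j) is arctanh of the Pearson correlation of rows i and j,
        with r clipped to +/-0.999; the diagonal is 0.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise InputError("timeseries must be 2-D (regions x frames)")
    n_regions, n_frames = ts.shape
    if n_frames < 3:
        raise InputError(f"need >=3 frames to correlate, got {n_frames}")
    if region_ids is None:
        region_ids = list(range(1, n_regions + 1))
    region_ids = list(region_ids)
    if len(region_ids) != n_regions:
        raise InputError("region_ids length does not match number of rows")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [region_ids[i] for i in bad[:5]]
        raise InputError(f"zero-variance time-series for region(s) {names}")
    r = np.corrcoef(ts)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return FCMatrix(values=z, region_ids=region_ids, subject_id=subject_id)


def average_and_threshold(matrices: Sequence[FCMatrix], density: float = 0.30) -> TemplateGraph:
    """Average FC matrices element-wise and keep the strongest connections.

    The ``ceil(density * P)`` largest off-diagonal values are retained
    (``P = n(n-1)/2`` region pairs); ranking is on signed values, so at
    customary densities negative correlations are discarded.  Ties at the
    cut are all kept, making the result order-independent.
    """
    if not matrices:
        raise InputError("no matrices to average")
    if not 0.0 < density <= 1.0:
        raise InputError(f"density must be in (0, 1], got {density}")
    ref_ids = matrices[0].region_ids
    for m in matrices[1:]:
        if m.region_ids != ref_ids:
            raise InputError(
                f"region order mismatch between matrices (subject {m.subject_id!r})"
            )
    mean = np.mean([m.values for m in matrices], axis=0)
    n = mean.shape[0]
    iu = np.triu_indices(n, k=1)
    pair_values = mean[iu]
    n_pairs = pair_values.size
    k = math.ceil(density * n_pairs)
    # k-th largest value is the cut; >= keeps ties at the cut
    cutoff = np.sort(pair_values)[::-1][k - 1]
    keep = mean >= cutoff
    out = np.where(keep, mean, 0.0)
    np.fill_diagonal(out, 0.0)
    n_retained = int(np.count_nonzero(keep[iu]))
    return TemplateGraph(
        values=out, density=density, region_ids=list(ref_ids), n_retained_pairs=n_retained
    )


def to_distance(template: TemplateGraph, multi_hop: bool = True) -> DistanceConnectome:
    """Convert a thresholded template to a connectivity-based distance matrix.

    Retained edges get length 1/weight; pairwise distance is the
    shortest-path length over these edges, so strongly connected regions
    end up close together.  Unreachable pairs are flagged as NaN and
    logged.  With ``multi_hop=False`` the distance is simply the one-hop
    inverse weight (NaN where no direct edge exists).
    """
    w = template.values
    if np.any(w < 0):
        neg = np.argwhere(np.triu(w, 1) < 0)[:3]
        raise InputError(
            f"negative retained edge weight(s), e.g. at pairs {neg.tolist()}; "
            "threshold at a density that excludes negative correlations"
        )
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    if multi_hop:
        dist = dijkstra(csr_matrix(lengths), directed=False)
    else:
        dist = np.where(lengths > 0, lengths, np.inf)
        np.fill_diagonal(dist, 0.0)
    unreachable = ~np.isfinite(dist)
    np.fill_diagonal(unreachable, False)
    if unreachable.any():
        logger.warning(
            "%d region pairs unreachable in the thresholded graph; marked missing",
            int(unreachable.sum()) // 2,
        )
    dist = dist.astype(float)
    dist[unreachable] = np.nan
    np.fill_diagonal(dist, 0.0)
    return DistanceConnectome(values=dist, region_ids=list(template.region_ids))


def distance_to_epicentres(
    distances: DistanceConnectome,
    epicentre_ids: Sequence,
    agg: str = "mean",
) -> pd.Series:
    """Profile of distances from each non-epicentre region to the epicentre set.

    Returns a Series indexed by non-epicentre region id; entry r is the
    mean (or min) of the finite distances from r to the epicentre regions.
    Regions with no finite distance to any epicentre are NaN and logged.
    """
    epi = list(epicentre_ids)
    if not epi:
        raise InputError("empty epicentre set")
    ids = distances.region_ids
    index = {rid: i for i, rid in enumerate(ids)}
    missing = [e for e in epi if e not in index]
    if missing:
        raise InputError(f"epicentre ids not present in distance matrix: {missing}")
    epi_idx = [index[e] for e in epi]
    non_epi = [rid for rid in ids if rid not in set(epi)]
    rows = [index[r] for r in non_epi]
    block = distances.values[np.ix_(rows, epi_idx)]
    finite = np.isfinite(block)
    counts = finite.sum(axis=1)
    if agg == "mean":
        sums = np.where(finite, block, 0.0).sum(axis=1)
        profile = np.divide(sums, counts, out=np.full(len(rows), np.nan), where=counts > 0)
    elif agg == "min":
        masked = np.where(finite, block, np.inf).min(axis=1)
        profile = np.where(counts > 0, masked, np.nan)
    else:
        raise InputError(f"unknown aggregation {agg!r} (use 'mean' or 'min')")
    n_missing = int(np.isnan(profile).sum())
    if n_missing:
        logger.warning("%d non-epicentre regions unreachable from every epicentre", n_missing)
    return pd.Series(profile, index=pd.Index(non_epi, name="region_id"), name="distance_to_epicentres")
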