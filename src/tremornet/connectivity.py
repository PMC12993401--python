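"""Functional connectivity construction and sparsity-grid binarization.

ROI time series become Pearson correlation matrices, Fisher r-to-z transformed,
with negative values set to zero, then thresholded to binary adjacency matrices
at each density of a sparsity grid: at density s the round(s * N(N-1)/2)
strongest connections are kept as edges. A single descending ordering of the
positive connections is shared by the whole grid, so the edge sets are nested
across densities by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AtlasSpec, SubjectSession

#: |r| clip applied before artanh so perfectly correlated pairs stay finite.
_R_CLIP = 1.0 - 1e-7


def read_timeseries(path: str | Path, subject_id: str, session: str) -> SubjectSession:
    """Read one TSV time-series matrix (header row = ROI labels)."""
    df = pd.read_csv(path, sep="\t")
    return SubjectSession(subject_id, session, df.to_numpy(dtype=float))


def read_cohort(directory: str | Path) -> tuple[list[SubjectSession], AtlasSpec]:
    """Read a cohort directory written by :func:`tremornet.cohort.write_cohort`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    atlas = AtlasSpec.from_tsv(directory / "atlas.tsv")
    sessions = []
    for row in manifest.itertuples(index=False):
        ss = read_timeseries(directory / row.path, row.subject, row.session)
        if ss.n_rois != atlas.n_rois:
            raise ValueError(f"{row.path}: column count does not match atlas")
        sessions.append(ss)
    return sessions, atlas


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative Fisher-z connectivity matrix for one subject-session."""

    values: np.ndarray
    subject_id: str
    session: str

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def fc_matrix(ts: SubjectSession, roi_labels: tuple[str, ...] | None = None) -> ConnectivityMatrix:
    """Pearson correlation -> Fisher z -> clip negatives to zero.

    The diagonal is forced to zero. Off-diagonal |r| = 1 (degenerate, never seen
    on real noisy data) is clipped just below 1 with a warning so z stays finite.
    """
    x = ts.timeseries
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points for a correlation matrix")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        label = roi_labels[bad] if roi_labels else f"column {bad}"
        raise ValueError(f"constant ROI time series: {label}")
    r = np.corrcoef(x, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= _R_CLIP):
        warnings.warn("off-diagonal |r| = 1 clipped before Fisher transform")
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    z[z < 0] = 0.0
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z, ts.subject_id, ts.session)


@dataclass(frozen=True)
class SparsityGrid:
    """Inclusive density grid start, start+step, ..., stop."""

    start: float = 0.05
    stop: float = 0.50
    step: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.start < self.stop <= 1:
            raise ValueError("require 0 < start < stop <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return np.round(self.start + self.step * np.arange(n), 10)

    def __len__(self) -> int:
        return len(self.values)

    def index_of(self, density: float) -> int:
        vals = self.values
        i = int(np.argmin(np.abs(vals - density)))
        if abs(vals[i] - density) > 1e-9:
            raise ValueError(f"density {density} not on grid")
        return i


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def edge_count_at_density(n_rois: int, density: float) -> int:
    """round(s * N(N-1)/2), ties rounded half-up."""
    return _round_half_up(density * n_rois * (n_rois - 1) / 2.0)


@dataclass(frozen=True)
class AdjacencyStack:
    """Binary adjacency matrices for one subject-session across the grid.

    Stored compactly as the positive connections ordered by (weight desc,
    row asc, col asc); the slice at grid index ``k`` is the first
    ``counts[k]`` connections, so the edge sets are nested by construction.
    """

    grid: SparsityGrid
    n_rois: int
    edge_rows: np.ndarray
    edge_cols: np.ndarray
    counts: np.ndarray
    achieved: np.ndarray
    subject_id: str = ""
    session: str = ""

    def adjacency(self, k: int) -> np.ndarray:
        """Dense boolean adjacency matrix at grid index ``k``."""
        a = np.zeros((self.n_rois, self.n_rois), dtype=bool)
        c = int(self.counts[k])
        r, s = self.edge_rows[:c], self.edge_cols[:c]
        a[r, s] = True
        a[s, r] = True
        return a

    def adjacency_at_density(self, density: float) -> np.ndarray:
        return self.adjacency(self.grid.index_of(density))

    def edge_count(self, k: int) -> int:
        return int(self.counts[k])

    def average_degree(self, k: int) -> float:
        return 2.0 * self.counts[k] / self.n_rois

    def __iter__(self):
        for k in range(len(self.grid)):
            yield float(self.grid.values[k]), self.adjacency(k)


def binarize_stack(fc: ConnectivityMatrix, grid: SparsityGrid) -> AdjacencyStack:
    """Threshold the FC matrix at every grid density.

    Connections tie-break deterministically by (weight desc, row asc, col asc).
    If fewer strictly positive connections exist than a density requests, all
    positive connections are kept and the achieved density recorded.
    """
    z = fc.values
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = z[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.lexsort((ju, iu, -w))
    iu, ju = iu[order], ju[order]
    n_pos = len(iu)
    n_pairs = n * (n - 1) // 2
    counts = np.array(
        [min(edge_count_at_density(n, s), n_pos) for s in grid.values], dtype=int
    )
    achieved = counts / n_pairs
    return AdjacencyStack(
        grid=grid,
        n_rois=n,
        edge_rows=iu,
        edge_cols=ju,
        counts=counts,
        achieved=achieved,
        subject_id=fc.subject_id,
        session=fc.session,
    )


def degree_threshold(n_rois: int) -> float:
    """Minimum admissible average degree, 2 * ln(N), rounded to 2 dp."""
    return round(2.0 * math.log(n_rois), 2)


def admissibility_check(
    stacks: list[AdjacencyStack],
    sigma_curves: dict[tuple[str, str], np.ndarray] | None = None,
    sigma_min: float = 1.1,
) -> pd.DataFrame:
    """Per subject-session admissibility report for the sparsity grid.

    Checks (a) the average degree at the sparsest density against 2*ln(N) and,
    when small-world curves are supplied, (b) min sigma over the grid against
    ``sigma_min``; failing densities are listed.
    """
    rows = []
    for st in stacks:
        thr = degree_threshold(st.n_rois)
        min_degree = st.average_degree(0)
        degree_ok = bool(min_degree > thr)
        sigma = None
        if sigma_curves is not None:
            sigma = np.asarray(sigma_curves[(st.subject_id, st.session)], dtype=float)
        if sigma is not None:
            min_sigma = float(np.nanmin(sigma))
            bad = st.grid.values[np.asarray(sigma) <= sigma_min]
            sigma_ok = bool(min_sigma > sigma_min)
            failing = ";".join(f"{d:g}" for d in bad)
        else:
            min_sigma, sigma_ok, failing = np.nan, None, ""
        rows.append(
            {
                "subject": st.subject_id,
                "session": st.session,
                "n_rois": st.n_rois,
                "degree_threshold": thr,
                "min_average_degree": min_degree,
                "degree_ok": degree_ok,
                "min_sigma": min_sigma,
                "sigma_ok": sigma_ok,
                "failing_densities": failing,
            }
        )
    return pd.DataFrame(rows)


def group_mean_fc(fcs: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of Fisher-z matrices (used for the group graph)."""
    if not fcs:
        raise ValueError("no connectivity matrices given")
    n = fcs[0].n_rois
    for f in fcs:
        if f.n_rois != n:
            raise ValueError("connectivity matrices differ in size")
    mean = np.mean([f.values for f in fcs], axis=0)
    return ConnectivityMatrix(mean, "group", fcs[0].session)
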