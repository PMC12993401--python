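"""Synthetic paired-cohort generator.

Emulates a longitudinal resting-state fMRI study design: each subject is
scanned at baseline and again at follow-up, each scan yielding a T x N matrix
of parcellated ROI time series. The generative model is a block-correlated
multivariate normal: ROIs fall into K planted modules with correlation
``rho_within`` inside a module and ``rho_between`` across modules. A follow-up
effect is planted two ways: designated module *pairs* gain ``delta_rho`` of
between-module coupling, and designated *hub* ROIs gain ``delta_hub`` on all
their cross-module couplings. Both effects are absent at baseline, so every
downstream paired statistic has a known ground truth.

Per-subject heterogeneity is a small seeded jitter on the correlation levels,
identical across a subject's two sessions (a subject trait), so that under a
null design (no planted effect) the two sessions are exchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

BASELINE = "baseline"
FOLLOWUP = "followup"
SESSIONS = (BASELINE, FOLLOWUP)

# Module sizes of the full-scale (273-ROI) design; they sum to 273.
FULL_SCALE_MODULE_SIZES = (31, 33, 77, 18, 69, 45)


@dataclass(frozen=True)
class AtlasSpec:
    """Parcellation bookkeeping: ROI labels and their cerebral/cerebellar class."""

    labels: tuple[str, ...]
    roi_class: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.roi_class):
            raise ValueError("labels and roi_class must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ROI labels must be unique")
        bad = set(self.roi_class) - {"cerebral", "cerebellar"}
        if bad:
            raise ValueError(f"unknown ROI classes: {sorted(bad)}")

    @property
    def n_rois(self) -> int:
        return len(self.labels)

    @property
    def n_cerebral(self) -> int:
        return sum(c == "cerebral" for c in self.roi_class)

    @property
    def n_cerebellar(self) -> int:
        return sum(c == "cerebellar" for c in self.roi_class)

    @classmethod
    def generate(cls, n_cerebral: int = 246, n_cerebellar: int = 27) -> "AtlasSpec":
        """Build a labelled atlas with the given class counts (defaults: 246 + 27)."""
        labels = [f"CER_{i+1:03d}" for i in range(n_cerebral)]
        labels += [f"CBL_{i+1:03d}" for i in range(n_cerebellar)]
        classes = ["cerebral"] * n_cerebral + ["cerebellar"] * n_cerebellar
        return cls(tuple(labels), tuple(classes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"roi_label": self.labels, "roi_class": self.roi_class})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtlasSpec":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(tuple(df["roi_label"]), tuple(df["roi_class"]))


@dataclass(frozen=True)
class SubjectSession:
    """One subject-session: a T x N ROI time-series matrix plus identity."""

    subject_id: str
    session: str
    timeseries: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2 or ts.shape[0] < 2:
            raise ValueError("timeseries must be a T x N matrix with T >= 2")
        if not np.all(np.isfinite(ts)):
            raise ValueError("timeseries contains non-finite values")
        if np.any(ts.std(axis=0) == 0):
            raise ValueError("timeseries has a constant ROI column")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        object.__setattr__(self, "timeseries", ts)

    @property
    def n_timepoints(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_rois(self) -> int:
        return self.timeseries.shape[1]


def _default_partition(n_rois: int, sizes: tuple[int, ...]) -> tuple[int, ...]:
    if sum(sizes) != n_rois:
        raise ValueError("module sizes must sum to n_rois")
    out: list[int] = []
    for k, s in enumerate(sizes):
        out.extend([k] * s)
    return tuple(out)


@dataclass(frozen=True)
class CohortDesign:
    """Full specification of a synthetic paired cohort.

    ``planted_partition`` maps each ROI to one of K modules; ``effect_pairs``
    are 0-indexed module pairs whose between-module coupling rises by
    ``delta_rho`` at follow-up; ``hub_rois`` are ROI indices whose cross-module
    coupling rises by ``delta_hub`` at follow-up (capped below ``rho_within``).
    """

    n_subjects: int = 20
    n_timepoints: int = 150
    n_rois: int = 90
    planted_partition: tuple[int, ...] = field(
        default_factory=lambda: _default_partition(90, (15,) * 6)
    )
    rho_within: float = 0.5
    rho_between: float = 0.1
    delta_rho: float = 0.15
    effect_pairs: tuple[tuple[int, int], ...] = ((1, 3), (1, 5))
    hub_rois: tuple[int, ...] = (15, 16, 17)
    delta_hub: float = 0.15
    noise_sd: float = 0.5
    subject_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 2 or self.n_rois < 2:
            raise ValueError("cohort dimensions out of range")
        if len(self.planted_partition) != self.n_rois:
            raise ValueError("planted_partition must cover all ROIs")
        if not 0 <= self.rho_between < self.rho_within <= 1:
            raise ValueError("require 0 <= rho_between < rho_within <= 1")
        k = self.n_modules
        counts = np.bincount(np.asarray(self.planted_partition), minlength=k)
        if np.any(counts == 0):
            raise ValueError("every module must be nonempty")
        for a, b in self.effect_pairs:
            if not (0 <= a < k and 0 <= b < k and a != b):
                raise ValueError(f"invalid effect pair ({a}, {b})")
        for h in self.hub_rois:
            if not 0 <= h < self.n_rois:
                raise ValueError(f"hub ROI {h} out of range")

    @property
    def n_modules(self) -> int:
        return max(self.planted_partition) + 1

    @classmethod
    def scaled(cls, seed: int = 0, **overrides) -> "CohortDesign":
        """Scaled study design: 20 subjects, 90 ROIs (6 x 15), 150 time points."""
        return cls(seed=seed, **overrides)

    @classmethod
    def full_scale(cls, seed: int = 0, **overrides) -> "CohortDesign":
        """Full-scale study design: 37 subjects, 273 ROIs in 6 modules, 250 time points."""
        partition = _default_partition(273, FULL_SCALE_MODULE_SIZES)
        offsets = np.cumsum((0,) + FULL_SCALE_MODULE_SIZES[:-1])
        kwargs = dict(
            n_subjects=37,
            n_timepoints=250,
            n_rois=273,
            planted_partition=partition,
            hub_rois=tuple(int(offsets[1]) + i for i in range(3)),
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def null(self) -> "CohortDesign":
        """Same design with every planted effect removed (paired null cohort)."""
        return replace(self, delta_rho=0.0, delta_hub=0.0)


def build_latent_correlation(
    design: CohortDesign,
    session: str,
    rho_within: float | None = None,
    rho_between: float | None = None,
) -> np.ndarray:
    """Latent N x N correlation matrix for one session.

    Block structure from the planted partition; at follow-up the effect pairs
    gain ``delta_rho`` and hub ROIs gain ``delta_hub`` on cross-module entries,
    capped just below ``rho_within``. The matrix is projected to the nearest
    positive semi-definite correlation matrix (eigenvalue clipping followed by
    diagonal rescaling) whenever clipping is needed.
    """
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}")
    rw = design.rho_within if rho_within is None else rho_within
    rb = design.rho_between if rho_between is None else rho_between
    if not 0 <= rb < rw <= 1:
        raise ValueError("require 0 <= rho_between < rho_within <= 1")
    part = np.asarray(design.planted_partition)
    same = part[:, None] == part[None, :]
    r = np.where(same, rw, rb).astype(float)
    if session == FOLLOWUP:
        for a, b in design.effect_pairs:
            mask = (part[:, None] == a) & (part[None, :] == b)
            mask |= mask.T
            r[mask] += design.delta_rho
        if design.hub_rois and design.delta_hub:
            hubs = np.asarray(design.hub_rois)
            cross = ~same
            hub_mask = np.zeros_like(cross)
            hub_mask[hubs, :] = True
            hub_mask[:, hubs] = True
            r = np.where(hub_mask & cross, r + design.delta_hub, r)
        cap = rw - 1e-3
        off = ~np.eye(design.n_rois, dtype=bool) & ~same
        r[off] = np.minimum(r[off], cap)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return _nearest_psd_correlation(r)


def _nearest_psd_correlation(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale the diagonal back to 1."""
    w = np.linalg.eigvalsh(r)
    if w[0] >= -1e-10:
        return r
    w, v = np.linalg.eigh(r)
    w = np.clip(w, 0.0, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    fixed = (fixed + fixed.T) / 2.0
    if np.linalg.eigvalsh(fixed)[0] < -1e-8:
        raise RuntimeError("PSD projection failed")  # pragma: no cover
    return fixed


def simulate_cohort(design: CohortDesign) -> list[SubjectSession]:
    """Draw the full paired cohort: two sessions per subject, seeded.

    Each session is T independent multivariate-normal samples with covariance
    (latent correlation + noise_sd**2 * I). The subject's jitter on the
    correlation levels is drawn once and shared by both sessions.
    """
    if design.n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    root = np.random.SeedSequence(design.seed)
    subject_seeds = root.spawn(design.n_subjects)
    sessions: list[SubjectSession] = []
    for s in range(design.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        j = design.subject_jitter
        rw = design.rho_within + rng.uniform(-j, j)
        rb = design.rho_between + rng.uniform(-j, j)
        rw = min(max(rw, 0.0), 1.0)
        rb = min(max(rb, 0.0), rw - 1e-3)
        sid = f"sub-{s+1:02d}"
        for sess in SESSIONS:
            latent = build_latent_correlation(design, sess, rho_within=rw, rho_between=rb)
            cov = latent + design.noise_sd**2 * np.eye(design.n_rois)
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(design.n_rois))
            z = rng.standard_normal((design.n_timepoints, design.n_rois))
            sessions.append(SubjectSession(sid, sess, z @ chol.T))
    return sessions


def simulate_clinical(design: CohortDesign) -> pd.DataFrame:
    """Synthetic tremor-severity (FTM-like) scores per subject and session.

    Treated-side and disability scores improve at follow-up by a per-subject
    fraction centred on 0.65; the untreated side is stable. Columns: subject,
    session, ftm_ab_treated, ftm_ab_untreated, ftm_c.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 9151]))
    rows = []
    for s in range(design.n_subjects):
        sid = f"sub-{s+1:02d}"
        bl_t = max(rng.normal(18.3, 5.5), 2.0)
        bl_u = max(rng.normal(16.1, 6.3), 2.0)
        bl_c = max(rng.normal(16.5, 4.2), 2.0)
        impr = float(np.clip(rng.normal(0.65, 0.15), 0.0, 1.0))
        impr_c = float(np.clip(rng.normal(0.66, 0.15), 0.0, 1.0))
        rows.append((sid, BASELINE, bl_t, bl_u, bl_c))
        rows.append(
            (
                sid,
                FOLLOWUP,
                bl_t * (1 - impr),
                bl_u + rng.normal(0.0, 1.5),
                bl_c * (1 - impr_c),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["subject", "session", "ftm_ab_treated", "ftm_ab_untreated", "ftm_c"],
    )


def write_cohort(
    sessions: list[SubjectSession],
    atlas: AtlasSpec,
    directory: str | Path,
    seed: int | None = None,
    clinical: pd.DataFrame | None = None,
) -> Path:
    """Write one TSV matrix per subject-session plus manifest and atlas tables.

    Returns the manifest path. Matrices carry a header row of ROI labels;
    the manifest records (subject, session, path) and the generating seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for ss in sessions:
        if ss.n_rois != atlas.n_rois:
            raise ValueError(
                f"{ss.subject_id}/{ss.session}: {ss.n_rois} columns but atlas has {atlas.n_rois} ROIs"
            )
        fname = f"{ss.subject_id}_{ss.session}.tsv"
        df = pd.DataFrame(ss.timeseries, columns=list(atlas.labels))
        df.to_csv(directory / fname, sep="\t", index=False, float_format="%.10g")
        rows.append((ss.subject_id, ss.session, fname))
    manifest = pd.DataFrame(rows, columns=["subject", "session", "path"])
    manifest["seed"] = "" if seed is None else seed
    manifest_path = directory / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    atlas.to_tsv(directory / "atlas.tsv")
    if clinical is not None:
        clinical.to_csv(directory / "clinical.tsv", sep="\t", index=False, float_format="%.10g")
    return manifest_path
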