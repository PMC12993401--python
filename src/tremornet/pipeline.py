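"""End-to-end orchestration of the analysis stages over on-disk artifacts.

Stages: simulate -> connect -> metrics -> modules -> stats. Each stage reads
the previous stage's plain-text artifacts (TSV/CSV/JSON) from the run
directory and writes its own, so any stage can be re-run in isolation and a
whole run is reproducible bit-identically from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    BASELINE,
    AtlasSpec,
    CohortDesign,
    simulate_clinical,
    simulate_cohort,
    write_cohort,
)
from .connectivity import (
    ConnectivityMatrix,
    SparsityGrid,
    admissibility_check,
    binarize_stack,
    fc_matrix,
    read_cohort,
)
from .metrics import compute_curves
from .modules import ModularPartition, detect_communities, group_graph, module_edge_counts, participation
from .nulls import NullConfig
from .stats import run_statistical_plan

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs: scale, grid, null ensemble, seed, paths."""

    out_dir: Path
    design: CohortDesign
    grid: SparsityGrid = SparsityGrid(0.05, 0.50, 0.01)
    modular_density: float = 0.15
    nulls: NullConfig = NullConfig(100, 10)
    seed: int = 0
    atlas_cerebral: int = 246
    atlas_cerebellar: int = 27
    with_clinical: bool = True

    def __post_init__(self) -> None:
        self.grid.index_of(self.modular_density)  # must lie on the grid
        if self.atlas_cerebral + self.atlas_cerebellar != self.design.n_rois:
            raise ValueError("atlas class counts must sum to n_rois")

    @classmethod
    def preset(cls, name: str, out_dir: str | Path, seed: int = 0) -> "RunConfig":
        """'test' = scaled desk-minutes design; 'paper' = full-scale design."""
        if name == "test":
            return cls(
                out_dir=Path(out_dir),
                design=CohortDesign.scaled(seed=seed),
                grid=SparsityGrid(0.10, 0.40, 0.05),
                nulls=NullConfig(20, 10),
                seed=seed,
                atlas_cerebral=75,
                atlas_cerebellar=15,
            )
        if name == "paper":
            return cls(
                out_dir=Path(out_dir),
                design=CohortDesign.full_scale(seed=seed),
                seed=seed,
            )
        raise ValueError(f"unknown preset {name!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        design = d.pop("design")
        design["planted_partition"] = tuple(design["planted_partition"])
        design["effect_pairs"] = tuple(tuple(p) for p in design["effect_pairs"])
        design["hub_rois"] = tuple(design["hub_rois"])
        return cls(
            out_dir=Path(d["out_dir"]),
            design=CohortDesign(**design),
            grid=SparsityGrid(**d["grid"]),
            modular_density=d["modular_density"],
            nulls=NullConfig(**d["nulls"]),
            seed=d["seed"],
            atlas_cerebral=d["atlas_cerebral"],
            atlas_cerebellar=d["atlas_cerebellar"],
            with_clinical=d["with_clinical"],
        )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _dir(cfg: RunConfig, name: str) -> Path:
    p = Path(cfg.out_dir) / name
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{stage}' stage first"
        )
    return path


def stage_simulate(cfg: RunConfig) -> Path:
    """Generate the synthetic paired cohort and write it to <out>/cohort."""
    atlas = AtlasSpec.generate(cfg.atlas_cerebral, cfg.atlas_cerebellar)
    sessions = simulate_cohort(cfg.design)
    clinical = simulate_clinical(cfg.design) if cfg.with_clinical else None
    return write_cohort(sessions, atlas, _dir(cfg, "cohort"), seed=cfg.design.seed, clinical=clinical)


def stage_connect(cfg: RunConfig) -> Path:
    """Fisher-z connectivity matrix per subject-session -> <out>/fc."""
    cohort_dir = _require(Path(cfg.out_dir) / "cohort" / "manifest.tsv", "simulate").parent
    sessions, atlas = read_cohort(cohort_dir)
    fc_dir = _dir(cfg, "fc")
    rows = []
    for ss in sessions:
        fc = fc_matrix(ss, atlas.labels)
        fname = f"{ss.subject_id}_{ss.session}_fc.tsv"
        pd.DataFrame(fc.values, columns=list(atlas.labels)).to_csv(
            fc_dir / fname, sep="\t", index=False, float_format=_FLOAT_FMT
        )
        rows.append((ss.subject_id, ss.session, fname))
    pd.DataFrame(rows, columns=["subject", "session", "path"]).to_csv(
        fc_dir / "manifest.tsv", sep="\t", index=False
    )
    return fc_dir


def _read_fcs(cfg: RunConfig) -> list[ConnectivityMatrix]:
    fc_dir = _require(Path(cfg.out_dir) / "fc" / "manifest.tsv", "connect").parent
    manifest = pd.read_csv(fc_dir / "manifest.tsv", sep="\t")
    out = []
    for row in manifest.itertuples(index=False):
        vals = pd.read_csv(fc_dir / row.path, sep="\t").to_numpy(dtype=float)
        out.append(ConnectivityMatrix(vals, row.subject, row.session))
    return out


def stage_metrics(cfg: RunConfig, include_nodal: bool = True) -> Path:
    """Metric curves, AUC tables and the admissibility report -> <out>/metrics."""
    fcs = _read_fcs(cfg)
    subjects = sorted({f.subject_id for f in fcs})
    mdir = _dir(cfg, "metrics")
    curve_rows, gauc_rows, nauc_rows = [], [], []
    stacks, sigma_curves = [], {}
    for fc in fcs:
        stack = binarize_stack(fc, cfg.grid)
        stacks.append(stack)
        si = subjects.index(fc.subject_id)
        ki = 0 if fc.session == BASELINE else 1
        curves = compute_curves(
            stack, cfg.nulls, cfg.seed, subject_idx=si, session_idx=ki, include_nodal=include_nodal
        )
        sigma_curves[(fc.subject_id, fc.session)] = curves.global_table["sigma"].to_numpy()
        for d, row in curves.global_table.iterrows():
            for metric, value in row.items():
                curve_rows.append((fc.subject_id, fc.session, d, metric, value))
        for metric, value in curves.global_auc().items():
            gauc_rows.append((fc.subject_id, fc.session, metric, value))
        if include_nodal:
            for metric, vals in curves.nodal_auc().items():
                for node, v in enumerate(vals):
                    nauc_rows.append((fc.subject_id, fc.session, node, metric, v))
    pd.DataFrame(
        curve_rows, columns=["subject", "session", "density", "metric", "value"]
    ).to_csv(mdir / "global_curves.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(gauc_rows, columns=["subject", "session", "metric", "auc"]).to_csv(
        mdir / "global_auc.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(nauc_rows, columns=["subject", "session", "node", "metric", "auc"]).to_csv(
        mdir / "nodal_auc.csv", index=False, float_format=_FLOAT_FMT
    )
    admissibility_check(stacks, sigma_curves).to_csv(
        mdir / "admissibility.csv", index=False, float_format=_FLOAT_FMT
    )
    return mdir


def stage_modules(cfg: RunConfig) -> Path:
    """Group partition at the modular density plus per-subject module tables."""
    fcs = _read_fcs(cfg)
    atlas = AtlasSpec.from_tsv(Path(cfg.out_dir) / "cohort" / "atlas.tsv")
    baseline_fcs = [f for f in fcs if f.session == BASELINE]
    adj, _ = group_graph(baseline_fcs, cfg.modular_density)
    part = detect_communities(adj)
    odir = _dir(cfg, "modules")
    part.to_tsv(odir / "partition.tsv", labels=atlas.labels)
    with open(odir / "group_partition.json", "w") as fh:
        json.dump(
            {
                "Q": part.Q,
                "n_modules": part.n_modules,
                "module_sizes": part.module_sizes.tolist(),
                "nonrandom": bool(part.nonrandom),
                "density": cfg.modular_density,
            },
            fh,
            indent=1,
        )
    count_rows, part_rows = [], []
    for fc in fcs:
        slice_adj = binarize_stack(fc, cfg.grid).adjacency_at_density(cfg.modular_density)
        counts = module_edge_counts(slice_adj, part, fc.subject_id, fc.session)
        for a in range(part.n_modules):
            for b in range(a, part.n_modules):
                count_rows.append(
                    (fc.subject_id, fc.session, a, b, int(counts.counts[a, b]))
                )
        for node, v in enumerate(participation(slice_adj, part)):
            part_rows.append((fc.subject_id, fc.session, node, "participation", v))
    pd.DataFrame(
        count_rows, columns=["subject", "session", "module_a", "module_b", "count"]
    ).to_csv(odir / "module_counts.csv", index=False)
    pd.DataFrame(
        part_rows, columns=["subject", "session", "node", "metric", "auc"]
    ).to_csv(odir / "participation.csv", index=False, float_format=_FLOAT_FMT)
    return odir


def stage_stats(cfg: RunConfig) -> Path:
    """Run the paired statistical plan on the metric and module tables."""
    out = Path(cfg.out_dir)
    mdir = _require(out / "metrics" / "global_auc.csv", "metrics").parent
    odir = _require(out / "modules" / "module_counts.csv", "modules").parent
    atlas = AtlasSpec.from_tsv(out / "cohort" / "atlas.tsv")
    global_auc = pd.read_csv(mdir / "global_auc.csv")
    nodal_auc = pd.read_csv(mdir / "nodal_auc.csv")
    module_counts = pd.read_csv(odir / "module_counts.csv")
    participation_table = pd.read_csv(odir / "participation.csv")
    part_df = pd.read_csv(odir / "partition.tsv", sep="\t")
    with open(odir / "group_partition.json") as fh:
        meta = json.load(fh)
    part = ModularPartition(part_df["module"].to_numpy(), meta["Q"])
    clinical_path = out / "cohort" / "clinical.tsv"
    clinical = pd.read_csv(clinical_path, sep="\t") if clinical_path.exists() else None
    report = run_statistical_plan(
        global_auc,
        nodal_auc,
        module_counts,
        participation_table,
        part,
        clinical=clinical,
        roi_labels=atlas.labels,
    )
    sdir = _dir(cfg, "stats")
    report.global_tests.to_csv(sdir / "global_tests.csv", index=False, float_format=_FLOAT_FMT)
    report.nodal_tests.to_csv(sdir / "nodal_tests.csv", index=False, float_format=_FLOAT_FMT)
    report.inter_module_tests.to_csv(
        sdir / "inter_module_tests.csv", index=False, float_format=_FLOAT_FMT
    )
    report.intra_module_tests.to_csv(
        sdir / "intra_module_tests.csv", index=False, float_format=_FLOAT_FMT
    )
    report.restricted_tests.to_csv(
        sdir / "restricted_tests.csv", index=False, float_format=_FLOAT_FMT
    )
    report.correlations.to_csv(sdir / "correlations.csv", index=False, float_format=_FLOAT_FMT)
    summary = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "group_Q": meta["Q"],
        "n_modules": meta["n_modules"],
        "module_sizes": meta["module_sizes"],
        "implicated_modules": report.implicated_modules,
        "hypothesis_directions": report.directions,
        "significant_global": report.global_tests.loc[
            report.global_tests["significant"], "metric"
        ].tolist(),
    }
    with open(sdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return sdir


STAGES = {
    "simulate": stage_simulate,
    "connect": stage_connect,
    "metrics": stage_metrics,
    "modules": stage_modules,
    "stats": stage_stats,
}


def run_all(cfg: RunConfig) -> Path:
    """Run every stage in order; returns the stats directory."""
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(Path(cfg.out_dir) / "config.yaml")
    for name in ("simulate", "connect", "metrics", "modules", "stats"):
        STAGES[name](cfg)
    return Path(cfg.out_dir) / "stats"
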