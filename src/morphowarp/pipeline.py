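"""End-to-end orchestration: landmark every target, then run the statistics.

The landmarking stage mirrors the six-step workflow: digitized fixed points
and a seeded template (steps 1-3) are inputs via the scheme; each target is
TPS-warped and projected (step 4), slid for six bending-energy cycles
(step 5); the statistics stage (step 6) superimposes the landmark data and
runs the error assessment and shape analyses, separately for the fixed-only,
semi-only, and combined landmark partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .errors import MorphowarpError
from .mesh import read_obj
from .sliding import DEFAULT_FIXED_NAMES, slide, transfer_template
from .stats import (
    allometric_regression,
    centroid_size,
    cva,
    gpa_align,
    manova_wilks,
    permutation_test,
    procrustes_anova,
    shape_pca,
)
from .tps import bending_energy_matrix

logger = logging.getLogger(__name__)


@dataclass
class TargetSpec:
    specimen_id: str
    mesh_path: str
    landmarks_path: str


@dataclass
class RunConfig:
    """A reproducible landmarking run: scheme + targets + parameters."""

    scheme_path: str
    targets: List[TargetSpec]
    out_dir: str
    n_iter: int = 6
    step_start: float = 1.0
    step_end: float = 0.05
    beta: float = 0.0
    n_perm: int = 1000
    seed: int = 0
    log_cs: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        targets = [TargetSpec(**t) for t in doc.pop("targets")]
        cfg = cls(targets=targets, **doc)
        # relative paths resolve against the config file
        def _resolve(p):
            p = Path(p)
            return str(p if p.is_absolute() else path.parent / p)

        cfg.scheme_path = _resolve(cfg.scheme_path)
        cfg.out_dir = _resolve(cfg.out_dir)
        for t in cfg.targets:
            t.mesh_path = _resolve(t.mesh_path)
            t.landmarks_path = _resolve(t.landmarks_path)
        return cfg

    def to_yaml(self, path) -> None:
        doc = {
            "scheme_path": self.scheme_path,
            "out_dir": self.out_dir,
            "n_iter": self.n_iter,
            "step_start": self.step_start,
            "step_end": self.step_end,
            "beta": self.beta,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "log_cs": self.log_cs,
            "targets": [
                {
                    "specimen_id": t.specimen_id,
                    "mesh_path": t.mesh_path,
                    "landmarks_path": t.landmarks_path,
                }
                for t in self.targets
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def run_landmarking(config: RunConfig):
    """Transfer + slide the template onto every target.

    Writes the flat landmark table (``landmarks.csv``, 3k coordinate columns)
    and one per-target energy trace CSV.  Individual target failures are
    logged and skipped; returns (table, list of (specimen_id, error)).
    """
    scheme = mio.load_scheme(config.scheme_path)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    B = bending_energy_matrix(scheme.coords)  # template is the reference form
    configs = []
    failures = []
    fixed_names = scheme.fixed_names
    for t in config.targets:
        try:
            mesh = read_obj(t.mesh_path)
            names, coords = mio.read_landmark_csv(t.landmarks_path)
            order = {n: i for i, n in enumerate(names)}
            missing = [n for n in fixed_names if n not in order]
            if missing:
                raise MorphowarpError(
                    f"landmark file {t.landmarks_path} missing {missing}"
                )
            fixed = coords[[order[n] for n in fixed_names]]
            cfg = transfer_template(scheme, mesh, fixed, beta=config.beta)
            cfg.specimen_id = t.specimen_id
            cfg, trace = slide(
                scheme,
                cfg,
                mesh,
                n_iter=config.n_iter,
                step_start=config.step_start,
                step_end=config.step_end,
                B=B,
            )
            trace.to_csv(out_dir / f"energy_{t.specimen_id}.csv")
            logger.info(
                "%s: bending energy %.6g -> %.6g",
                t.specimen_id,
                trace.initial_energy,
                trace.final_energy,
            )
            configs.append(cfg)
        except (MorphowarpError, OSError) as exc:
            logger.error("target %s failed: %s", t.specimen_id, exc)
            failures.append((t.specimen_id, exc))
    table = mio.configs_to_table(configs, scheme.landmark_names)
    mio.write_flat_table(table, out_dir / "landmarks.csv")
    return table, failures


# ---------------------------------------------------------------------- #
# Synthetic study emission (the layout run_landmarking consumes)
# ---------------------------------------------------------------------- #

def write_synthetic_study(
    out_dir,
    spec,
    n_semis: int = 60,
    spacing_radius: float = 1.5,
) -> RunConfig:
    """Emit a full synthetic study: template OBJ + scheme, one OBJ per
    individual, one fixed-landmark CSV per replicate digitization, ground
    truth tables, metadata, and a ready-to-run config.yaml.

    Returns the RunConfig (also written to ``<out_dir>/config.yaml``).
    """
    from .mesh import write_obj
    from .sliding import build_scheme
    from .synthetic import make_face_mesh, simulate_study

    out_dir = Path(out_dir)
    (out_dir / "targets").mkdir(parents=True, exist_ok=True)
    (out_dir / "landmarks").mkdir(exist_ok=True)
    base_mesh, base_points = make_face_mesh(spec.resolution, seed=spec.seed)
    scheme = build_scheme(
        base_mesh,
        base_points,
        n_semis=n_semis,
        spacing_radius=spacing_radius,
        seed=spec.seed,
    )
    write_obj(base_mesh, out_dir / "template.obj")
    mio.save_scheme(scheme, out_dir / "scheme.yaml", "template.obj")
    specimens = simulate_study(spec, semi_coords=scheme.semi_coords)
    targets = []
    meta_rows = []
    truth_rows = []
    for sp in specimens:
        mesh_path = out_dir / "targets" / f"{sp.specimen_id}.obj"
        write_obj(sp.mesh, mesh_path)
        truth_rows.append(
            [sp.specimen_id]
            + list(np.vstack([sp.true_fixed, sp.true_semis]).ravel())
        )
        for r, digitized in enumerate(sp.digitized_fixed):
            rid = f"{sp.specimen_id}_r{r}"
            lm_path = out_dir / "landmarks" / f"{rid}.csv"
            mio.write_landmark_csv(lm_path, scheme.fixed_names, digitized)
            targets.append(
                TargetSpec(
                    specimen_id=rid,
                    mesh_path=str(Path("targets") / f"{sp.specimen_id}.obj"),
                    landmarks_path=str(Path("landmarks") / f"{rid}.csv"),
                )
            )
            meta_rows.append(
                {
                    "id": rid,
                    "population": sp.population,
                    "individual": sp.specimen_id,
                    "replicate": f"r{r}",
                    "template": "template.obj",
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["id"] + mio.flat_columns(scheme.landmark_names)
    )
    mio.write_flat_table(truth, out_dir / "truth.csv")
    mio.write_metadata(pd.DataFrame(meta_rows), out_dir / "metadata.csv")
    cfg = RunConfig(
        scheme_path="scheme.yaml",
        targets=targets,
        out_dir="results",
        seed=spec.seed,
    )
    cfg.to_yaml(out_dir / "config.yaml")
    return cfg


# ---------------------------------------------------------------------- #
# Statistics stage
# ---------------------------------------------------------------------- #

def _partitions(names: List[str], fixed_names=None) -> Dict[str, List[str]]:
    fixed_set = set(DEFAULT_FIXED_NAMES if fixed_names is None else fixed_names)
    fixed = [n for n in names if n in fixed_set]
    semis = [n for n in names if n not in fixed_set]
    parts = {}
    if fixed:
        parts["fixed"] = fixed
    if semis:
        parts["semis"] = semis
    if fixed and semis:
        parts["combined"] = names
    return parts


def run_stats(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    out_dir,
    n_perm: int = 1000,
    seed: int = 0,
    log_cs: bool = False,
    fixed_names=None,
) -> Dict[str, dict]:
    """Run the statistics bundle on a flat landmark table.

    For each landmark partition (fixed anatomical landmarks, sliding
    semi-landmarks, combined): GPA, shape PCA with broken-stick retention,
    Procrustes ANOVA when replicates are present, pairwise permutation
    distance tests, allometric regression, CVA, and Wilks' MANOVA.  Writes
    CSV tables and a plain-text summary; returns the results keyed by
    partition.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = metadata.set_index("id")
    orphans = [i for i in table["id"] if i not in meta.index]
    if orphans:
        raise MorphowarpError(f"specimens missing from metadata: {orphans}")
    meta = meta.loc[table["id"]]
    pops = meta["population"].to_numpy()
    inds = meta["individual"].to_numpy()
    reps = meta["replicate"].to_numpy()
    names = mio.table_names(table)
    has_reps = (
        pd.DataFrame({"p": pops, "i": inds}).groupby(["p", "i"]).size().max() > 1
    )
    n_pops = len(pd.unique(pops))
    results: Dict[str, dict] = {}
    summary: List[str] = []
    for part, part_names in _partitions(names, fixed_names).items():
        X = mio.table_to_array(table, part_names)
        res: dict = {}
        gpa = gpa_align(X)
        res["gpa"] = gpa
        res["centroid_sizes"] = np.array([centroid_size(c) for c in X])
        pca = shape_pca(gpa)
        res["pca"] = pca
        pd.DataFrame(
            {
                "eigenvalue": pca.eigenvalues,
                "pct_variance": pca.pct_variance,
            }
        ).to_csv(out_dir / f"pca_eigen_{part}.csv", index=False)
        scores = pd.DataFrame(
            pca.scores, columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])]
        )
        scores.insert(0, "id", table["id"].to_numpy())
        scores.to_csv(out_dir / f"pca_scores_{part}.csv", index=False)
        summary.append(
            f"[{part}] n={len(X)} k={len(part_names)}: PCA retained "
            f"{pca.n_retained_broken_stick} components (broken stick); "
            f"PC1 {pca.pct_variance[0]:.2f}%"
        )
        if has_reps:
            anova = procrustes_anova(gpa, pops, inds, reps)
            anova.to_csv(out_dir / f"procrustes_anova_{part}.csv", index=False)
            res["anova"] = anova
            err = anova.loc[anova["effect"] == "Error", "pct_var"]
            summary.append(
                f"[{part}] Procrustes ANOVA error variance "
                f"{float(err.iloc[0]):.2f}%"
            )
        else:
            summary.append(f"[{part}] no replicates: Procrustes ANOVA skipped")
        if n_pops >= 2 and min(np.bincount(pd.factorize(pops)[0])) >= 2:
            perm = permutation_test(gpa, pops, n_perm=n_perm, seed=seed)
            perm.to_csv(out_dir / f"procrustes_distances_{part}.csv", index=False)
            res["distances"] = perm
            cs = res["centroid_sizes"]
            allo = allometric_regression(
                gpa, cs, groups=pops, n_perm=n_perm, seed=seed, log_size=log_cs
            )
            res["allometry"] = allo
            summary.append(
                f"[{part}] allometry: {allo.pct_predicted:.2f}% of shape "
                f"variance predicted by centroid size (p={allo.p_value:.4g})"
            )
            try:
                n_cv_dim = min(
                    pca.scores.shape[1], max(1, len(X) - n_pops - 1)
                )
                res["cva"] = cva(pca.scores[:, :n_cv_dim], pops)
                res["cva"].mahalanobis.to_csv(
                    out_dir / f"cva_mahalanobis_{part}.csv", index=False
                )
            except MorphowarpError as exc:
                summary.append(f"[{part}] CVA skipped: {exc}")
            q = max(1, min(3, (len(X) - 2 * n_pops - 2) // 2))
            try:
                res["manova"] = manova_wilks(
                    pca.scores[:, :q], pops, covariate=res["centroid_sizes"],
                    with_interaction=True,
                )
                res["manova_no_interaction"] = manova_wilks(
                    pca.scores[:, :q], pops, covariate=res["centroid_sizes"],
                    with_interaction=False,
                )
                res["manova"].to_csv(out_dir / f"manova_{part}.csv", index=False)
                res["manova_no_interaction"].to_csv(
                    out_dir / f"manova_no_interaction_{part}.csv", index=False
                )
            except MorphowarpError as exc:
                summary.append(f"[{part}] MANOVA skipped: {exc}")
        else:
            summary.append(
                f"[{part}] fewer than 2 usable populations: group tests skipped"
            )
        results[part] = res
    (out_dir / "summary.txt").write_text("\n".join(summary) + "\n")
    return results
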