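"""End-to-end orchestration: simulate a cohort, run every analysis stage,
and write the report tables and deformation-grid figures to disk.

``run_full`` reproduces the study's analysis sequence on any dataset with
the expected structure (TPS landmarks + subjects CSV):

1. GPA with sliding semilandmarks, symmetrization, re-superimposition;
2. whole-sample sequential PERMANOVA (age, then sex) and per-cohort
   models (sex alone; BMI, then sex);
3. facial-index table with per-cohort BMI-controlled ANCOVA sex effects;
4. body-dimorphism table (Levene-gated t, Hedges' g) per cohort;
5. stepwise forward-Wald logistic regression of sex on body parameters;
6. static allometry: shape vs log centroid size and vs body height per
   sex, and index-level MANCOVA against centroid size;
7. index-level MANCOVA against skeletal/muscular body parameters;
8. stepwise linear regression of handgrip strength (per sex);
9. thin-plate-spline deformation grids, female mean toward male mean,
   at exaggeration 1x and 3x per cohort.

Every stage writes a CSV (or SVG) under the output directory; a stage
failure is recorded and re-raised at the end so partial outputs survive.
All randomness flows from the single seed in the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bodystats, indices, inference, synthesize
from .landmarks import LandmarkScheme, default_scheme, load_scheme, read_tps, write_tps
from .procrustes import gpa, symmetrize, tps_warp

__all__ = ["AnalysisConfig", "PipelineError", "run_full", "simulate"]

logger = logging.getLogger(__name__)

LOGISTIC_PREDICTORS = list(bodystats.BODY_PARAMETERS)
HGS_PREDICTORS = [p for p in bodystats.BODY_PARAMETERS if p != "handgrip"]
SKELETAL_PREDICTORS = ["wrist_diameter", "upper_arm_circ", "under_chest_circ", "hips_circ"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    tps_path: str | Path
    subjects_path: str | Path
    out_dir: str | Path
    scheme_path: str | Path | None = None
    cohort_bounds: dict = field(
        default_factory=lambda: {"young": (17, 29), "mid": (30, 50), "elderly": (51, 150)}
    )
    n_perm: int = 10_000
    seed: int = 0
    bonferroni_m: int = 12
    slide: bool = True
    symmetrize: bool = True
    exaggeration: float = 3.0

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        if self.exaggeration < 0:
            raise ValueError("exaggeration factor must be >= 0")


def assign_cohort(ages, bounds) -> pd.Series:
    ages = pd.Series(ages, dtype=float)
    out = pd.Series(index=ages.index, dtype=object)
    for name, (lo, hi) in bounds.items():
        out[(ages >= lo) & (ages <= hi)] = name
    return out


def simulate(
    design: synthesize.SyntheticDesign,
    out_dir: str | Path,
    scheme: LandmarkScheme | None = None,
    seed: int | None = 0,
) -> dict:
    """Write a synthetic dataset (TPS + subjects CSV + design echo) to disk."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = scheme or default_scheme()
    configs, subjects = synthesize.generate_cohort(design, scheme, seed=seed)
    write_tps(configs, out / "landmarks.tps")
    subjects.to_csv(out / "subjects.csv", index=False)
    with open(out / "design.yaml", "w") as fh:
        yaml.safe_dump(synthesize.design_to_dict(design), fh, sort_keys=False)
    return {
        "n_subjects": len(subjects),
        "n_male": int((subjects["sex"] == "male").sum()),
        "tps": str(out / "landmarks.tps"),
        "subjects": str(out / "subjects.csv"),
    }


def _deformation_grid_svg(reference, target, k, path, n_grid=24, pad=0.08):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference)
    tgt = inference.exaggerate(ref, np.asarray(target), k)
    lo = ref.min(axis=0) - pad * np.ptp(ref, axis=0)
    hi = ref.max(axis=0) + pad * np.ptp(ref, axis=0)
    gx = np.linspace(lo[0], hi[0], n_grid)
    gy = np.linspace(lo[1], hi[1], n_grid)
    xx, yy = np.meshgrid(gx, gy)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    warped = tps_warp(ref, tgt, nodes).reshape(n_grid, n_grid, 2)
    fig, ax = plt.subplots(figsize=(5, 5))
    for i in range(n_grid):
        ax.plot(warped[i, :, 0], warped[i, :, 1], color="0.7", lw=0.5)
        ax.plot(warped[:, i, 0], warped[:, i, 1], color="0.7", lw=0.5)
    ax.scatter(ref[:, 0], ref[:, 1], s=8, color="crimson", label="reference (female)")
    ax.scatter(tgt[:, 0], tgt[:, 1], s=8, color="navy", label=f"target x{k:g} (male)")
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="lower right", fontsize=7)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


def run_full(config: AnalysisConfig) -> dict:
    """Run every analysis stage; returns a summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log: dict = {"stages": {}, "n": {}, "seed": config.seed}
    errors: list[PipelineError] = []

    def stage(name):
        def wrap(fn):
            try:
                fn()
                log["stages"][name] = "ok"
            except Exception as exc:  # noqa: BLE001 - reported per stage
                logger.exception("stage %s failed", name)
                log["stages"][name] = f"error: {exc}"
                errors.append(PipelineError(name, exc))

        return wrap

    scheme = (
        default_scheme() if config.scheme_path is None else load_scheme(config.scheme_path)
    )
    configs = read_tps(config.tps_path, scheme)
    subjects = pd.read_csv(config.subjects_path)
    order = {c.subject_id: i for i, c in enumerate(configs)}
    missing = [s for s in subjects["subject_id"] if s not in order]
    if missing:
        logger.warning("subjects without landmarks excluded: %s", missing)
        subjects = subjects[~subjects["subject_id"].isin(missing)]
    subjects = subjects.set_index("subject_id").loc[[c.subject_id for c in configs]]
    subjects = subjects.reset_index()
    if "cohort" not in subjects.columns:
        subjects["cohort"] = assign_cohort(subjects["age"], config.cohort_bounds)
    log["n"]["subjects"] = len(subjects)

    # --- superimposition ---------------------------------------------------
    res = gpa(configs, scheme, slide=config.slide)
    if config.symmetrize:
        sym = symmetrize(list(res.aligned), scheme)
        res_in = [np.asarray(s) for s in sym]
        res2 = gpa(res_in, scheme, slide=False)
        aligned = type(res)(
            aligned=res2.aligned,
            consensus=res2.consensus,
            centroid_sizes=res.centroid_sizes,
            n_iterations=res.n_iterations + res2.n_iterations,
            converged=res.converged and res2.converged,
            subject_ids=res.subject_ids,
        )
    else:
        aligned = res
    subjects = subjects.assign(facial_cs=aligned.centroid_sizes)
    coords_flat = pd.DataFrame(
        aligned.flat, index=subjects["subject_id"]
    )
    coords_flat.to_csv(out / "aligned_coordinates.csv")

    sex = subjects["sex"].to_numpy()
    cohort = subjects["cohort"].to_numpy()
    young_mid = subjects["cohort"].isin(["young", "mid"]).to_numpy()

    @stage("permanova_whole_sample")
    def _():
        tab = inference.permanova(
            aligned.flat,
            {"age": subjects["age"], "sex": sex},
            n_perm=config.n_perm,
            seed=rng,
        )
        tab.to_frame().to_csv(out / "permanova_whole_sample.csv", index=False)

    @stage("permanova_per_cohort")
    def _():
        rows = []
        for name in pd.unique(cohort):
            mask = cohort == name
            t_sex = inference.permanova(
                aligned.flat[mask], {"sex": sex[mask]}, n_perm=config.n_perm, seed=rng
            )
            t_bmi = inference.permanova(
                aligned.flat[mask],
                {"bmi": subjects["bmi"][mask], "sex": sex[mask]},
                n_perm=config.n_perm,
                seed=rng,
            )
            rows.append(
                {
                    "cohort": name,
                    "n": int(mask.sum()),
                    "sex_r2": t_sex["sex"]["r2"],
                    "sex_p": t_sex["sex"]["p"],
                    "sex_r2_bmi_controlled": t_bmi["sex"]["r2"],
                    "sex_p_bmi_controlled": t_bmi["sex"]["p"],
                    "bmi_r2": t_bmi["bmi"]["r2"],
                    "bmi_p": t_bmi["bmi"]["p"],
                }
            )
        pd.DataFrame(rows).to_csv(out / "permanova_per_cohort.csv", index=False)

    # --- facial indices ----------------------------------------------------
    index_df = indices.index_table(
        [c.with_coords(a) for c, a in zip(configs, aligned.aligned)], scheme, subjects
    )
    index_df.to_csv(out / "facial_indices.csv", index=False)

    @stage("index_dimorphism")
    def _():
        rows = []
        for name in ("young", "mid"):
            sub = index_df[index_df["cohort"] == name]
            for ix in indices.INDEX_NAMES:
                f, eta2, p = bodystats.ancova_sex_effect(sub[ix], sub["bmi"], sub["sex"])
                male = sub.loc[sub["sex"] == "male", ix]
                female = sub.loc[sub["sex"] == "female", ix]
                rows.append(
                    {
                        "cohort": name,
                        "index": ix,
                        "male_mean": male.mean(),
                        "male_sd": male.std(),
                        "female_mean": female.mean(),
                        "female_sd": female.std(),
                        "F": f,
                        "partial_eta2": eta2,
                        "p": p,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "index_dimorphism.csv", index=False)

    # --- body statistics ---------------------------------------------------
    @stage("body_dimorphism")
    def _():
        rows = []
        for name in ("young", "mid"):
            sub = subjects[subjects["cohort"] == name]
            tab = bodystats.dimorphism_table(sub)
            tab.insert(0, "cohort", name)
            rows.append(tab)
        pd.concat(rows, ignore_index=True).to_csv(
            out / "body_dimorphism.csv", index=False
        )

    @stage("logistic_sex_model")
    def _():
        sub = subjects[young_mid]
        # outcome coded female = 1, so coefficients carry the conventional
        # "male-typical parameter -> negative B" signs
        model = bodystats.stepwise_logistic(
            sub[LOGISTIC_PREDICTORS], (sub["sex"] == "female").to_numpy().astype(float)
        )
        pd.DataFrame(
            {
                "predictor": model.predictors,
                "B": [model.coefficients[p] for p in model.predictors],
                "p": [model.coefficient_p[p] for p in model.predictors],
            }
        ).assign(model_p=model.model_p, r2=model.r2, accuracy=model.accuracy).to_csv(
            out / "logistic_sex_model.csv", index=False
        )

    # --- allometry ---------------------------------------------------------
    @stage("allometry_shape")
    def _():
        rows = []
        for sx in ("male", "female"):
            mask = young_mid & (sex == sx)
            sub_cfg = [c for c, m in zip(configs, mask) if m]
            res_sx = gpa(sub_cfg, scheme, slide=config.slide)
            if config.symmetrize:
                res_sx = gpa(
                    [np.asarray(s) for s in symmetrize(list(res_sx.aligned), scheme)],
                    scheme,
                    slide=False,
                )
            log_cs = np.log(aligned.centroid_sizes[mask])
            sub = subjects[mask]
            for size_name, size_vals, cov in (
                ("log_cs", log_cs, None),
                ("log_cs_bmi_controlled", log_cs, sub["bmi"].to_numpy()),
                ("height", sub["height"].to_numpy(), None),
            ):
                tab = inference.allometry_test(
                    res_sx,
                    size_vals,
                    covariate=cov,
                    size_name="size",
                    n_perm=config.n_perm,
                    seed=rng,
                )
                rows.append(
                    {
                        "sex": sx,
                        "size_measure": size_name,
                        "n": int(mask.sum()),
                        "r2": tab["size"]["r2"],
                        "p": tab["size"]["p"],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "allometry_shape.csv", index=False)

    @stage("allometry_indices")
    def _():
        frames = []
        for sx in ("male", "female"):
            sub = index_df[index_df["cohort"].isin(["young", "mid"]) & (index_df["sex"] == sx)]
            tab = bodystats.mancova_trait_effects(
                sub[list(indices.INDEX_NAMES)],
                sub["bmi"],
                np.log(sub["facial_cs"]),
                trait_name="log_facial_cs",
                n_tests=config.bonferroni_m,
            )
            tab.insert(0, "sex", sx)
            frames.append(tab)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "allometry_indices.csv", index=False
        )

    @stage("body_trait_mancova")
    def _():
        frames = []
        for sx in ("male", "female"):
            sub = index_df[index_df["cohort"].isin(["young", "mid"]) & (index_df["sex"] == sx)]
            for trait in SKELETAL_PREDICTORS:
                tab = bodystats.mancova_trait_effects(
                    sub[list(indices.INDEX_NAMES)],
                    sub["bmi"],
                    sub[trait],
                    trait_name=trait,
                    n_tests=config.bonferroni_m,
                )
                tab.insert(0, "sex", sx)
                frames.append(tab)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "body_trait_mancova.csv", index=False
        )

    @stage("handgrip_model")
    def _():
        frames = []
        for sx in ("male", "female"):
            sub = subjects[young_mid & (sex == sx)]
            model = bodystats.stepwise_linear(sub[HGS_PREDICTORS], sub["handgrip"])
            frames.append(
                pd.DataFrame(
                    {
                        "sex": sx,
                        "predictor": model.predictors or ["<none>"],
                        "B": [model.coefficients[p] for p in model.predictors] or [np.nan],
                        "p": [model.coefficient_p[p] for p in model.predictors]
                        or [np.nan],
                        "model_p": model.model_p,
                        "r2": model.r2,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(
            out / "handgrip_model.csv", index=False
        )

    @stage("deformation_grids")
    def _():
        labels = np.where(sex == "male", "male", "female")
        for name in pd.unique(cohort):
            mask = cohort == name
            means = inference.group_mean_shapes(
                type(aligned)(
                    aligned=aligned.aligned[mask],
                    consensus=aligned.consensus,
                    centroid_sizes=aligned.centroid_sizes[mask],
                    n_iterations=aligned.n_iterations,
                    converged=aligned.converged,
                ),
                labels[mask],
            )
            for k in (1.0, config.exaggeration):
                _deformation_grid_svg(
                    means["female"],
                    means["male"],
                    k,
                    out / f"deformation_{name}_x{k:g}.svg",
                )

    log["n"]["converged"] = bool(aligned.converged)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    if errors:
        raise errors[0]
    return log
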