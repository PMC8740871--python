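#!/usr/bin/env python
"""Static allometry and facial-body associations.

Per sex over the pooled 17-50-year cohorts: shape-on-size PERMANOVA
against log centroid size (with and without BMI control) and against body
height; index-level MANCOVA against centroid size and against the
skeletal/muscular body parameters (Bonferroni over 12 indices); and the
stepwise linear model of handgrip strength.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from morphodim import (
    INDEX_NAMES,
    allometry_test,
    default_scheme,
    gpa,
    mancova_trait_effects,
    read_tps,
    stepwise_linear,
    symmetrize,
)
from morphodim.pipeline import HGS_PREDICTORS, SKELETAL_PREDICTORS

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "dataset"
RESULTS = ROOT / "results"
SEED = 2024
N_PERM = 10_000

if __name__ == "__main__":
    scheme = default_scheme()
    configs = read_tps(DATA / "landmarks.tps", scheme)
    subjects = pd.read_csv(DATA / "subjects.csv").set_index("subject_id")
    indices_df = pd.read_csv(RESULTS / "facial_indices.csv")

    rows = []
    for sx in ("male", "female"):
        ids = subjects[(subjects["sex"] == sx) & subjects["cohort"].isin(["young", "mid"])].index
        keep = [c for c in configs if c.subject_id in set(ids)]
        res = gpa(keep, scheme, slide=True)
        res = gpa([np.asarray(s) for s in symmetrize(list(res.aligned), scheme)],
                  scheme, slide=False)
        sub = subjects.loc[[c.subject_id for c in keep]]
        res = type(res)(
            aligned=res.aligned, consensus=res.consensus,
            centroid_sizes=np.array([np.linalg.norm(c.coords - c.coords.mean(0)) for c in keep]),
            n_iterations=res.n_iterations, converged=res.converged,
        )
        log_cs = np.log(res.centroid_sizes)
        for label, size, cov in (
            ("log_cs", log_cs, None),
            ("log_cs_bmi_controlled", log_cs, sub["bmi"].to_numpy()),
            ("height", sub["height"].to_numpy(), None),
        ):
            tab = allometry_test(res, size, covariate=cov, size_name="size",
                                 n_perm=N_PERM, seed=SEED)
            rows.append({"sex": sx, "size_measure": label, "n": len(keep),
                         "r2": tab["size"]["r2"], "p": tab["size"]["p"]})
    shape_allometry = pd.DataFrame(rows)
    shape_allometry.to_csv(RESULTS / "allometry_shape.csv", index=False)
    print(shape_allometry.round(4).to_string(index=False))

    frames, body_frames = [], []
    for sx in ("male", "female"):
        sub = indices_df[(indices_df["sex"] == sx) & indices_df["cohort"].isin(["young", "mid"])]
        tab = mancova_trait_effects(sub[list(INDEX_NAMES)], sub["bmi"],
                                    np.log(sub["facial_cs"]), trait_name="log_facial_cs")
        tab.insert(0, "sex", sx)
        frames.append(tab)
        for trait in SKELETAL_PREDICTORS:
            t2 = mancova_trait_effects(sub[list(INDEX_NAMES)], sub["bmi"], sub[trait],
                                       trait_name=trait)
            t2.insert(0, "sex", sx)
            body_frames.append(t2)
    pd.concat(frames, ignore_index=True).to_csv(RESULTS / "allometry_indices.csv", index=False)
    pd.concat(body_frames, ignore_index=True).to_csv(RESULTS / "body_trait_mancova.csv", index=False)

    print("\nhandgrip-strength stepwise models:")
    hgs_frames = []
    for sx in ("male", "female"):
        sub = subjects[(subjects["sex"] == sx) & subjects["cohort"].isin(["young", "mid"])]
        model = stepwise_linear(sub[HGS_PREDICTORS], sub["handgrip"])
        print(f"  {sx}: predictors={model.predictors} R2={model.r2:.3f}")
        hgs_frames.append(pd.DataFrame({
            "sex": sx,
            "predictor": model.predictors or ("<none>",),
            "B": [model.coefficients[p] for p in model.predictors] or [np.nan],
            "r2": model.r2,
        }))
    pd.concat(hgs_frames, ignore_index=True).to_csv(RESULTS / "handgrip_model.csv", index=False)
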