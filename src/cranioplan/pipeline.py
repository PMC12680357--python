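"""End-to-end orchestration: corpus generation, training, prediction, validation.

A corpus run fans one master seed out to per-patient seeds, builds each
patient's skull, samples their design of experiments, runs every spring
simulation, fits the pre-operative and outcome shape models, and
assembles the regression dataset — all deterministically.  Downstream
helpers train/tune the surrogate, predict a new patient's outcome, and
score predictions against a reference surface.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from cranioplan.anatomy import PatientParams, PopulationSpec, SkullModel, apply_osteotomy, build_skull, sample_population
from cranioplan.doe import DoEPlan, generate_doe
from cranioplan.mesh import (
    TriangleMesh,
    cranial_index,
    flatten_shape,
    offset_mesh,
    surface_distance,
    unflatten_shape,
    volume_match_scale,
)
from cranioplan.registration import nricp
from cranioplan.shape_model import StatisticalShapeModel
from cranioplan.springs import SolverOptions, SurgicalConfig, simulate
from cranioplan.surrogate import (
    SplitData,
    SurrogateRegressor,
    assemble_dataset,
    split_and_scale,
)

__all__ = [
    "derive_patient_seed",
    "CorpusResult",
    "run_corpus",
    "train_surrogate",
    "PredictionReport",
    "predict_outcome",
    "evaluate_validation",
    "correlation_analysis",
]


def derive_patient_seed(master_seed: int, patient_id: int) -> int:
    """Stable per-patient seed: corpora extend without reshuffling earlier patients."""
    return int((master_seed * 1_000_003 + 7919 * patient_id + 1) % (2 ** 31))


def reference_skull_volume(population: PopulationSpec) -> float:
    """Volume of the population-mean skull; the target of volume normalisation."""
    from cranioplan.mesh import mesh_volume

    mean_params = PatientParams(
        age_days=int(round(population.age_mean)),
        t_skull=population.t_skull_mean,
        t_skin=population.t_skin_mean,
        semi_axes=(population.ax_mean, population.ay_mean, population.az_mean),
        elongation=population.elongation_mean,
    )
    return mesh_volume(build_skull(mean_params, population).mesh, warn_open=False)


@dataclass
class CorpusResult:
    """Everything a corpus run produces, in memory."""

    patients: dict[int, PatientParams]
    skulls: dict[int, SkullModel]
    plans: dict[int, DoEPlan]
    preop_shapes: dict[int, np.ndarray]
    sim_shapes: dict[tuple[int, int], np.ndarray]
    openings: dict[tuple[int, int], dict[str, float]]
    volume_scales: dict[int, float]
    reference_volume: float
    ssm_in: StatisticalShapeModel
    ssm_out: StatisticalShapeModel
    dataset: pd.DataFrame
    template_faces: np.ndarray
    master_seed: int
    manifest: dict = field(default_factory=dict)


def run_corpus(n_patients: int = 30, master_seed: int = 0,
               population: PopulationSpec | None = None,
               solver: SolverOptions | None = None,
               variance_threshold: float = 0.94,
               out_dir: str | Path | None = None,
               progress: bool = False) -> CorpusResult:
    """Generate the full synthetic training corpus.

    For every patient: build the skull, draw the surgical design of
    experiments, run each spring simulation; then fit the input SSM on
    the pre-operative shapes and the output SSM on all simulated
    outcomes, and assemble the regression dataset.  Byte-identical output
    for a fixed ``master_seed``.
    """
    population = population or PopulationSpec()
    solver = solver or SolverOptions()
    t0 = time.time()

    patients = {i: p for i, p in enumerate(sample_population(n_patients, master_seed, population))}
    skulls: dict[int, SkullModel] = {}
    plans: dict[int, DoEPlan] = {}
    preop: dict[int, np.ndarray] = {}
    sims: dict[tuple[int, int], np.ndarray] = {}
    openings: dict[tuple[int, int], dict[str, float]] = {}
    scales: dict[int, float] = {}

    # shapes enter the shape models volume-normalised (overall cranial size
    # is removed here, and restored at prediction time, under the same
    # unchanged-volume assumption used to compare against follow-up scans)
    v_ref = reference_skull_volume(population)

    for pid, params in patients.items():
        seed_i = derive_patient_seed(master_seed, pid)
        skull = build_skull(params, population)
        skulls[pid] = skull
        from cranioplan.mesh import mesh_volume

        scale = (v_ref / mesh_volume(skull.mesh, warn_open=False)) ** (1.0 / 3.0)
        scales[pid] = scale
        preop[pid] = scale * flatten_shape(skull.mesh)
        plan = generate_doe(params, seed_i, patient_id=pid)
        plans[pid] = plan
        for cid, cfg in enumerate(plan.configs):
            cut = apply_osteotomy(skull, cfg)
            result = simulate(cut, cfg, solver)
            sims[(pid, cid)] = scale * flatten_shape(result.postop_mesh)
            openings[(pid, cid)] = result.spring_openings
        if progress:
            print(f"patient {pid}: {len(plan)} simulations done "
                  f"({time.time() - t0:.1f}s elapsed)", flush=True)

    ssm_in = StatisticalShapeModel(variance_threshold=variance_threshold)
    ssm_in.fit(np.vstack([preop[p] for p in sorted(preop)]))
    ssm_out = StatisticalShapeModel(variance_threshold=variance_threshold)
    ssm_out.fit(np.vstack([sims[k] for k in sorted(sims)]))

    dataset = assemble_dataset(ssm_in, ssm_out, plans, patients, preop, sims)

    template_faces = skulls[0].mesh.faces
    manifest = {
        "n_patients": n_patients,
        "master_seed": master_seed,
        "n_simulations": len(sims),
        "n_input_modes": ssm_in.n_modes_,
        "n_output_modes": ssm_out.n_modes_,
        "n_columns": dataset.shape[1],
        "reference_volume_mm3": v_ref,
        "elapsed_s": round(time.time() - t0, 2),
    }
    result = CorpusResult(
        patients=patients, skulls=skulls, plans=plans, preop_shapes=preop,
        sim_shapes=sims, openings=openings, volume_scales=scales,
        reference_volume=v_ref, ssm_in=ssm_in, ssm_out=ssm_out,
        dataset=dataset, template_faces=template_faces,
        master_seed=master_seed, manifest=manifest,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dataset.to_csv(out_dir / "dataset.csv", float_format="%.12g")
        pd.concat([plan.to_dataframe() for plan in plans.values()]).to_csv(
            out_dir / "doe_plans.csv", index=False)
        ssm_in.save(out_dir / "ssm_in", faces=template_faces)
        ssm_out.save(out_dir / "ssm_out", faces=template_faces)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def train_surrogate(corpus: CorpusResult, kind: str = "svm", tune: bool = True,
                    hyperparams: dict | None = None, n_iter: int = 50,
                    test_fraction: float = 0.33, seed: int = 0):
    """Split/standardise the corpus dataset and fit (optionally tune) a surrogate.

    Returns ``(model, report, split)`` where the report's metrics are on
    the held-out test partition, standardised output-mode scale.
    """
    split = split_and_scale(corpus.dataset, test_fraction=test_fraction, seed=seed)
    model = SurrogateRegressor(kind=kind, hyperparams=hyperparams, tune=tune,
                               n_iter=n_iter, seed=seed)
    model.fit(split.X_train, split.Y_train)
    report = model.report(split.X_test, split.Y_test)
    return model, report, split


@dataclass
class PredictionReport:
    predicted_mesh: TriangleMesh
    preop_ci: float
    predicted_ci: float
    config: SurgicalConfig
    b_in: np.ndarray
    b_out: np.ndarray
    error_map: np.ndarray | None = None
    mean_error: float | None = None
    max_error: float | None = None
    elapsed_s: float = 0.0


def predict_outcome(preop_head: TriangleMesh, age_days: float, config: SurgicalConfig,
                    corpus: CorpusResult, model: SurrogateRegressor, split: SplitData,
                    t_skin: float = 3.42, reference: TriangleMesh | None = None,
                    is_head: bool = True) -> PredictionReport:
    """Predict the post-operative head shape for one patient and configuration.

    Pipeline: (head -> inward skin offset ->) template correspondence ->
    projection onto the input shape model -> feature assembly ->
    standardise -> surrogate prediction -> reconstruction from output
    modes -> outward skin offset back to the soft-tissue surface.  If the
    input mesh is not on the template topology it is registered with
    non-rigid ICP first.
    """
    t0 = time.time()
    from cranioplan.mesh import mesh_volume

    skull_mesh = offset_mesh(preop_head, t_skin, "inward") if is_head else preop_head
    template = unflatten_shape(corpus.ssm_in.mean_, corpus.template_faces)
    if skull_mesh.n_vertices != template.n_vertices:
        corr = nricp(template, skull_mesh)
        skull_mesh = corr.deformed_template

    # volume-normalise (as the training shapes were); the inverse scale is
    # applied to the prediction — cranial volume is assumed unchanged
    scale = (corpus.reference_volume / mesh_volume(skull_mesh, warn_open=False)) ** (1.0 / 3.0)
    b_in = corpus.ssm_in.project(scale * flatten_shape(skull_mesh))
    features = {
        "age_days": float(age_days),
        "A": config.A, "AP": config.AP, "LAT": config.LAT,
        "ant_k": config.anterior_spring.stiffness,
        "ant_L0": config.anterior_spring.free_length,
        "post_k": config.posterior_spring.stiffness,
        "post_L0": config.posterior_spring.free_length,
    }
    row = np.array([features[c] if c in features else b_in[int(c.split("_")[-1]) - 1]
                    for c in split.feature_names], dtype=float)
    if len(row) != model.n_features_in_:
        raise ValueError(f"feature row has {len(row)} entries, model expects "
                         f"{model.n_features_in_}")
    x = split.x_scaler.transform(row[None])
    y_std = model.predict(x)
    b_out = split.y_scaler.inverse_transform(y_std)[0]

    skull_pred = unflatten_shape(corpus.ssm_out.reconstruct(b_out) / scale,
                                 corpus.template_faces)
    head_pred = offset_mesh(skull_pred, t_skin, "outward")

    report = PredictionReport(
        predicted_mesh=head_pred,
        preop_ci=cranial_index(preop_head),
        predicted_ci=cranial_index(head_pred),
        config=config, b_in=b_in, b_out=b_out,
        elapsed_s=time.time() - t0,
    )
    if reference is not None:
        dm = surface_distance(head_pred, reference)
        report.error_map = dm.distances
        report.mean_error = dm.mean
        report.max_error = dm.max
    return report


def evaluate_validation(predicted: TriangleMesh, reference: TriangleMesh,
                        volume_match: bool = True) -> dict:
    """Surface-error report between a predicted and a reference surface.

    The reference is first uniformly rescaled to the predicted volume
    (removing growth under the unchanged-volume assumption), then
    unsigned distances are taken in both directions.
    """
    ref = volume_match_scale(reference, predicted) if volume_match else reference
    fwd = surface_distance(predicted, ref)
    bwd = surface_distance(ref, predicted)
    both = np.concatenate([fwd.distances, bwd.distances])
    return {
        "mean_error_mm": float(both.mean()),
        "max_error_mm": float(both.max()),
        "p95_error_mm": float(np.percentile(both, 95)),
        "forward_mean_mm": fwd.mean,
        "backward_mean_mm": bwd.mean,
        "per_vertex_forward": fwd.distances,
        "per_vertex_backward": bwd.distances,
    }


def correlation_analysis(errors, covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-case mean error against each covariate.

    Returns a table of r and two-sided p per covariate; zero-variance
    covariates yield undefined (NaN) correlations.
    """
    errors = np.asarray(errors, dtype=float)
    if len(errors) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    for col in covariates.columns:
        x = covariates[col].to_numpy(dtype=float)
        if len(x) != len(errors):
            raise ValueError(f"covariate {col!r} length mismatch")
        if np.std(x) == 0 or np.std(errors) == 0:
            rows.append({"covariate": col, "r": np.nan, "p": np.nan,
                         "note": "zero variance"})
            continue
        r, p = pearsonr(errors, x)
        rows.append({"covariate": col, "r": float(r), "p": float(p), "note": ""})
    return pd.DataFrame(rows).set_index("covariate")
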