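"""Configuration-driven orchestration of the full analysis.

Three entry points, each writing machine-readable artifacts plus a
provenance record (config hash, seed, package version):

* :func:`run_simulate` — synthetic study generation (feature table CSV,
  marker ground truth, provenance);
* :func:`run_discriminate` — autoscale -> PCA with group confidence
  ellipses -> one-vs-rest PLS-DA -> VIP marker selection -> double CV ->
  permutation test, with CSV/JSON/figure outputs;
* :func:`run_optimize_doe` — fiber comparison, response-surface fits and
  desirability optimization from a DoE response table.

The CLI in :mod:`cheesevoc.cli` is a thin shell over these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Literal

import matplotlib
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import __version__
from .chemometrics import (
    DEFAULT_VIP_CUTOFF,
    Autoscaler,
    PrincipalComponents,
    PLSDAClassifier,
    confidence_ellipse,
    select_markers,
    vip_per_class,
)
from .chromatography import FeatureTable
from .doe import (
    STUDY_FACTORS,
    Factor,
    compare_fibers,
    default_spec_for_surface,
    fit_response_surface,
    generate_ccd,
    optimize_dom,
)
from .exceptions import ConfigurationError, DataError
from .synthetic import SyntheticStudyConfig, generate_voc_table
from .validation import double_cross_validate, permutation_test

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

log = logging.getLogger("cheesevoc")


class SyntheticBlock(BaseModel):
    cheese: Literal["brie", "camembert"] = "camembert"
    n_control: int = Field(default=45, ge=1)
    n_per_dose: int = Field(default=15, ge=1)
    effect_size: float = Field(default=3.0, ge=1.0)
    noise_sigma: float = Field(default=0.25, ge=0.0)


class InputBlock(BaseModel):
    feature_table: str


class ChemometricsBlock(BaseModel):
    n_pca_components: int = Field(default=2, ge=2)
    ellipse_level: float = Field(default=0.95, gt=0, lt=1)
    vip_cutoff: float = Field(default=DEFAULT_VIP_CUTOFF, gt=0)
    max_lv: int = Field(default=5, ge=1)


class ValidationBlock(BaseModel):
    outer_k: int = Field(default=5, ge=2)
    inner_k: int = Field(default=5, ge=2)
    n_repetitions: int = Field(default=20, ge=1)
    permutation_iterations: int = Field(default=1000, ge=1)


class DoeBlock(BaseModel):
    n_center: int = Field(default=3, ge=1)
    grid_resolution: int = Field(default=201, ge=2)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML or JSON on disk)."""

    synthetic: SyntheticBlock | None = None
    input: InputBlock | None = None
    chemometrics: ChemometricsBlock = ChemometricsBlock()
    validation: ValidationBlock = ValidationBlock()
    doe: DoeBlock = DoeBlock()
    seed: int | None = None

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "PipelineConfig":
        if (self.synthetic is None) == (self.input is None):
            raise ValueError(
                "exactly one of 'synthetic' and 'input' must be present"
            )
        if self.synthetic is not None and self.seed is None:
            raise ValueError("seed is mandatory when stochastic stages run")
        return self


def load_config(path) -> PipelineConfig:
    import yaml

    try:
        raw = yaml.safe_load(Path(path).read_text())
    except Exception as exc:  # bad YAML/JSON
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(x) for x in e["loc"]) + ": " + e["msg"]
            for e in exc.errors()
        )
        raise ConfigurationError(f"invalid config: {locs}") from exc


def _provenance(config: PipelineConfig, seed: int | None) -> dict[str, Any]:
    dump = config.model_dump_json()
    return {
        "config": json.loads(dump),
        "config_sha256": hashlib.sha256(dump.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }


def _write_provenance(out_dir: Path, config: PipelineConfig, seed: int | None):
    (out_dir / "provenance.json").write_text(
        json.dumps(_provenance(config, seed), indent=2) + "\n"
    )


def run_simulate(config: PipelineConfig, out_dir) -> FeatureTable:
    """Generate the synthetic study and write its artifacts."""
    if config.synthetic is None:
        raise ConfigurationError("simulate requires a 'synthetic' block")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blk = config.synthetic
    log.info("simulate: cheese=%s seed=%s", blk.cheese, config.seed)
    from .synthetic import default_templates

    study = SyntheticStudyConfig(
        cheese=blk.cheese,
        n_control=blk.n_control,
        n_per_dose=blk.n_per_dose,
        seed=int(config.seed),
    )
    table = generate_voc_table(
        study,
        default_templates(
            effect_size=blk.effect_size, noise_sigma=blk.noise_sigma
        ),
    )
    table.to_csv(out / "feature_table.csv")
    (out / "markers_truth.txt").write_text(
        "\n".join(table.markers) + "\n"
    )
    _write_provenance(out, config, config.seed)
    return table


def _load_table(config: PipelineConfig, out_dir: Path) -> FeatureTable:
    if config.input is not None:
        return FeatureTable.from_csv(config.input.feature_table)
    return run_simulate(config, out_dir)


def run_discriminate(
    config: PipelineConfig, out_dir, plots: bool = True
) -> dict[str, Any]:
    """Run the full discrimination chain and write all report files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = _load_table(config, out)
    labels = table.doses.to_numpy()
    if len(np.unique(labels)) < 2:
        raise DataError("discriminate: feature table has a single class")
    X = table.data.to_numpy()
    names = list(table.data.columns)
    chem = config.chemometrics
    val = config.validation
    seed = config.seed

    log.info("discriminate: autoscale + PCA")
    scaler = Autoscaler().fit(X)
    Xs = scaler.transform(X)
    pca_model = PrincipalComponents(n_components=chem.n_pca_components).fit(Xs)
    scores = pca_model.transform(Xs)
    score_df = pd.DataFrame(
        scores,
        index=table.data.index,
        columns=[f"pc{j + 1}" for j in range(pca_model.n_components_)],
    )
    score_df["dose_kgy"] = labels
    score_df.to_csv(out / "pca_scores.csv")
    pd.DataFrame(
        pca_model.loadings_,
        index=names,
        columns=[f"pc{j + 1}" for j in range(pca_model.n_components_)],
    ).to_csv(out / "pca_loadings.csv")

    ellipses = {}
    for dose in np.unique(labels):
        ell = confidence_ellipse(
            scores[labels == dose, :2],
            label=str(dose),
            level=chem.ellipse_level,
        )
        ellipses[str(dose)] = {
            "center": ell.center.tolist(),
            "shape": ell.shape.tolist(),
            "level": ell.level,
        }
    (out / "ellipses.json").write_text(json.dumps(ellipses, indent=2) + "\n")

    log.info("discriminate: PLS-DA + VIP (cutoff %.2f)", chem.vip_cutoff)
    plsda = PLSDAClassifier(n_components=chem.max_lv, scale=True).fit(X, labels)
    per_class = vip_per_class(plsda, variable_names=names)
    vip_df = pd.DataFrame(
        {str(cls): v.as_series() for cls, v in per_class.items()}
    )
    vip_df.to_csv(out / "vip_scores.csv")
    selected = sorted(
        set().union(
            *(select_markers(v, chem.vip_cutoff) for v in per_class.values())
        )
    )
    (out / "markers_selected.txt").write_text("\n".join(selected) + "\n")

    log.info(
        "discriminate: double CV (outer %d, inner %d, reps %d)",
        val.outer_k, val.inner_k, val.n_repetitions,
    )
    report = double_cross_validate(
        X,
        labels,
        outer_k=val.outer_k,
        inner_k=val.inner_k,
        n_repetitions=val.n_repetitions,
        max_lv=chem.max_lv,
        seed=seed,
    )
    report.to_csv(out / "cv_report.csv")

    log.info(
        "discriminate: permutation test (%d iterations)",
        val.permutation_iterations,
    )
    irradiated = np.where(labels > 0, "irradiated", "control")
    perm = permutation_test(
        X,
        irradiated,
        n_iterations=val.permutation_iterations,
        n_folds=val.outer_k,
        seed=None if seed is None else seed + 1,
    )
    perm.to_frame().to_csv(out / "permutation.csv", index=False)

    if plots:
        _plot_scores(score_df, ellipses, out / "pca_scores.svg")
        _plot_vip(vip_df.max(axis=1), chem.vip_cutoff, out / "vip.svg")
    _write_provenance(out, config, seed)
    return {
        "table": table,
        "pca": pca_model,
        "plsda": plsda,
        "markers": selected,
        "cv_report": report,
        "permutation": perm,
    }


def run_optimize_doe(
    config: PipelineConfig,
    responses: pd.DataFrame,
    out_dir,
    factors: tuple[Factor, ...] = STUDY_FACTORS,
) -> dict[str, Any]:
    """Fiber comparison, surface fits and DOM optimum from a response table.

    ``responses`` columns: ``run, fiber, temp_c, time_min, y1_total_area,
    y2_n_vocs`` (fiber optional when only one coating was measured).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    needed = {"run", "y1_total_area", "y2_n_vocs"}
    if not needed.issubset(responses.columns):
        raise DataError(
            f"response table lacks columns {sorted(needed - set(responses.columns))}"
        )
    design = generate_ccd(factors, n_center=config.doe.n_center)

    result: dict[str, Any] = {}
    if "fiber" in responses.columns and responses["fiber"].nunique() > 1:
        runs_by_fiber = {}
        for fiber, grp in responses.groupby("fiber"):
            grp = grp.sort_values("run")
            missing = set(design.run_order) - set(grp["run"])
            if missing:
                raise DataError(
                    f"fiber {fiber!r} missing runs {sorted(missing)}"
                )
            runs_by_fiber[fiber] = grp["y2_n_vocs"].to_numpy()
        comp = compare_fibers(runs_by_fiber)
        result["fiber"] = {
            "selected": comp.selected,
            "dominant": comp.dominant,
            "tie": comp.tie,
            "mean_y2": comp.mean_y2,
        }
        sel = responses[responses["fiber"] == comp.selected].sort_values("run")
    else:
        sel = responses.sort_values("run")

    missing = set(design.run_order) - set(sel["run"])
    if missing:
        raise DataError(f"response table missing runs {sorted(missing)}")
    surfaces = []
    for col in ("y1_total_area", "y2_n_vocs"):
        surf = fit_response_surface(design, sel[col].to_numpy())
        surfaces.append(surf)
        result[col] = {
            "coefficients": dict(
                zip(surf.term_names, surf.coefficients.tolist())
            ),
            "r2": surf.fit_r2,
        }
    specs = [
        default_spec_for_surface(s, factors, config.doe.grid_resolution)
        for s in surfaces
    ]
    dom = optimize_dom(surfaces, specs, factors, config.doe.grid_resolution)
    result["dom"] = {
        "optimum": dom.optimum,
        "d_max": dom.d_max,
        "d_individual": list(dom.d_individual),
        "tie": dom.tie,
    }
    (out / "dom_report.json").write_text(json.dumps(result, indent=2) + "\n")
    _write_provenance(out, config, config.seed)
    return result


def _plot_scores(score_df: pd.DataFrame, ellipses: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    for dose, grp in score_df.groupby("dose_kgy"):
        ax.scatter(grp["pc1"], grp["pc2"], s=18, label=f"{dose} kGy")
    for label, e in ellipses.items():
        center = np.asarray(e["center"])
        shape = np.asarray(e["shape"])
        theta = np.linspace(0, 2 * np.pi, 200)
        circ = np.column_stack([np.cos(theta), np.sin(theta)])
        try:
            L = np.linalg.cholesky(shape)
        except np.linalg.LinAlgError:
            continue
        b = center + circ @ L.T
        ax.plot(b[:, 0], b[:, 1], lw=1, alpha=0.7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(title="dose")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_vip(vip: pd.Series, cutoff: float, path: Path) -> None:
    top = vip.sort_values(ascending=False).head(30)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.barh(top.index[::-1], top.values[::-1])
    ax.axvline(cutoff, color="red", lw=1, ls="--")
    ax.set_xlabel("VIP score")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
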