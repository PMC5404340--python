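"""End-to-end orchestration: volumes in, shape model and quality metrics out.

Workflow per run: extract/smooth/decimate/dualize every sample; pick the
most average sample as template; affinely initialize the template to each
target with GMM L2 registration; precompute the VFC energy volume per
target; greedily evolve the initialized template in each energy volume (the
converged vertex positions define the point correspondence); GPA-align the
corresponded landmark vectors; build the PCA model; evaluate compactness,
generalization and specificity.  Every stage's outputs and the resolved
configuration can be written to a run directory; reruns with identical
config and seed are bitwise identical.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import PipelineStageError
from .gmm import mesh_to_gmm, register_affine, select_template, apply_affine, _mean_edge_length
from .greedy import EvolutionParams, evolve
from .mesh import SimplexMesh, save_simplex_mesh
from .metrics import metric_curves
from .ssm import ShapeModel, build_model, gpa_align, save_model
from .surface import simplex_from_volume
from .vfc import build_kernel, compute_edge_map, compute_vfc_field, energy_from_field
from .volume import LabelVolume, read_volume

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "export_variation_map"]


@dataclass
class PipelineConfig:
    """All pipeline parameters plus optional input/output paths."""

    # surface extraction
    iso_level: float = 0.5
    smooth_iterations: int = 20
    smooth_passband: float = 0.1
    target_faces: int = 2500
    closing: bool = False
    # GMM affine initialization
    gmm_scale_mm: float | None = None      # None -> mean edge length per mesh
    gmm_max_components: int = 1000
    # VFC energy
    vfc_R: int = 256
    vfc_gamma: float = 1.7
    vfc_eps_div: float = 1e-8
    vfc_magnitude: str = "m1"
    vfc_zeta: float = 1.0
    edge_sigma: float = 1.0
    # greedy evolution
    alpha: float = 0.4
    beta: float = 1.0
    w: int = 11
    max_iters: int = 200
    move_tol: float = 0.1
    # model building / evaluation
    gpa_scaling: bool = False
    n_samples: int = 10000
    metric_units: str = "rms"
    seed: int = 0
    # I/O
    input_paths: list = field(default_factory=list)
    out_dir: str | None = None

    def validate(self) -> None:
        if self.iso_level <= 0 or self.iso_level >= 1:
            raise ValueError("iso_level must be in (0, 1)")
        if self.target_faces < 4:
            raise ValueError("target_faces must be >= 4")
        if self.vfc_R < 1:
            raise ValueError("vfc_R must be >= 1")
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError("w must be odd and >= 3")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.metric_units not in ("rms", "sq"):
            raise ValueError("metric_units must be 'rms' or 'sq'")


def _stage(name: str, ident, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineStageError(f"stage '{name}' failed on input {ident!r}: {exc}") from exc


def energy_volume_for(vol: LabelVolume, config: PipelineConfig):
    """Edge map + VFC kernel + convolution for one target volume."""
    edge = compute_edge_map(vol, sigma=config.edge_sigma)
    R = min(config.vfc_R, max(vol.shape))
    if R != config.vfc_R:
        logger.info("VFC kernel radius clipped from %d to %d (volume %s); "
                    "the kernel decays so the truncation error is bounded",
                    config.vfc_R, R, vol.shape)
    kernel = build_kernel(R, config.vfc_magnitude, gamma=config.vfc_gamma,
                          zeta=config.vfc_zeta, eps_div=config.vfc_eps_div)
    field_ = compute_vfc_field(edge, kernel)
    return energy_from_field(field_, vol.spacing, vol.origin)


def run_pipeline(config: PipelineConfig, volumes: list | None = None):
    """Execute the full workflow.

    ``volumes`` may be in-memory :class:`LabelVolume` objects; otherwise
    ``config.input_paths`` are read.  Returns ``(fitted_meshes, model,
    curves)``; writes per-stage outputs to ``config.out_dir`` when set.
    """
    config.validate()
    if volumes is None:
        volumes = [_stage("read", p, read_volume, p) for p in config.input_paths]
    idents = (config.input_paths if config.input_paths
              else [f"volume[{i}]" for i in range(len(volumes))])
    if len(volumes) < 2:
        raise ValueError("the pipeline needs at least 2 training volumes")
    for ident, vol in zip(idents, volumes):
        _stage("validate", ident, vol.validate_binary)

    meshes = [_stage("surface", ident, simplex_from_volume, vol,
                     level=config.iso_level,
                     smooth_iterations=config.smooth_iterations,
                     passband=config.smooth_passband,
                     target_faces=config.target_faces,
                     closing=config.closing)
              for ident, vol in zip(idents, volumes)]

    t_idx = _stage("template", "all", select_template, meshes,
                   scale=config.gmm_scale_mm,
                   max_components=min(config.gmm_max_components, 250))
    template = meshes[t_idx]
    logger.info("template: sample %d (%s)", t_idx, idents[t_idx])
    t_scale = config.gmm_scale_mm or _mean_edge_length(template)
    t_gmm = mesh_to_gmm(template, t_scale, max_components=config.gmm_max_components)

    params = EvolutionParams(alpha=config.alpha, beta=config.beta, w=config.w,
                             max_iters=config.max_iters, move_tol=config.move_tol)
    fitted = []
    for i, (ident, vol) in enumerate(zip(idents, volumes)):
        if i == t_idx:
            init = template.copy()
        else:
            s = config.gmm_scale_mm or _mean_edge_length(meshes[i])
            g = mesh_to_gmm(meshes[i], s, max_components=config.gmm_max_components)
            T = _stage("gmm-init", ident, register_affine, t_gmm, g)
            init = apply_affine(template, T)
        ev = _stage("vfc-energy", ident, energy_volume_for, vol, config)
        mesh, report = _stage("evolve", ident, evolve, init, ev, params,
                              log=logger.info)
        logger.info("sample %s: %d iterations, converged=%s", ident,
                    report.iterations, report.converged)
        fitted.append(mesh)

    shapes = np.stack([m.vertices.ravel() for m in fitted])
    aligned = _stage("gpa", "all", gpa_align, shapes,
                     with_scaling=config.gpa_scaling)
    model = _stage("ssm", "all", build_model, aligned)
    K = len(aligned)
    mode_range = range(1, min(model.n_modes, K - 2) + 1) if K >= 3 else []
    curves = _stage("metrics", "all", metric_curves, model, aligned,
                    mode_range=mode_range, n_samples=config.n_samples,
                    seed=config.seed, units=config.metric_units)

    if config.out_dir:
        _write_outputs(config, fitted, aligned, model, curves, t_idx)
    return fitted, model, curves


def _write_outputs(config, fitted, aligned, model, curves, t_idx) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = dataclasses.asdict(config)
    resolved["template_index"] = int(t_idx)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh)
    for i, mesh in enumerate(fitted):
        save_simplex_mesh(mesh, out / f"fitted_{i:03d}.ply")
    np.savetxt(out / "aligned_shapes.csv", aligned, delimiter=",")
    save_model(model, out / "model.npz")
    with open(out / "metrics.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metric", "M", "mean", "sd", "units"])
        for curve in curves:
            for m, mu, sd in zip(curve.modes, curve.mean, curve.sd):
                writer.writerow([curve.metric, m, f"{mu:.9g}", f"{sd:.9g}",
                                 curve.units])


def export_variation_map(model: ShapeModel, mean_mesh: SimplexMesh):
    """Per-landmark total variance as a scalar attribute on the mean mesh.

    ``var_k = sum_m lambda_m * ||mode_m at landmark k||^2`` (mm^2); the
    attribute sums over landmarks to the total variance.  Returns
    ``(mesh, var)`` with the mesh vertices set to the model mean.
    """
    if mean_mesh.n_vertices != model.N:
        raise ValueError(f"mesh has {mean_mesh.n_vertices} vertices but the "
                         f"model has N={model.N} landmarks")
    comp = model.modes.reshape(model.N, 3, model.n_modes)
    var = np.einsum("m,kim->k", model.eigenvalues, comp ** 2)
    out = mean_mesh.copy()
    out.vertices = model.mean.reshape(model.N, 3)
    return out, var
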