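"""Shape-model quality metrics: compactness, generalization, specificity.

Compactness is the cumulative variance of the first M modes.  Generalization
is the leave-one-out reconstruction error of held-out training shapes;
specificity is the distance from randomly synthesized shapes (coefficients
uniform in ``+-3 sqrt(lambda_m)``) to their nearest training shape.

Units: the defining sums are squared norms, but reported model-quality
numbers in this field are mm-scale distances, so the default ``units='rms'``
reports the root-mean point-to-point distance per shape pair,
``||x - x'|| / sqrt(N)`` in mm; ``units='sq'`` gives the raw squared norm
(mm^2).  The choice is logged once per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ssm import ShapeModel, build_model, _align_one, _as_matrix, project, synthesize

logger = logging.getLogger(__name__)

__all__ = ["MetricCurve", "compactness", "generalization", "specificity",
           "metric_curves"]


@dataclass
class MetricCurve:
    """One metric evaluated over a range of mode counts."""

    metric: str
    modes: list
    mean: list
    sd: list
    units: str


def _pair_error(x: np.ndarray, y: np.ndarray, units: str) -> np.ndarray:
    d = np.linalg.norm(np.atleast_2d(x) - np.atleast_2d(y), axis=-1)
    if units == "rms":
        return d / np.sqrt(x.shape[-1] / 3)
    if units == "sq":
        return d ** 2
    raise ValueError(f"unknown units {units!r}")


def compactness(model: ShapeModel, M: int) -> float:
    """Cumulative variance of the first ``M`` modes (mm^2)."""
    if M < 0:
        raise ValueError("M must be >= 0")
    if M > model.n_modes:
        raise ValueError(f"M={M} exceeds available modes ({model.n_modes})")
    return float(model.eigenvalues[:M].sum())


def generalization(shapes, M: int, units: str = "rms",
                   with_rotation: bool = False) -> tuple:
    """Leave-one-out reconstruction error with ``M`` modes: ``(mean, sd)``.

    For every training shape, a model is rebuilt from the other K-1 shapes;
    the held-out shape is re-centered on the leave-one-out mean centroid
    (pose must not count as shape error), projected onto the first M modes
    and reconstructed.  The inputs are expected to be jointly GPA-aligned
    already, so only the translation is re-estimated by default;
    ``with_rotation=True`` additionally Procrustes-rotates the held-out
    shape onto the leave-one-out mean (note a rotation moves an in-span
    shape out of the mode span, so exact reconstructions become approximate).
    """
    X = _as_matrix(shapes)
    K = len(X)
    if K < 3:
        raise ValueError("generalization needs at least 3 shapes")
    if M > K - 2:
        raise ValueError(f"M={M} exceeds the K-2={K - 2} modes a "
                         "leave-one-out model can have")
    logger.info("generalization: units=%s", units)
    errs = []
    for i in range(K):
        rest = np.delete(X, i, axis=0)
        model = build_model(rest)
        mean_pts = model.mean.reshape(-1, 3)
        offset = mean_pts.mean(axis=0)
        held_pts = X[i].reshape(-1, 3)
        held = (held_pts - held_pts.mean(axis=0)).ravel()
        if with_rotation:
            held = _align_one(held, (mean_pts - offset).ravel(), False)
        held = held + np.tile(offset, model.N)
        Mi = min(M, model.n_modes)
        b = project(model, held, Mi)
        recon = model.mean + model.modes[:, :Mi] @ b
        errs.append(_pair_error(held, recon, units)[0])
    errs = np.asarray(errs)
    return float(errs.mean()), float(errs.std(ddof=1))


def specificity(model: ShapeModel, shapes, M: int, n_samples: int = 10000,
                seed: int | None = None, units: str = "rms",
                chunk: int = 512) -> tuple:
    """Monte-Carlo specificity with ``M`` modes: ``(mean, sd)``.

    Draws ``n_samples`` shapes with coefficients uniform on
    ``[-3 sqrt(lambda_m), +3 sqrt(lambda_m)]`` and measures each sample's
    distance to its nearest training shape (exact linear scan).
    Deterministic given ``seed``.
    """
    X = _as_matrix(shapes)
    if len(X) == 0:
        raise ValueError("specificity needs a nonempty training set")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if M > model.n_modes:
        raise ValueError(f"M={M} exceeds available modes ({model.n_modes})")
    logger.info("specificity: units=%s, n_samples=%d", units, n_samples)
    rng = np.random.default_rng(seed)
    bound = 3.0 * np.sqrt(model.eigenvalues[:M])
    coeffs = rng.uniform(-1.0, 1.0, size=(n_samples, M)) * bound
    dmin = np.empty(n_samples)
    for s in range(0, n_samples, chunk):
        sl = slice(s, min(s + chunk, n_samples))
        samples = model.mean + coeffs[sl] @ model.modes[:, :M].T
        d = np.linalg.norm(samples[:, None, :] - X[None, :, :], axis=-1)
        dmin[sl] = d.min(axis=1)
    if units == "rms":
        errs = dmin / np.sqrt(model.N)
    elif units == "sq":
        errs = dmin ** 2
    else:
        raise ValueError(f"unknown units {units!r}")
    sd = float(errs.std(ddof=1)) if n_samples > 1 else 0.0
    return float(errs.mean()), sd


def metric_curves(model: ShapeModel, shapes, mode_range=None,
                  n_samples: int = 1000, seed: int | None = None,
                  units: str = "rms") -> list:
    """All three metrics over a range of mode counts, as MetricCurve rows."""
    X = _as_matrix(shapes)
    K = len(X)
    if mode_range is None:
        mode_range = range(1, min(model.n_modes, K - 2) + 1)
    mode_range = [int(m) for m in mode_range]
    comp = MetricCurve("compactness", mode_range,
                       [compactness(model, m) for m in mode_range],
                       [0.0] * len(mode_range), "mm^2")
    gen_vals = [generalization(X, m, units=units) for m in mode_range]
    gen = MetricCurve("generalization", mode_range,
                      [v[0] for v in gen_vals], [v[1] for v in gen_vals],
                      "mm" if units == "rms" else "mm^2")
    spec_vals = [specificity(model, X, m, n_samples=n_samples, seed=seed,
                             units=units) for m in mode_range]
    spec = MetricCurve("specificity", mode_range,
                       [v[0] for v in spec_vals], [v[1] for v in spec_vals],
                       "mm" if units == "rms" else "mm^2")
    return [comp, gen, spec]
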