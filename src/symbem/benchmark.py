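"""Sphere benchmark harness: regular/random 3-layer models, z-axis dipoles,
RDM/MAG scoring against the analytic solutions.

The reference configuration is three nested spheres of radii 0.088 / 0.092
/ 0.100 m with conductivities (1, 1/80, 1) S/m, five dipoles on the z axis
with orientation (1, 0, 1) at configurable relative depths, EEG electrodes
at every scalp vertex and magnetometers at radius 0.120 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

import dataclasses

from .assembly import (OperatorCache, assemble_dipole_source_matrix,
                       assemble_head_matrix, dipsource2meg, head2eeg,
                       head2meg)
from .mesh import (DipoleSet, HeadModel, make_icosphere,
                   make_random_sphere_mesh, meg_sensors, project_electrodes)
from .metrics import mag, rdm
from .operators import QuadratureConfig
from .sphere import SphereModel, eeg_sphere_potential, meg_sphere_field

__all__ = ["BenchmarkConfig", "BenchmarkResult", "run_benchmark",
           "run_paired_benchmark", "DEFAULT_DEPTHS"]

#: Relative dipole depths z / rho_1, shallow to near-boundary.
DEFAULT_DEPTHS = (0.50, 0.70, 0.85, 0.93, 0.97)


@dataclass(frozen=True)
class BenchmarkConfig:
    mesh_type: str = "regular"           # "regular" | "random"
    level: int = 2                        # icosphere level (regular)
    n_vertices: int = 600                 # per layer (random)
    n_models: int = 1                     # repetitions (random meshes)
    seed: int = 0
    radii: tuple[float, ...] = (0.088, 0.092, 0.100)
    conductivities: tuple[float, ...] = (1.0, 1.0 / 80.0, 1.0)
    depths: tuple[float, ...] = DEFAULT_DEPTHS
    orientation: tuple[float, float, float] = (1.0, 0.0, 1.0)
    moment: float = 1e-8                  # A*m
    modality: str = "EEG"                 # "EEG" | "MEG"
    meg_radius: float = 0.120
    meg_orientation: str = "fixed"        # "fixed" (1,0,1) | "radial"
    adaptive: bool = True                 # OM (True) vs OMNA (False)
    quad_tol: float = 1e-4
    series_order: int = 100

    def __post_init__(self):
        if self.mesh_type not in ("regular", "random"):
            raise ValueError("mesh_type must be 'regular' or 'random'")
        if self.modality not in ("EEG", "MEG"):
            raise ValueError("modality must be 'EEG' or 'MEG'")
        if any(r <= 0 for r in self.radii) or any(
                s <= 0 for s in self.conductivities):
            raise ValueError("radii and conductivities must be positive")
        if max(self.depths) >= 1.0:
            raise ValueError("dipoles must lie inside the innermost sphere")


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    rows: list[dict] = field(default_factory=list)  # per (model, dipole)

    def table(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def summary(self) -> dict:
        """Median / quartile / whisker statistics per metric."""
        out = {}
        for key in ("rdm", "mag"):
            vals = np.array([r[key] for r in self.rows])
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
            out[key] = {"median": float(med), "q1": float(q1),
                        "q3": float(q3), "iqr": float(iqr),
                        "whisker_low": float(lo), "whisker_high": float(hi),
                        "n": int(len(vals))}
        return out


def _build_model(cfg: BenchmarkConfig, seeds) -> HeadModel:
    if cfg.mesh_type == "regular":
        meshes = tuple(make_icosphere(r, cfg.level) for r in cfg.radii)
    else:
        meshes = tuple(
            make_random_sphere_mesh(r, cfg.n_vertices, int(s))
            for r, s in zip(cfg.radii, seeds))
    return HeadModel(meshes, cfg.conductivities)


def _dipoles(cfg: BenchmarkConfig) -> DipoleSet:
    q = np.asarray(cfg.orientation, float)
    q = q / np.linalg.norm(q) * cfg.moment
    pos = [[0.0, 0.0, d * cfg.radii[0]] for d in cfg.depths]
    return DipoleSet(pos, [q] * len(cfg.depths))


def run_benchmark(cfg: BenchmarkConfig) -> BenchmarkResult:
    """Run the full pipeline for every mesh instance and score each dipole
    column against the matching analytic solution.  Fully seeded: the same
    configuration and seed reproduce identical tables."""
    quad = QuadratureConfig(adaptive=cfg.adaptive, tol=cfg.quad_tol)
    sphere = SphereModel(cfg.radii, cfg.conductivities, L=cfg.series_order)
    dipoles = _dipoles(cfg)
    rng = np.random.SeedSequence(cfg.seed)
    n_models = 1 if cfg.mesh_type == "regular" else cfg.n_models
    model_seeds = rng.generate_state(3 * n_models).reshape(n_models, 3)

    result = BenchmarkResult(cfg)
    for im in range(n_models):
        model = _build_model(cfg, model_seeds[im])
        try:
            rows = _score_model(cfg, model, dipoles, quad, sphere, im)
        except Exception as exc:  # annotate the failing instance
            raise RuntimeError(
                f"benchmark failed on model {im} "
                f"(seed {cfg.seed}, {cfg.mesh_type})") from exc
        result.rows.extend(rows)
    for r in result.rows:
        assert 0.0 <= r["rdm"] <= 2.0 and r["mag"] > 0.0
    return result


def run_paired_benchmark(cfg: BenchmarkConfig):
    """Run the adaptive (OM) and non-adaptive (OMNA) solvers on identical
    mesh instances, sharing the far-pair quadrature between the two modes.

    Returns ``(result_adaptive, result_nonadaptive)``.
    """
    cfg_om = dataclasses.replace(cfg, adaptive=True)
    cfg_na = dataclasses.replace(cfg, adaptive=False)
    quad_om = QuadratureConfig(adaptive=True, tol=cfg.quad_tol)
    quad_na = QuadratureConfig(adaptive=False, tol=cfg.quad_tol)
    sphere = SphereModel(cfg.radii, cfg.conductivities, L=cfg.series_order)
    dipoles = _dipoles(cfg)
    rng = np.random.SeedSequence(cfg.seed)
    n_models = 1 if cfg.mesh_type == "regular" else cfg.n_models
    model_seeds = rng.generate_state(3 * n_models).reshape(n_models, 3)

    res_om = BenchmarkResult(cfg_om)
    res_na = BenchmarkResult(cfg_na)
    for im in range(n_models):
        model = _build_model(cfg, model_seeds[im])
        far = OperatorCache.far_only(model, quad_na)
        oracle = _analytic_columns(cfg, dipoles.resolve(model), sphere,
                                   model)
        for quad, cfg_i, res in ((quad_om, cfg_om, res_om),
                                 (quad_na, cfg_na, res_na)):
            cache = OperatorCache(model, quad, far_cache=far)
            try:
                rows = _score_model(cfg_i, model, dipoles, quad, sphere, im,
                                    cache=cache, oracle=oracle)
            except Exception as exc:
                raise RuntimeError(
                    f"benchmark failed on model {im} "
                    f"(seed {cfg.seed}, adaptive={quad.adaptive})") from exc
            res.rows.extend(rows)
    return res_om, res_na


def _analytic_columns(cfg, dip, sphere, model):
    """Analytic reference column per dipole for the configured modality."""
    if cfg.modality == "EEG":
        scalp = model.scalp
        return [eeg_sphere_potential(sphere, dip.positions[i],
                                     dip.moments[i], scalp.vertices)
                for i in range(len(dip))]
    pts, dirs = _meg_layout(cfg)
    return [meg_sphere_field(dip.positions[i], dip.moments[i], pts, dirs)
            for i in range(len(dip))]


def _meg_layout(cfg):
    pts = make_icosphere(cfg.meg_radius, 1).vertices
    if cfg.meg_orientation == "radial":
        dirs = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    else:
        d = np.asarray(cfg.orientation, float)
        dirs = np.tile(d / np.linalg.norm(d), (len(pts), 1))
    return pts, dirs


def _score_model(cfg, model, dipoles, quad, sphere, im, cache=None,
                 oracle=None):
    dip = dipoles.resolve(model)
    head = assemble_head_matrix(model, quad, cache=cache, check=False)
    src = assemble_dipole_source_matrix(model, dip, quad)
    lu = scipy.linalg.lu_factor(head.matrix)
    x = scipy.linalg.lu_solve(lu, src.matrix)
    if oracle is None:
        oracle = _analytic_columns(cfg, dip, sphere, model)

    if cfg.modality == "EEG":
        scalp = model.scalp
        electrodes = project_electrodes(scalp.vertices, scalp)
        g = head2eeg(model, electrodes).matrix @ x
        g -= g.mean(axis=0, keepdims=True)
    else:
        pts, dirs = _meg_layout(cfg)
        sens = meg_sensors(pts, dirs)
        g = head2meg(model, sens, quad).matrix @ x \
            + dipsource2meg(dip, sens).matrix
    return [_row(cfg, im, idip, g[:, idip], oracle[idip])
            for idip in range(len(dip))]


def _row(cfg, im, idip, gn, ga):
    return {
        "model": im,
        "dipole": idip,
        "depth": cfg.depths[idip],
        "modality": cfg.modality,
        "adaptive": cfg.adaptive,
        "rdm": rdm(gn, ga),
        "mag": mag(gn, ga),
    }
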