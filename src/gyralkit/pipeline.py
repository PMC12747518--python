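"""End-to-end pipeline: synth -> simulate -> morphometry -> map -> compare.

A single TOML config drives the whole chain; every stage reads and writes
declared files only, so deleting intermediates and rerunning reproduces
them bit for bit (all stages are seeded).  The manifest records the
config snapshot, content hashes of every output, per-stage wall-clock and
the quantities of record (energy traces, landmark residuals, similarity
table).

The demo profile compares the two hemispheres of one simulated brain:
the folded surface is dissected at the midsagittal plane, the right
hemisphere is mirrored onto the left's side, both are normalized by half
their longitudinal extent, flattened to disks, aligned on synthetic
landmark curves and scored with the p-norm similarity index.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

from . import io as gio
from .growth import GrowthConfig, extract_boundary_surface, run_growth
from .morphometry import classify_shape, curvature_field, histogram_modes
from .similarity import compare_surfaces
from .synth import make_brainlike_solid, make_landmark_curves
from .types import ScalarField, TriSurface

__all__ = ["RunManifest", "run_pipeline", "DEMO_CONFIG", "folding_reproduction"]


def folding_reproduction(seed: int = 1, n_bins: int = 64, prominence: float = 0.1):
    """Scaled-down in-silico folding of a ferret-like brain solid.

    Study conditions: growth ratio 1.8, stiffness ratio 1, normalized
    cortical thickness 0.1 - 0.005 t, step-wise protocol (the relaxed
    geometry becomes the new stress-free reference at each stage
    boundary, with stages emulating the successive fetal reference
    geometries of ferret development).  The solid is a seeded perturbed
    ellipsoid with semi-axes (1, 0.8, 0.7) and a surface layer two to
    three elements thick (~66k tets).

    Returns (surface, curvature_field, probabilities, smoothed_histogram,
    bin_centers): the folded boundary surface, its morphometry and the
    shape-index histogram of the final state.
    """
    from scipy.ndimage import gaussian_filter1d

    volume = make_brainlike_solid(
        seed=seed,
        semi_axes=(1.0, 0.8, 0.7),
        n_modes=4,
        amplitude=0.05,
        target_edge=0.09,
        shell_fractions=(1.0, 0.95, 0.88, 0.78, 0.62),
    )
    config = GrowthConfig(
        g_g=1.8,
        mu_g=1.0,
        mu_w=1.0,
        h0=0.1,
        h_slope=0.005,
        protocol="step-wise",
        stage_times=(0.2, 0.4, 0.6, 0.8),
        g_increment=0.04,
        max_iters=1000,
        force_tol=1e-5,
        seed=seed,
    )
    final = run_growth(volume, config)[-1]
    surface = extract_boundary_surface(final)
    cf = curvature_field(surface)
    probs, _ = histogram_modes(cf.SI, n_bins=n_bins, prominence=prominence)
    smooth = gaussian_filter1d(probs.astype(float), 1.5, mode="constant")
    centers = np.linspace(-1.0 + 1.0 / n_bins, 1.0 - 1.0 / n_bins, n_bins)
    return surface, cf, probs, smooth, centers


@dataclass
class RunManifest:
    config: dict
    outputs: dict = dfield(default_factory=dict)  # path -> sha256
    stages: dict = dfield(default_factory=dict)  # stage -> wall seconds
    results: dict = dfield(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "outputs": self.outputs,
            "stages": self.stages,
            "results": self.results,
        }

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


DEMO_CONFIG = """\
# gyralkit demo profile: ferret-like ellipsoid, folded step-wise,
# hemispheres compared against each other.
[synth]
seed = 1
semi_axes = [1.0, 0.8, 0.7]
n_modes = 4
amplitude = 0.05
target_edge = 0.14

[simulate]
growth_ratio = 1.8
stiffness_ratio = 1.0
thickness = 0.1
thickness_slope = 0.005
protocol = "step-wise"
stage_times = [0.5]
g_increment = 0.1
max_iters = 400
force_tol = 1e-5

[landmarks]
n_curves = 3
seed = 7
min_separation = 0.15

[compare]
measures = ["si", "htilde"]
p_norms = ["1", "2", "inf"]
landmark_tol = 1e-3

[morphometry]
n_bins = 64
prominence = 0.1
"""


def run_pipeline(config_path, out_dir=None) -> RunManifest:
    """Execute the configured pipeline; returns the manifest.

    Any stage failure aborts with the stage name; the partial manifest is
    attached to the raised exception as ``exc.manifest``.
    """
    config_path = Path(config_path)
    cfg = tomllib.loads(config_path.read_text())
    out = Path(out_dir) if out_dir else config_path.parent / "pipeline_out"
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    stage = "setup"
    try:
        # ---- synth
        stage = "synth"
        t0 = time.perf_counter()
        scfg = cfg.get("synth", {})
        volume = make_brainlike_solid(
            seed=int(scfg.get("seed", 1)),
            semi_axes=tuple(scfg.get("semi_axes", (1.0, 0.8, 0.7))),
            n_modes=int(scfg.get("n_modes", 4)),
            amplitude=float(scfg.get("amplitude", 0.05)),
            target_edge=float(scfg.get("target_edge", 0.14)),
        )
        vol_path = out / "initial_volume.vtk"
        gio.write_mesh(volume, vol_path)
        manifest.outputs[str(vol_path)] = _sha256(vol_path)
        manifest.stages[stage] = time.perf_counter() - t0

        # ---- simulate
        stage = "simulate"
        t0 = time.perf_counter()
        mcfg = cfg.get("simulate", {})
        stiffness_ratio = float(mcfg.get("stiffness_ratio", 1.0))
        gconf = GrowthConfig(
            g_g=float(mcfg.get("growth_ratio", 1.8)),
            mu_g=1.0,
            mu_w=1.0 / stiffness_ratio,
            h0=float(mcfg.get("thickness", 0.1)),
            h_slope=float(mcfg.get("thickness_slope", 0.005)),
            protocol=str(mcfg.get("protocol", "continuous")),
            stage_times=tuple(mcfg.get("stage_times", ())),
            g_increment=float(mcfg.get("g_increment", 0.02)),
            max_iters=int(mcfg.get("max_iters", 1500)),
            force_tol=float(mcfg.get("force_tol", 1e-5)),
        )
        snaps = run_growth(volume, gconf)
        final = snaps[-1]
        folded = extract_boundary_surface(final)
        folded_path = out / "folded_surface.off"
        gio.write_mesh(folded, folded_path)
        manifest.outputs[str(folded_path)] = _sha256(folded_path)
        manifest.results["final_energy"] = final.total_energy
        manifest.results["energy_trace_len"] = len(final.energy_trace)
        manifest.stages[stage] = time.perf_counter() - t0

        # ---- morphometry on the whole folded surface
        stage = "morphometry"
        t0 = time.perf_counter()
        ocfg = cfg.get("morphometry", {})
        cf = curvature_field(folded)
        si_path = out / "shape_index.csv"
        gio.write_mesh(ScalarField(cf.SI), si_path)
        manifest.outputs[str(si_path)] = _sha256(si_path)
        probs, modes = histogram_modes(
            cf.SI[~cf.boundary_mask],
            n_bins=int(ocfg.get("n_bins", 64)),
            prominence=float(ocfg.get("prominence", 0.1)),
        )
        hist_path = out / "si_histogram.json"
        hist_path.write_text(
            json.dumps(
                {
                    "probabilities": probs.tolist(),
                    "modes": modes.tolist(),
                    "classes": classify_shape(cf.SI),
                },
                indent=1,
            )
        )
        manifest.outputs[str(hist_path)] = _sha256(hist_path)
        manifest.results["si_modes"] = modes.tolist()
        manifest.stages[stage] = time.perf_counter() - t0

        # ---- dissect, normalize, landmarks, map, compare
        stage = "compare"
        t0 = time.perf_counter()
        lcfg = cfg.get("landmarks", {})
        ccfg = cfg.get("compare", {})
        left = gio.cut_hemisphere(folded, (0, 0, 0), (0, 0, 1))
        right = gio.cut_hemisphere(folded, (0, 0, 0), (0, 0, -1))
        # mirror the right hemisphere onto the left's side
        right = TriSurface(
            right.vertices * np.array([1.0, 1.0, -1.0]), right.faces[:, ::-1]
        )
        left = gio.normalize_halflength(left)
        right = gio.normalize_halflength(right)
        lm_seed = int(lcfg.get("seed", 7))
        n_curves = int(lcfg.get("n_curves", 3))
        sep = float(lcfg.get("min_separation", 0.15))
        lm_left = make_landmark_curves(left, n_curves, lm_seed, sep)
        lm_right = _transfer_landmarks(left, lm_left, right)
        for name, surf, lm in (("left", left, lm_left), ("right", right, lm_right)):
            p = out / f"hemisphere_{name}.off"
            gio.write_mesh(surf, p)
            manifest.outputs[str(p)] = _sha256(p)
            p = out / f"landmarks_{name}.json"
            gio.write_mesh(lm, p)
            manifest.outputs[str(p)] = _sha256(p)
        p_norms = [
            np.inf if str(p) == "inf" else float(p)
            for p in ccfg.get("p_norms", ["1", "2", "inf"])
        ]
        reports = compare_surfaces(
            left,
            right,
            lm_left,
            lm_right,
            p_list=p_norms,
            measures=tuple(ccfg.get("measures", ("si", "htilde"))),
            landmark_tol=float(ccfg.get("landmark_tol", 1e-3)),
        )
        table = [r.to_dict() for r in reports]
        rep_path = out / "similarity_report.json"
        rep_path.write_text(json.dumps(table, indent=1))
        manifest.outputs[str(rep_path)] = _sha256(rep_path)
        manifest.results["similarity"] = table
        manifest.stages[stage] = time.perf_counter() - t0
    except Exception as exc:
        exc.manifest = manifest  # partial manifest for debugging
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest.save(out / "manifest.json")
    return manifest


def _transfer_landmarks(src_surface, curves, dst_surface):
    """Carry landmark curves from one hemisphere to the other by nearest
    vertices (the mirrored hemisphere has different connectivity), then
    repair into valid edge paths via shortest paths."""
    from scipy.spatial import cKDTree

    from .synth import _dijkstra_path, _surface_graph
    from .types import LandmarkCurve

    tree = cKDTree(dst_surface.vertices)
    graph = _surface_graph(dst_surface)
    blocked = np.zeros(dst_surface.n_vertices, dtype=bool)
    blocked[dst_surface.boundary_vertices()] = True
    out = []
    for c in curves:
        _, nearest = tree.query(src_surface.vertices[c.vertex_path])
        ends = (int(nearest[0]), int(nearest[-1]))
        blocked[list(ends)] = False
        path = _dijkstra_path(graph, ends[0], ends[1], blocked)
        if path is None or len(path) < 2:
            raise RuntimeError(f"could not transfer landmark '{c.name}'")
        out.append(LandmarkCurve(path, name=c.name))
        blocked[path] = True
    return out
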