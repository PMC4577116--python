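"""The in-silico indentation experiments and their derived metrics.

Four studies are provided, mirroring the capabilities of the multiscale
corpuscle model:

* isolated-corpuscle indentation (displacement transmission down the z axis
  and per-element Von Mises stress, isotropic vs circumferentially aligned
  networks);
* incremental indentation (long-axis neurite strain and cross-section area
  strain versus cumulative depth);
* receptive-field mapping of skin-embedded corpuscles (one independent
  simulation per surface indentation site, shallow vs deep embedding);
* corpuscle-orientation comparison (long axis parallel vs perpendicular to
  the skin surface).

All strains are dimensionless, depths in μm, stresses in kPa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .mesh import (HexMesh, CorpuscleGeometry, EPIDERMIS, DERMIS,
                   DERMIS_VERTICAL, mesh_embedded, mesh_half_ellipsoid)
from .network import AlignmentPolicy, assign_networks
from . import fem
from .fem import (IndentationProtocol, MacroState, embedded_protocol,
                  isolated_protocol, newton_solve, pack_library)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def long_axis_strain(mesh: HexMesh, state: MacroState) -> float:
    """Linear strain (l − l₀)/l₀ of the corpuscle long axis.

    Measured between the two interface nodes of the ``long_axis_pair`` node
    set along the mesh's long-axis direction (y for horizontal models, z for
    the vertically oriented corpuscle) — the model's proxy for neurite
    stretch.
    """
    if "long_axis_pair" not in mesh.node_sets:
        raise ValueError("mesh has no long_axis_pair node set")
    a, b = mesh.node_sets["long_axis_pair"]
    ax = int(mesh.geometry_params.get("long_axis_index", 1))
    l0 = mesh.node_coords[b, ax] - mesh.node_coords[a, ax]
    l = l0 + state.u[b, ax] - state.u[a, ax]
    return float((l - l0) / l0)


def von_mises(tensor: np.ndarray, kind: str = "stress") -> float:
    """Deviatoric equivalent scalar of a symmetric 3×3 tensor.

    ``kind='stress'`` uses the √(3/2 s:s) convention (uniaxial σ → σ, pure
    shear τ → √3 τ); ``kind='strain'`` uses the equivalent-strain convention
    √(2/3 e:e). Raises on significant asymmetry.
    """
    T = np.asarray(tensor, dtype=float)
    asym = np.linalg.norm(T - T.T)
    if asym > 1e-6 * max(np.linalg.norm(T), 1e-30) and asym > 1e-12:
        raise ValueError("von Mises of a non-symmetric tensor")
    dev = T - np.trace(T) / 3.0 * np.eye(3)
    j2 = float((dev * dev).sum())
    factor = 1.5 if kind == "stress" else 2.0 / 3.0
    return float(np.sqrt(factor * j2))


def element_von_mises_stress(state: MacroState) -> np.ndarray:
    """Per-element Von Mises stress (kPa): mean over the 8 Gauss points."""
    S = state.S_gp
    Ssym = 0.5 * (S + np.swapaxes(S, -1, -2))
    dev = Ssym - (np.trace(Ssym, axis1=-2, axis2=-1) / 3.0)[..., None, None] * np.eye(3)
    vm = np.sqrt(1.5 * (dev ** 2).sum(axis=(-2, -1)))
    return vm.mean(axis=1)


def element_von_mises_strain(state: MacroState) -> np.ndarray:
    """Per-element equivalent (Von Mises) Green–Lagrange strain.

    E = ½(FᵀF − I) per Gauss point, equivalent-strain convention with the
    2/3 deviatoric factor, averaged over the element's 8 points. Multiply by
    1e3 for millistrain.
    """
    F = state.F_gp
    C = np.einsum("egki,egkj->egij", F, F)
    E = 0.5 * (C - np.eye(3))
    dev = E - (np.trace(E, axis1=-2, axis2=-1) / 3.0)[..., None, None] * np.eye(3)
    vm = np.sqrt(2.0 / 3.0 * (dev ** 2).sum(axis=(-2, -1)))
    return vm.mean(axis=1)


def area_strain(mesh: HexMesh, state: MacroState) -> float:
    """Relative area change of the corpuscle's x–z cross-section at y = 0.

    Shoelace area over the deformed ``midplane_loop`` boundary node loop;
    raises if the deformed loop self-intersects (signed area collapses).
    """
    if "midplane_loop" not in mesh.node_sets:
        raise ValueError("mesh has no midplane_loop node set")
    loop = mesh.node_sets["midplane_loop"]
    ref = mesh.node_coords[loop][:, [0, 2]]
    cur = ref + state.u[loop][:, [0, 2]]

    def shoelace(p):
        x, z = p[:, 0], p[:, 1]
        return 0.5 * float(np.sum(x * np.roll(z, -1) - z * np.roll(x, -1)))

    a0 = abs(shoelace(ref))
    a1 = shoelace(cur)
    if a1 * shoelace(ref) <= 0:
        raise ValueError("deformed cross-section loop self-intersects")
    return (abs(a1) - a0) / a0


def peak_vm_near_indenter(mesh: HexMesh, state: MacroState,
                          protocol: IndentationProtocol) -> float:
    """Peak per-element Von Mises stress among elements adjacent to the
    indenter footprint (elements owning at least one footprint node)."""
    foot = set(int(n) for n in fem.footprint_nodes(mesh, protocol))
    vm = element_von_mises_stress(state)
    near = np.array([
        e for e in range(mesh.n_elements)
        if foot.intersection(mesh.elements[e].tolist())
    ])
    if len(near) == 0:
        raise ValueError("no element adjacent to the indenter footprint")
    return float(vm[near].max())


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class StrainCurve:
    """Metric value after each cumulative indentation increment."""

    depths: np.ndarray        # μm, strictly increasing
    values: np.ndarray        # dimensionless metric (ε_yy or area strain)
    metric: str = "long_axis_strain"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.depths) != len(self.values):
            raise ValueError("one value per increment required")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")

    def to_dict(self) -> dict:
        return {"metric": self.metric, "depths": self.depths.tolist(),
                "values": self.values.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StrainCurve":
        return cls(d["depths"], d["values"], d.get("metric", ""))


@dataclass
class ReceptiveFieldMap:
    """Long-axis strain per surface indentation site (independent solves)."""

    sites: np.ndarray         # (n, 2) x, y site positions, μm
    strains: np.ndarray       # (n,) ε along the corpuscle long axis
    depth: float = 10.0       # μm indentation per site
    model: str = ""
    quarter: bool = True      # sites restricted to the x ≥ 0, y ≥ 0 quarter
    failed_sites: list = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failed_sites

    def coefficient_of_variation(self) -> float:
        """CV of |strain| across sites: the spatial-sensitivity measure (a
        deep receptor shows a lower CV = a flatter, larger receptive field)."""
        v = np.abs(self.strains)
        return float(v.std() / max(v.mean(), 1e-30))

    def mirrored(self) -> "ReceptiveFieldMap":
        """Reflect a quarter map into the full surface for presentation."""
        if not self.quarter:
            return self
        pts = [self.sites]
        vals = [self.strains]
        for sx, sy in ((-1, 1), (1, -1), (-1, -1)):
            mask = ~((self.sites[:, 0] == 0) & (sx < 0)) \
                & ~((self.sites[:, 1] == 0) & (sy < 0))
            pts.append(self.sites[mask] * [sx, sy])
            vals.append(self.strains[mask])
        return ReceptiveFieldMap(np.vstack(pts), np.concatenate(vals),
                                 self.depth, self.model, quarter=False,
                                 failed_sites=list(self.failed_sites))

    def zero_contour(self) -> np.ndarray:
        """Sign-change crossings of the strain along grid rows (x varying at
        fixed y): linear interpolation; the boundary of the responsive
        region."""
        pts = []
        for y in np.unique(self.sites[:, 1]):
            row = self.sites[:, 1] == y
            xs = self.sites[row, 0]
            vs = self.strains[row]
            order = np.argsort(xs)
            xs, vs = xs[order], vs[order]
            for i in range(len(xs) - 1):
                if vs[i] == 0.0:
                    pts.append((xs[i], y))
                elif vs[i] * vs[i + 1] < 0:
                    t = vs[i] / (vs[i] - vs[i + 1])
                    pts.append((xs[i] + t * (xs[i + 1] - xs[i]), y))
        return np.asarray(pts).reshape(-1, 2)

    def to_dict(self) -> dict:
        return {
            "sites": self.sites.tolist(), "strains": self.strains.tolist(),
            "depth": self.depth, "model": self.model, "quarter": self.quarter,
            "failed_sites": list(self.failed_sites),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReceptiveFieldMap":
        return cls(np.asarray(d["sites"], dtype=float),
                   np.asarray(d["strains"], dtype=float),
                   float(d["depth"]), d.get("model", ""),
                   bool(d.get("quarter", True)),
                   list(d.get("failed_sites", [])))


# ---------------------------------------------------------------------------
# model assembly from a RunConfig
# ---------------------------------------------------------------------------

_EMBEDDINGS = {"epidermis": EPIDERMIS, "dermis": DERMIS,
               "dermis_vertical": DERMIS_VERTICAL}


def build_mesh(config: RunConfig) -> HexMesh:
    pc = CorpuscleGeometry()
    if config.model == "isolated":
        return mesh_half_ellipsoid(pc, resolution=int(config.resolution))
    return mesh_embedded(_EMBEDDINGS[config.model], pc,
                         resolution=float(config.resolution))


def policies_for(config: RunConfig, corpuscle_kind: str | None = None) -> dict:
    kind = corpuscle_kind or config.corpuscle_policy
    pol = {"corpuscle": AlignmentPolicy(kind, config.stretch_ratio)
           if kind != "isotropic" else AlignmentPolicy("isotropic")}
    if config.model != "isolated":
        pol["skin"] = AlignmentPolicy(config.skin_policy, config.stretch_ratio,
                                      frame_source="global") \
            if config.skin_policy != "isotropic" else AlignmentPolicy("isotropic")
    return pol


def build_library(config: RunConfig, mesh: HexMesh,
                  corpuscle_kind: str | None = None):
    return assign_networks(mesh, policies_for(config, corpuscle_kind),
                           seed=config.seed,
                           fiber_count_range=config.fiber_count_range)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

@dataclass
class IsolatedResult:
    """Outcome of one isolated-corpuscle indentation."""

    policy: str
    depth: float
    axis_z: np.ndarray          # reference z of the top-axis probe nodes, μm
    axis_uz: np.ndarray         # their vertical displacements, μm
    midplane_ref: np.ndarray    # y=0 cross-section nodes, reference (x, z)
    midplane_def: np.ndarray    # same nodes, deformed
    vm_stress: np.ndarray       # per-element Von Mises stress, kPa
    peak_vm_near_indenter: float
    states: list = field(default_factory=list)


def run_isolated_indentation(config: RunConfig,
                             policies=("surface_aligned_corpuscle", "isotropic"),
                             mesh: HexMesh | None = None) -> dict:
    """10 μm (by default) indentation of the isolated corpuscle.

    Runs once per requested corpuscle network policy and reports the
    displacement of the nodes along the top of the z-axis (the transmission
    profile), the y = 0 midplane nodal positions (nodal-gap visualization)
    and the per-element Von Mises stress field.
    """
    mesh = mesh or build_mesh(config)
    out = {}
    for kind in policies:
        lib = build_library(config, mesh, corpuscle_kind=kind)
        prot = isolated_protocol(mesh, increments=config.increments,
                                 diameter=config.indenter_diameter,
                                 center=config.indenter_center)
        states = newton_solve(mesh, prot, lib, config.params,
                              tol_rel=config.tol_rel, tol_abs=config.tol_abs,
                              max_iter=config.max_iter,
                              eq4_correction=config.eq4_correction)
        s = states[-1]
        axis = mesh.node_sets["top_z_line"]
        order = np.argsort(-mesh.node_coords[axis, 2])
        axis = axis[order]
        mid = mesh.node_sets["midplane_loop"]
        out[kind] = IsolatedResult(
            policy=kind,
            depth=float(s.depth),
            axis_z=mesh.node_coords[axis, 2].copy(),
            axis_uz=s.u[axis, 2].copy(),
            midplane_ref=mesh.node_coords[mid][:, [0, 2]].copy(),
            midplane_def=(mesh.node_coords[mid] + s.u[mid])[:, [0, 2]],
            vm_stress=element_von_mises_stress(s),
            peak_vm_near_indenter=peak_vm_near_indenter(mesh, s, prot),
            states=states,
        )
    return out


def run_incremental(config: RunConfig, n_steps: int = 25, step_size: float = 1.0,
                    policies=("surface_aligned_corpuscle", "isotropic"),
                    with_area: bool = True,
                    mesh: HexMesh | None = None) -> dict:
    """Incremental indentation of the isolated corpuscle.

    Returns {policy: {'long_axis': StrainCurve, 'area': StrainCurve}} with
    the long-axis strain (and, when the mesh provides the midplane loop, the
    cross-section area strain) after every cumulative increment.
    """
    mesh = mesh or build_mesh(config)
    out = {}
    for kind in policies:
        lib = build_library(config, mesh, corpuscle_kind=kind)
        prot = isolated_protocol(mesh, increments=(step_size,) * n_steps,
                                 diameter=config.indenter_diameter,
                                 center=config.indenter_center)
        states = newton_solve(mesh, prot, lib, config.params,
                              tol_rel=config.tol_rel, tol_abs=config.tol_abs,
                              max_iter=config.max_iter)
        depths = [s.depth for s in states]
        eps = [long_axis_strain(mesh, s) for s in states]
        curves = {"long_axis": StrainCurve(depths, eps, "long_axis_strain"),
                  "states": states}
        if with_area and "midplane_loop" in mesh.node_sets:
            curves["area"] = StrainCurve(
                depths, [area_strain(mesh, s) for s in states], "area_strain")
        out[kind] = curves
    return out


def run_receptive_field(config: RunConfig, sites: np.ndarray | None = None,
                        mesh: HexMesh | None = None,
                        lib=None) -> ReceptiveFieldMap:
    """Map the receptive field of an embedded corpuscle.

    One independent simulation per surface site (single-node indentation to
    the protocol depth); by default the site grid is the surface nodes of
    the symmetric x ≥ 0, y ≥ 0 quarter within ``config.rf_extent`` of the
    center. A failed site is recorded and leaves the map marked incomplete.
    """
    if config.model == "isolated":
        raise ValueError("receptive fields require an embedded model")
    mesh = mesh or build_mesh(config)
    lib = lib or build_library(config, mesh)
    packed = pack_library(lib)
    surf = mesh.node_sets["surface"]
    xy = mesh.node_coords[surf, :2]
    quarter = sites is None
    if sites is None:
        keep = (xy[:, 0] >= 0) & (xy[:, 1] >= 0) \
            & (np.linalg.norm(xy, axis=1) <= config.rf_extent)
        sites = xy[keep]
    sites = np.asarray(sites, dtype=float)
    strains = np.zeros(len(sites))
    failed = []
    for i, (sx, sy) in enumerate(sites):
        packed.xcur[:] = packed.net_ref  # fresh micro state per site
        prot = embedded_protocol(mesh, site=(sx, sy),
                                 increments=config.increments, kind="node")
        try:
            states = newton_solve(mesh, prot, packed, config.params,
                                  tol_rel=config.tol_rel,
                                  tol_abs=config.tol_abs,
                                  max_iter=config.max_iter)
            strains[i] = long_axis_strain(mesh, states[-1])
        except Exception as exc:  # noqa: BLE001 — record and continue
            logger.warning("site (%g, %g) failed: %s", sx, sy, exc)
            failed.append(i)
            strains[i] = np.nan
    return ReceptiveFieldMap(sites, strains,
                             depth=float(np.sum(config.increments)),
                             model=config.model, quarter=quarter,
                             failed_sites=failed)


def run_orientation_study(config_h: RunConfig, config_v: RunConfig,
                          sites=None) -> dict:
    """Horizontal vs vertical dermally-embedded corpuscle receptive fields."""
    if config_v.model != "dermis_vertical":
        raise ValueError("config_v must use the dermis_vertical model")
    return {
        "horizontal": run_receptive_field(config_h, sites=sites),
        "vertical": run_receptive_field(config_v, sites=sites),
    }
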