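"""Synthetic vascular phantoms with full ground truth.

Generates random quasi-planar vessel networks (centerlines, radii, wall
permeabilities), rasterizes them into binary z-stack masks, and simulates
two-photon time-series of two dextran tracer channels: intravascular signal
follows plasma concentration ``C_p(t) = C0 * exp(-k_c * t)`` (renal
clearance), a perivascular shell fills by first-order exchange
``dC_e/dt = P_eff * (C_p - C_e)``, the extravascular pool spreads by Gaussian
diffusion, and the volume is degraded by PSF blur and Poisson-Gaussian noise.

Ground truth (masks, centerline length, branch count, per-point diameters,
noise-free outside/inside curves) is recorded before blur and noise so every
downstream stage of the analysis can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from vasomet.stack_io import TimeSeriesStack

DEFAULT_TIMEPOINTS_MIN = tuple(float(t) for t in range(5, 65, 5))
DEFAULT_CHANNELS = (("FITC40", 40.0, 1.0), ("TRITC70", 70.0, 0.0))


class PhantomError(ValueError):
    """Raised for invalid phantom specifications or network requests."""


@dataclass(frozen=True)
class PhantomSpec:
    """Acquisition and simulation parameters for one phantom volume.

    Geometry defaults mirror the two-photon protocol being emulated:
    512x512 frames, five z-layers at 1 um spacing, one frame every 5 min
    over 1 h, and a 40 kDa (permeable) plus a 70 kDa (size-excluded)
    dextran channel.
    """

    frame_shape: tuple[int, int] = (512, 512)
    n_layers: int = 5
    layer_spacing_um: float = 1.0
    pixel_size_um: float = 1.0
    timepoints_min: tuple[float, ...] = DEFAULT_TIMEPOINTS_MIN
    clearance_rate_kc: float = 0.02
    tracer_channels: tuple[tuple[str, float, float], ...] = DEFAULT_CHANNELS
    # Diffraction-limited two-photon PSF of a 0.8 NA water objective at
    # 860 nm excitation: lateral FWHM ~0.24 um, axial FWHM ~1.2 um.
    psf_sigma_um: float = 0.1
    psf_axial_sigma_um: float = 0.5
    noise_model: tuple[float, float] = (2.0, 1.0)  # (gaussian_sd, poisson_gain)
    seed: int = 0
    shell_width_um: float = 3.0
    diffusion_sigma_um: float = 1.0  # extravascular spreading per minute step
    intensity_scale: float = 1000.0
    boundary: str = "closed"  # 'closed' (reflecting) or 'open' (absorbing)

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints_min, dtype=float)
        if tp.ndim != 1 or tp.size == 0 or np.any(np.diff(tp) <= 0):
            raise PhantomError("timepoints_min must be strictly increasing")
        for name in ("clearance_rate_kc", "psf_sigma_um", "psf_axial_sigma_um",
                     "shell_width_um", "diffusion_sigma_um", "pixel_size_um",
                     "layer_spacing_um"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be >= 0")
        if self.pixel_size_um == 0 or self.layer_spacing_um == 0:
            raise PhantomError("physical spacings must be positive")
        if any(s < 0 for s in self.noise_model):
            raise PhantomError("noise parameters must be >= 0")
        for _, mw, scale in self.tracer_channels:
            if mw <= 0 or scale < 0:
                raise PhantomError("channel molecular weight > 0, scale >= 0")
        if self.boundary not in ("closed", "open"):
            raise PhantomError("boundary must be 'closed' or 'open'")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.tracer_channels)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extents of the imaged volume in um."""
        ny, nx = self.frame_shape
        return (
            (self.n_layers - 1) * self.layer_spacing_um,
            (ny - 1) * self.pixel_size_um,
            (nx - 1) * self.pixel_size_um,
        )


@dataclass
class Edge:
    """One vessel segment: a polyline centerline with constant radius."""

    node_a: int
    node_b: int
    polyline_um: np.ndarray  # (n, 3) float, (z, y, x) um
    radius_um: float
    permeability_per_min: float


@dataclass
class VesselGraph:
    """Ground-truth vascular network in physical (z, y, x) um coordinates."""

    nodes: list[np.ndarray]
    edges: list[Edge]
    bounding_box_um: tuple[float, float, float]
    n_components: int = 1

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for e in self.edges:
            deg[e.node_a] += 1
            deg[e.node_b] += 1
        return deg

    @property
    def branch_count(self) -> int:
        """Number of junction nodes (degree >= 3)."""
        return int(np.sum(self.degrees() >= 3))

    @property
    def total_length_um(self) -> float:
        return float(sum(_polyline_length(e.polyline_um) for e in self.edges))

    def validate(self) -> None:
        box = np.asarray(self.bounding_box_um)
        for e in self.edges:
            if e.radius_um <= 0:
                raise PhantomError("edge radius must be > 0")
            pts = np.asarray(e.polyline_um)
            if np.any(pts < -1e-9) or np.any(pts > box + 1e-9):
                raise PhantomError("polyline point outside bounding box")


@dataclass
class GroundTruth:
    """Noise-free truth recorded alongside a simulated time series."""

    true_masks: np.ndarray            # (z, y, x) bool
    true_mask_2d: np.ndarray          # (y, x) bool, max over z
    true_centerline_length_um: float
    true_branch_count: int
    centerline_points_um: np.ndarray  # (n, 3)
    centerline_diameters_um: np.ndarray
    oi_curves: dict[str, np.ndarray] = field(default_factory=dict)
    timepoints_min: tuple[float, ...] = ()


def _polyline_length(poly: np.ndarray) -> float:
    poly = np.asarray(poly, dtype=float)
    if len(poly) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _grow_path(rng: np.random.Generator, start: np.ndarray, direction: np.ndarray,
               box: np.ndarray, margin: float, step_um: float = 4.0,
               wiggle_sd: float = 0.12, max_steps: int = 400) -> np.ndarray:
    """Random slightly-wiggly path from `start`, stopped at the margin box.

    The margin applies in-plane only; z stays inside the (thin) stack.
    """
    lo = np.array([0.0, margin, margin])
    hi = np.array([box[0], box[1] - margin, box[2] - margin])
    pts = [start.copy()]
    d = _unit(direction.astype(float))
    p = start.copy()
    for _ in range(max_steps):
        # jitter heading in-plane, keep z nearly flat (superficial vessels)
        d = d + rng.normal(0.0, wiggle_sd, size=3) * np.array([0.15, 1.0, 1.0])
        d = _unit(d)
        q = p + step_um * d
        q[0] = np.clip(q[0], lo[0], hi[0])  # z pinned inside the thin stack
        if np.any(q < lo) or np.any(q > hi):
            break
        pts.append(q)
        p = q
    return np.asarray(pts)


def build_network(spec: PhantomSpec, n_segments: int = 8,
                  branch_prob: float = 0.6,
                  radius_range: tuple[float, float] = (3.0, 8.0),
                  permeability_range: tuple[float, float] = (0.005, 0.02),
                  seed: int | None = None,
                  wiggle_sd: float = 0.08) -> VesselGraph:
    """Grow a random vessel network inside the imaged volume.

    The first segment spans the field of view; each subsequent segment either
    branches off a random point of an existing vessel (probability
    ``branch_prob``, creating a degree-3 junction node) or starts a new
    disconnected vessel. Trunk vessels start at low-discrepancy (stratified)
    vertical positions so the field is covered the way well-separated
    superficial cortical vessels cover a projection, rather than piling up by
    chance. Radii are drawn per edge from ``radius_range`` and wall
    permeabilities (1/min) from ``permeability_range``.
    """
    if n_segments < 1:
        raise PhantomError("n_segments must be >= 1")
    if not (0.0 <= branch_prob <= 1.0):
        raise PhantomError("branch_prob must be a probability")
    ez, ey, ex = spec.extent_um
    box = np.array([ez, ey, ex])
    min_frame_extent = min(ey, ex)
    r_lo, r_hi = radius_range
    if r_lo <= 0 or r_hi < r_lo:
        raise PhantomError("radius_range must be a positive interval")
    if r_hi >= min_frame_extent / 4:
        raise PhantomError(
            f"radius_range upper bound {r_hi} um exceeds a quarter of the "
            f"smallest frame extent ({min_frame_extent / 4:.1f} um)")

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    margin = r_hi + 2.0 * spec.pixel_size_um
    zmid = ez / 2.0

    nodes: list[np.ndarray] = []
    edges: list[Edge] = []
    n_components = 0

    def new_node(p: np.ndarray) -> int:
        nodes.append(np.asarray(p, dtype=float))
        return len(nodes) - 1

    trunk_idx = 0
    u0 = rng.uniform()

    def new_vessel() -> None:
        nonlocal n_components, trunk_idx
        side = rng.integers(0, 2)
        # golden-ratio stratification keeps trunks spread across the frame
        frac = (u0 + 0.61803398875 * trunk_idx) % 1.0
        trunk_idx += 1
        y0 = margin + frac * (ey - 2 * margin)
        x0 = margin if side == 0 else ex - margin
        start = np.array([zmid, y0, x0])
        d = np.array([0.0, rng.uniform(-0.15, 0.15), 1.0 if side == 0 else -1.0])
        poly = _grow_path(rng, start, d, box, margin, wiggle_sd=wiggle_sd)
        if len(poly) < 2:
            return
        a, b = new_node(poly[0]), new_node(poly[-1])
        edges.append(Edge(a, b, poly, float(rng.uniform(r_lo, r_hi)),
                          float(rng.uniform(*permeability_range))))
        n_components += 1

    new_vessel()
    for _ in range(n_segments - 1):
        if edges and rng.random() < branch_prob:
            # branch: split a random edge at an interior polyline vertex
            candidates = [i for i, e in enumerate(edges)
                          if len(e.polyline_um) >= 5]
            if not candidates:
                new_vessel()
                continue
            ei = int(rng.choice(candidates))
            parent = edges[ei]
            k = int(rng.integers(2, len(parent.polyline_um) - 2))
            p_branch = parent.polyline_um[k]
            j = new_node(p_branch)
            edges[ei] = Edge(parent.node_a, j, parent.polyline_um[: k + 1],
                             parent.radius_um, parent.permeability_per_min)
            edges.append(Edge(j, parent.node_b, parent.polyline_um[k:],
                              parent.radius_um, parent.permeability_per_min))
            tangent = _unit(parent.polyline_um[min(k + 1, len(parent.polyline_um) - 1)]
                            - parent.polyline_um[k - 1])
            normal = np.array([0.0, -tangent[2], tangent[1]])
            if rng.random() < 0.5:
                normal = -normal
            d = _unit(normal + rng.normal(0, 0.2, size=3) * np.array([0.1, 1, 1]))
            poly = _grow_path(rng, p_branch.astype(float), d, box, margin)
            if len(poly) < 2:
                continue
            r_child = float(np.clip(parent.radius_um * rng.uniform(0.6, 0.9),
                                    r_lo, r_hi))
            b = new_node(poly[-1])
            edges.append(Edge(j, b, poly, r_child,
                              float(rng.uniform(*permeability_range))))
        else:
            new_vessel()

    g = VesselGraph(nodes=nodes, edges=edges, bounding_box_um=(ez, ey, ex),
                    n_components=n_components)
    g.validate()
    return g


def _voxel_grids(spec: PhantomSpec):
    nz, (ny, nx) = spec.n_layers, spec.frame_shape
    z = np.arange(nz) * spec.layer_spacing_um
    y = np.arange(ny) * spec.pixel_size_um
    x = np.arange(nx) * spec.pixel_size_um
    return z, y, x


def _segment_distance_field(spec: PhantomSpec, graph: VesselGraph,
                            pad_um: float):
    """Per-voxel distance to the nearest centerline and attributes of that edge.

    Returns (dist, radius, permeability, inside) arrays over the full volume;
    voxels farther than their nearest edge's radius + pad keep dist = +inf.
    `inside` is the union over edges of (distance <= that edge's radius), so
    overlapping vessels rasterize as the union of the individual tubes.
    Distances are exact point-to-segment distances in um.
    """
    nz, (ny, nx) = spec.n_layers, spec.frame_shape
    zs, ys, xs = _voxel_grids(spec)
    dist = np.full((nz, ny, nx), np.inf)
    rad = np.zeros((nz, ny, nx))
    perm = np.zeros((nz, ny, nx))
    inside = np.zeros((nz, ny, nx), dtype=bool)
    for e in graph.edges:
        poly = np.asarray(e.polyline_um, dtype=float)
        reach = e.radius_um + pad_um
        for p0, p1 in zip(poly[:-1], poly[1:]):
            lo = np.minimum(p0, p1) - reach
            hi = np.maximum(p0, p1) + reach
            iz = np.searchsorted(zs, [lo[0], hi[0]])
            iy = np.searchsorted(ys, [lo[1], hi[1]])
            ix = np.searchsorted(xs, [lo[2], hi[2]])
            iz1 = min(iz[1] + 1, nz)
            iy1 = min(iy[1] + 1, ny)
            ix1 = min(ix[1] + 1, nx)
            if iz[0] >= iz1 or iy[0] >= iy1 or ix[0] >= ix1:
                continue
            Z, Y, X = np.meshgrid(zs[iz[0]:iz1], ys[iy[0]:iy1], xs[ix[0]:ix1],
                                  indexing="ij")
            pts = np.stack([Z, Y, X], axis=-1)
            seg = p1 - p0
            seg_len2 = float(seg @ seg)
            if seg_len2 == 0:
                d = np.linalg.norm(pts - p0, axis=-1)
            else:
                t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0)
                proj = p0 + t[..., None] * seg
                d = np.linalg.norm(pts - proj, axis=-1)
            sub = (slice(iz[0], iz1), slice(iy[0], iy1), slice(ix[0], ix1))
            closer = d < dist[sub]
            within = closer & (d <= reach)
            dist[sub][within] = d[within]
            rad[sub][within] = e.radius_um
            perm[sub][within] = e.permeability_per_min
            inside[sub] |= d <= e.radius_um
    return dist, rad, perm, inside


def rasterize(graph: VesselGraph, spec: PhantomSpec) -> np.ndarray:
    """Binary truth masks (z, y, x): a voxel is vessel iff its center lies
    within the local radius of the nearest centerline point (union over
    overlapping vessels). An empty graph yields all-zero masks."""
    nz, (ny, nx) = spec.n_layers, spec.frame_shape
    if not graph.edges:
        return np.zeros((nz, ny, nx), dtype=bool)
    _, _, _, inside = _segment_distance_field(spec, graph, pad_um=0.0)
    return inside


def _diffuse(field3d: np.ndarray, sigma_vox: tuple[float, float, float],
             boundary: str) -> np.ndarray:
    """One extravascular spreading step. The 'closed' (reflecting) boundary
    conserves total mass; the 'open' boundary lets tracer leave the volume."""
    mode = "reflect" if boundary == "closed" else "constant"
    return ndimage.gaussian_filter(field3d, sigma=sigma_vox, mode=mode, cval=0.0)


def _oi_from_volume(volume: np.ndarray, mask2d: np.ndarray,
                    guard_band_px: int = 2) -> float:
    """Outside/inside ratio on the max projection of a noise-free volume.

    Same definition the measurement pipeline uses (see
    :func:`vasomet.permeability.oi_ratio`): outside excludes the mask dilated
    by the guard band.
    """
    mip = volume.max(axis=0)
    inside = mip[mask2d].mean()
    if guard_band_px > 0:
        guard = ndimage.binary_dilation(
            mask2d, structure=ndimage.generate_binary_structure(2, 2),
            iterations=guard_band_px)
    else:
        guard = mask2d
    outside_region = ~guard
    return float(mip[outside_region].mean() / inside)


def simulate_timeseries(graph: VesselGraph, spec: PhantomSpec,
                        guard_band_px: int = 2
                        ) -> tuple[TimeSeriesStack, GroundTruth]:
    """Simulate the two-photon acquisition of a phantom network.

    Per channel: intravascular intensity tracks plasma concentration
    ``C_p(t) = exp(-k_c t)``; the perivascular shell fills by first-order
    exchange with effective permeability (edge permeability x channel scale);
    the extravascular pool spreads by a Gaussian kernel per 1-min step. The
    ground-truth O/I curve is recorded before PSF blur and noise; frames are
    then blurred, noise is applied last, and intensities are quantized to
    16-bit counts.
    """
    if spec.clearance_rate_kc < 0:
        raise PhantomError("clearance rate must be >= 0")
    nz, (ny, nx) = spec.n_layers, spec.frame_shape
    dist, rad, perm, mask = _segment_distance_field(spec, graph,
                                                    pad_um=spec.shell_width_um)
    shell = (~mask) & (dist <= rad + spec.shell_width_um)
    mask2d = mask.any(axis=0)

    sigma_vox = (spec.diffusion_sigma_um / spec.layer_spacing_um,
                 spec.diffusion_sigma_um / spec.pixel_size_um,
                 spec.diffusion_sigma_um / spec.pixel_size_um)
    psf_vox = (spec.psf_axial_sigma_um / spec.layer_spacing_um,
               spec.psf_sigma_um / spec.pixel_size_um,
               spec.psf_sigma_um / spec.pixel_size_um)
    gauss_sd, poisson_gain = spec.noise_model
    rng = np.random.default_rng(spec.seed)

    timepoints = tuple(float(t) for t in spec.timepoints_min)
    n_t, n_c = len(timepoints), len(spec.tracer_channels)
    data = np.zeros((n_t, n_c, nz, ny, nx), dtype=np.uint16)
    oi_curves: dict[str, np.ndarray] = {}

    for ci, (label, _mw, scale) in enumerate(spec.tracer_channels):
        p_eff = perm * scale * shell
        extra = np.zeros((nz, ny, nx))
        t = 0.0
        dt = 1.0  # min
        oi = np.zeros(n_t)
        ti = 0
        t_end = timepoints[-1]
        while True:
            c_p = np.exp(-spec.clearance_rate_kc * t)
            while ti < n_t and abs(timepoints[ti] - t) < dt / 2:
                clean = spec.intensity_scale * (c_p * mask + extra)
                oi[ti] = _oi_from_volume(clean, mask2d, guard_band_px)
                blurred = ndimage.gaussian_filter(clean, sigma=psf_vox,
                                                  mode="nearest")
                noisy = blurred
                if poisson_gain > 0:
                    noisy = rng.poisson(noisy * poisson_gain) / poisson_gain
                if gauss_sd > 0:
                    noisy = noisy + rng.normal(0.0, gauss_sd, size=noisy.shape)
                data[ti, ci] = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)
                ti += 1
            if t >= t_end:
                break
            extra = extra + dt * p_eff * (c_p - extra)
            extra = _diffuse(extra, sigma_vox, spec.boundary)
            extra[mask] = 0.0  # vessel interior carries plasma, not leaked pool
            np.clip(extra, 0.0, None, out=extra)
            t += dt
        oi_curves[label] = oi

    stack = TimeSeriesStack(
        data=data, timepoints_min=timepoints,
        channel_labels=spec.channel_labels,
        pixel_size_um=spec.pixel_size_um,
        layer_spacing_um=spec.layer_spacing_um,
    )
    cl_pts, cl_dia = _centerline_samples(graph)
    truth = GroundTruth(
        true_masks=mask,
        true_mask_2d=mask2d,
        true_centerline_length_um=graph.total_length_um,
        true_branch_count=graph.branch_count,
        centerline_points_um=cl_pts,
        centerline_diameters_um=cl_dia,
        oi_curves=oi_curves,
        timepoints_min=timepoints,
    )
    return stack, truth


def _centerline_samples(graph: VesselGraph) -> tuple[np.ndarray, np.ndarray]:
    pts, dia = [], []
    for e in graph.edges:
        pts.append(np.asarray(e.polyline_um, dtype=float))
        dia.append(np.full(len(e.polyline_um), 2.0 * e.radius_um))
    if not pts:
        return np.zeros((0, 3)), np.zeros(0)
    return np.concatenate(pts), np.concatenate(dia)


def straight_tube_graph(spec: PhantomSpec, radius_um: float,
                        angle_deg: float = 0.0,
                        permeability_per_min: float = 0.01,
                        margin_um: float | None = None,
                        length_um: float | None = None) -> VesselGraph:
    """Deterministic single straight tube through the volume center.

    A workhorse test phantom: the true centerline, length, and diameter are
    known in closed form. The tube runs in the xy mid-plane at `angle_deg`
    from the x-axis and is clipped to leave `margin_um` at each end.
    """
    ez, ey, ex = spec.extent_um
    if margin_um is None:
        margin_um = radius_um + 2.0 * spec.pixel_size_um
    # snap the axis to the voxel grid so the digital centerline is unambiguous
    px = spec.pixel_size_um
    c = np.array([ez / 2.0, round(ey / 2.0 / px) * px, round(ex / 2.0 / px) * px])
    th = np.deg2rad(angle_deg)
    d = np.array([0.0, np.sin(th), np.cos(th)])
    # distance from center to margin box along +-d
    lo = np.array([0.0, margin_um, margin_um])
    hi = np.array([ez, ey - margin_um, ex - margin_um])
    tmax = np.inf
    for i in range(3):
        if abs(d[i]) > 1e-12:
            tmax = min(tmax, (hi[i] - c[i]) / d[i] if d[i] > 0 else (lo[i] - c[i]) / d[i])
    if length_um is not None:
        if length_um / 2.0 > tmax:
            raise PhantomError("requested tube length exceeds the margin box")
        tmax = length_um / 2.0
    tmin = -tmax
    n_pts = max(int(2 * tmax / 2.0), 2)
    ts = np.linspace(tmin, tmax, n_pts)
    poly = c + ts[:, None] * d
    g = VesselGraph(nodes=[poly[0], poly[-1]],
                    edges=[Edge(0, 1, poly, radius_um, permeability_per_min)],
                    bounding_box_um=(ez, ey, ex), n_components=1)
    g.validate()
    return g


def parallel_tubes_graph(spec: PhantomSpec, n_tubes: int = 4,
                         radius_range: tuple[float, float] = (3.0, 6.0),
                         seed: int | None = None,
                         wiggle_sd: float = 0.05) -> VesselGraph:
    """Non-overlapping, gently meandering vessels in disjoint y-bands.

    Each tube wanders across the field of view inside its own band, with
    band gaps wide enough that rasterized tubes can never touch — the
    ground-truth centerline length is therefore fully recoverable from the
    mask. Branch count is 0 by construction. The default wiggle keeps path
    curvature small relative to the tube radius, as for real superficial
    cortical vessels at this field size; high-curvature paths shorten their
    own medial axis and are not a useful length oracle.
    """
    if n_tubes < 1:
        raise PhantomError("n_tubes must be >= 1")
    ez, ey, ex = spec.extent_um
    r_lo, r_hi = radius_range
    if r_hi >= min(ey, ex) / 4:
        raise PhantomError("radius_range too large for the frame")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    margin = r_hi + 2.0 * spec.pixel_size_um
    band_h = (ey - 2 * margin) / n_tubes
    if band_h < 2 * r_hi + 4 * spec.pixel_size_um:
        raise PhantomError("too many tubes for non-overlapping bands")
    nodes: list[np.ndarray] = []
    edges: list[Edge] = []
    box = np.array([ez, ey, ex])
    for i in range(n_tubes):
        r = float(rng.uniform(r_lo, r_hi))
        y_lo = margin + i * band_h + r + 1.5 * spec.pixel_size_um
        y_hi = margin + (i + 1) * band_h - r - 1.5 * spec.pixel_size_um
        y0 = rng.uniform(y_lo + 0.2 * (y_hi - y_lo), y_hi - 0.2 * (y_hi - y_lo))
        # grow inside the band, reflecting the heading at band edges so the
        # path stays smooth (no clipping kinks)
        p = np.array([ez / 2.0, y0, margin])
        d = _unit(np.array([0.0, rng.uniform(-0.2, 0.2), 1.0]))
        pts = [p.copy()]
        for _ in range(400):
            d = _unit(d + rng.normal(0.0, wiggle_sd, size=3)
                      * np.array([0.0, 1.0, 1.0]))
            if d[2] <= 0.3:  # keep heading broadly along +x
                d[2] = 0.3
                d = _unit(d)
            q = p + 4.0 * d
            if not (y_lo <= q[1] <= y_hi):
                d[1] = -d[1]
                q = p + 4.0 * d
            if not (margin <= q[2] <= ex - margin) or not (y_lo <= q[1] <= y_hi):
                break
            pts.append(q)
            p = q
        poly = np.asarray(pts)
        if len(poly) < 2:
            continue
        a, b = len(nodes), len(nodes) + 1
        nodes.extend([poly[0], poly[-1]])
        edges.append(Edge(a, b, poly, r, float(rng.uniform(0.005, 0.02))))
    g = VesselGraph(nodes=nodes, edges=edges, bounding_box_um=(ez, ey, ex),
                    n_components=len(edges))
    g.validate()
    return g


def grid_graph(spec: PhantomSpec, n_horizontal: int = 3, n_vertical: int = 3,
               radius_um: float = 3.0,
               permeability_per_min: float = 0.01) -> VesselGraph:
    """Axis-aligned grid of crossing tubes with analytic branch count.

    Lines span the field of view between margins, so the four outermost
    corner crossings are degree-2 elbows; every other crossing is a degree-3
    or degree-4 junction. The analytic branch count is therefore
    ``n_horizontal * n_vertical - 4`` (for grids of at least 2x2), which the
    graph's degree census reproduces. Line spacing is uniform and far
    exceeds the junction-merging scale.
    """
    ez, ey, ex = spec.extent_um
    margin = radius_um + 2.0 * spec.pixel_size_um
    px = spec.pixel_size_um
    ys = [round(v / px) * px
          for v in np.linspace(margin, ey - margin, n_horizontal)]
    xs = [round(v / px) * px
          for v in np.linspace(margin, ex - margin, n_vertical)]
    zmid = ez / 2.0
    nodes: list[np.ndarray] = []
    node_id: dict[tuple[float, float], int] = {}

    def nid(y: float, x: float) -> int:
        key = (y, x)
        if key not in node_id:
            node_id[key] = len(nodes)
            nodes.append(np.array([zmid, y, x]))
        return node_id[key]

    edges: list[Edge] = []

    def seg(y0, x0, y1, x1):
        n_pts = max(int(np.hypot(y1 - y0, x1 - x0) / 2.0), 2)
        t = np.linspace(0, 1, n_pts)[:, None]
        poly = np.stack([np.full(n_pts, zmid),
                         y0 + t[:, 0] * (y1 - y0),
                         x0 + t[:, 0] * (x1 - x0)], axis=1)
        edges.append(Edge(nid(y0, x0), nid(y1, x1), poly, radius_um,
                          permeability_per_min))

    for y in ys:
        stops = [margin] + xs + [ex - margin]
        for x0, x1 in zip(stops[:-1], stops[1:]):
            if x1 > x0:
                seg(y, x0, y, x1)
    for x in xs:
        stops = [margin] + ys + [ey - margin]
        for y0, y1 in zip(stops[:-1], stops[1:]):
            if y1 > y0:
                seg(y0, x, y1, x)
    g = VesselGraph(nodes=nodes, edges=edges, bounding_box_um=(ez, ey, ex),
                    n_components=1)
    g.validate()
    return g


def y_junction_graph(spec: PhantomSpec, radius_um: float = 4.0,
                     permeability_per_min: float = 0.01) -> VesselGraph:
    """Single Y junction: three arms meeting at one degree-3 node."""
    ez, ey, ex = spec.extent_um
    px = spec.pixel_size_um
    cz, cy, cx = ez / 2.0, round(ey / 2 / px) * px, round(ex / 2 / px) * px
    margin = radius_um + 2.0 * spec.pixel_size_um
    arm = min(cy, cx) - margin
    tips = [(cy, cx - arm), (cy - arm, cx + 0.6 * arm), (cy + arm, cx + 0.6 * arm)]
    nodes = [np.array([cz, cy, cx])]
    edges: list[Edge] = []
    for ty, tx in tips:
        n_pts = max(int(np.hypot(ty - cy, tx - cx) / 2.0), 2)
        t = np.linspace(0, 1, n_pts)[:, None]
        poly = np.stack([np.full(n_pts, cz),
                         cy + t[:, 0] * (ty - cy),
                         cx + t[:, 0] * (tx - cx)], axis=1)
        nodes.append(np.array([cz, ty, tx]))
        edges.append(Edge(0, len(nodes) - 1, poly, radius_um,
                          permeability_per_min))
    g = VesselGraph(nodes=nodes, edges=edges, bounding_box_um=(ez, ey, ex),
                    n_components=1)
    g.validate()
    return g
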