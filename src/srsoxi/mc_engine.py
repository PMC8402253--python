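"""Weighted Monte Carlo photon transport with detector-ring path tallies.

The engine launches a pencil beam at the origin of a layered
:class:`~srsoxi.tissue_models.TissueModel`, records the geometric path length
each photon accumulates in every depth slab (or voxel, in ``full_3d`` mode),
and, when the photon escapes through the top surface, credits its exit weight
``I_i`` and weighted paths ``L_i I_i`` to the annular detector ring containing
its exit radius.  Those per-ring aggregates are exactly the inputs of the
mean partial path length

    L = sum_i L_i I_i / sum_i I_i

from which SRS measurement sensitivities are built (:mod:`srsoxi.sensitivity`).

Detectors are concentric annuli rather than points: a pencil beam on
laterally homogeneous layers is cylindrically symmetric, so every photon
exiting at radius r is statistically a detection at any azimuth.  In
``full_3d`` mode each detected photon's trajectory is first rotated about the
z axis so its exit point lies on +x, placing both detectors of a pair on a
common axis before voxel binning.

A single run with fine contiguous annuli (default 0.5 mm wide, spanning
0-31 mm) serves every detector pair at once: rings are additive, so any
nominal detector of width w centered at rho is the union of fine rings
covering [rho - w/2, rho + w/2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from . import _kernel as K
from .errors import (
    AnisotropyRangeError,
    ConfigValidationError,
    GeometryMismatchError,
    MemoryGuardError,
)
from .tissue_models import TissueModel

#: Upper bound (bytes) on a full-3D tally allocation before refusing to run.
FULL3D_MEMORY_BUDGET = 2_000_000_000

STATUS_NAMES = {
    K.ST_DETECTED: "detected",
    K.ST_ESCAPED: "escaped",
    K.ST_TRANSMITTED: "transmitted",
    K.ST_ROULETTED: "rouletted",
    K.ST_TERMINATED: "terminated",
}


@dataclass(frozen=True)
class DetectorAnnuli:
    """Concentric detector rings on the top surface.

    ``ring_edges`` are strictly increasing radii (mm); ring k is the
    half-open annulus [edges[k], edges[k+1]).  Photons exiting outside
    [edges[0], edges[-1]) are tallied as escaped.
    """

    ring_edges: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.ring_edges, dtype=np.float64)
        if edges.ndim != 1 or edges.size < 2:
            raise ConfigValidationError("ring_edges needs at least two radii")
        if edges[0] < 0 or np.any(np.diff(edges) <= 0):
            raise ConfigValidationError(
                "ring_edges must be >= 0 and strictly increasing"
            )
        object.__setattr__(self, "ring_edges", edges)

    @classmethod
    def uniform(cls, width: float, r_max: float, r0: float = 0.0) -> "DetectorAnnuli":
        """Contiguous rings of equal width from ``r0`` to at least ``r_max``."""
        if width <= 0:
            raise ConfigValidationError("ring width must be > 0")
        n = int(np.ceil((r_max - r0) / width))
        return cls(r0 + width * np.arange(n + 1))

    @property
    def n_rings(self) -> int:
        return self.ring_edges.size - 1

    @property
    def ring_centers(self) -> np.ndarray:
        return 0.5 * (self.ring_edges[:-1] + self.ring_edges[1:])

    def ring_areas(self) -> np.ndarray:
        e = self.ring_edges
        return np.pi * (e[1:] ** 2 - e[:-1] ** 2)

    def interval_slice(self, r_lo: float, r_hi: float) -> slice:
        """Slice of rings exactly covering [r_lo, r_hi).

        Raises GeometryMismatchError when the interval does not align with
        ring edges (tolerance 1e-9 mm).
        """
        e = self.ring_edges
        i0 = int(np.argmin(np.abs(e - r_lo)))
        i1 = int(np.argmin(np.abs(e - r_hi)))
        if abs(e[i0] - r_lo) > 1e-9 or abs(e[i1] - r_hi) > 1e-9 or i1 <= i0:
            raise GeometryMismatchError(
                f"interval [{r_lo}, {r_hi}) does not align with ring edges"
            )
        return slice(i0, i1)


@dataclass(frozen=True)
class RunConfig:
    """Monte Carlo run configuration.

    Parameters
    ----------
    n_photons : int
        Photons to launch.
    seed : int
        Seed of the counter-based per-photon substream generator.
    voxel_size : float
        Depth-slab (and, in ``full_3d`` mode, voxel cube) size, mm.
        0.2 mm resolves single-pair sensitivity profiles; 0.5 mm is used for
        the many-pair depth-map sweeps to keep memory and noise manageable.
    tally_mode : {"depth_profile", "full_3d"}
    roulette_threshold, roulette_survival : float
        Russian-roulette weight threshold and survival probability
        (MCML convention: 1e-4 and 0.1).  Set ``roulette_threshold=0`` to
        disable roulette.
    max_total_path : float
        Hard cap on a photon's geometric path length, mm (loop guard).
    weighting : {"discrete", "continuous"}
        Absorption estimator; see :mod:`srsoxi._kernel`.
    grid_x, grid_y : (float, float)
        Lateral extents of the full-3D grid, mm.
    grid_z_max : float or None
        Depth extent of the full-3D grid (None: the whole model).  Path
        outside the 3-D grid is clamped into the boundary voxels so that
        depth sums are conserved; trim edge voxels when imaging.
    """

    n_photons: int
    seed: int = 0
    voxel_size: float = 0.2
    tally_mode: str = "depth_profile"
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_total_path: float = 1e4
    weighting: str = "discrete"
    grid_x: tuple[float, float] = (-10.0, 35.0)
    grid_y: tuple[float, float] = (-10.0, 10.0)
    grid_z_max: float | None = None

    def __post_init__(self):
        if self.n_photons < 1:
            raise ConfigValidationError("n_photons must be >= 1")
        if not self.voxel_size > 0:
            raise ConfigValidationError("voxel_size must be > 0")
        if self.tally_mode not in ("depth_profile", "full_3d"):
            raise ConfigValidationError(
                f"unknown tally_mode {self.tally_mode!r}"
            )
        if self.roulette_threshold and not 0.0 < self.roulette_survival < 1.0:
            raise ConfigValidationError("roulette_survival must be in (0, 1)")
        if self.weighting not in ("discrete", "continuous"):
            raise ConfigValidationError(f"unknown weighting {self.weighting!r}")
        if not self.max_total_path > 0:
            raise ConfigValidationError("max_total_path must be > 0")

    def to_dict(self) -> dict:
        return {
            "n_photons": self.n_photons,
            "seed": self.seed,
            "voxel_size": self.voxel_size,
            "tally_mode": self.tally_mode,
            "roulette_threshold": self.roulette_threshold,
            "roulette_survival": self.roulette_survival,
            "max_total_path": self.max_total_path,
            "weighting": self.weighting,
            "grid_x": list(self.grid_x),
            "grid_y": list(self.grid_y),
            "grid_z_max": self.grid_z_max,
        }


@dataclass
class TallySet:
    """Aggregated tallies of one run.

    ``path_weight_by_ring`` holds sum_i L_i(x) I_i per ring: shape
    (n_rings, n_slabs) in depth-profile mode and (n_rings, nx, ny, nz) in
    full-3D mode.  ``detected_weight_by_ring`` holds sum_i I_i.
    """

    detected_weight_by_ring: np.ndarray
    path_weight_by_ring: np.ndarray
    launched: float
    absorbed_weight: float
    transmitted_weight: float
    escaped_outside_weight: float
    terminated_weight: float
    rouletted_weight: float
    annuli: DetectorAnnuli
    config: RunConfig
    model_hash: str = ""
    detected_weight_sq_by_ring: np.ndarray | None = None
    grid_origin: tuple[float, float] = (0.0, 0.0)

    @property
    def detected_weight(self) -> float:
        return float(self.detected_weight_by_ring.sum())

    @property
    def ledger_closure(self) -> float:
        """Relative imbalance of the weight ledger (0 when it closes)."""
        total = (
            self.detected_weight
            + self.absorbed_weight
            + self.transmitted_weight
            + self.escaped_outside_weight
            + self.terminated_weight
            + self.rouletted_weight
        )
        return (total - self.launched) / self.launched

    @property
    def n_slabs(self) -> int:
        return self.path_weight_by_ring.shape[-1]

    @property
    def depth_centers(self) -> np.ndarray:
        dz = self.config.voxel_size
        return dz * (np.arange(self.n_slabs) + 0.5)

    # -- ring arithmetic ---------------------------------------------------

    def interval_weight(self, r_lo: float, r_hi: float) -> float:
        sl = self.annuli.interval_slice(r_lo, r_hi)
        return float(self.detected_weight_by_ring[sl].sum())

    def interval_rel_se(self, r_lo: float, r_hi: float) -> float:
        """Relative standard error of the detected weight in [r_lo, r_hi).

        sqrt(sum w_i^2) / sum w_i — the self-normalized Monte Carlo error of
        the ring intensity; 1/sqrt(effective sample size).  Infinite when the
        ring is empty; NaN when the run predates the squared-weight tally.
        """
        if self.detected_weight_sq_by_ring is None:
            return float("nan")
        sl = self.annuli.interval_slice(r_lo, r_hi)
        w = float(self.detected_weight_by_ring[sl].sum())
        if w <= 0:
            return float("inf")
        w2 = float(self.detected_weight_sq_by_ring[sl].sum())
        return float(np.sqrt(w2) / w)

    def interval_path_weight(self, r_lo: float, r_hi: float) -> np.ndarray:
        sl = self.annuli.interval_slice(r_lo, r_hi)
        return self.path_weight_by_ring[sl].sum(axis=0)

    def intensity(self, r_lo: float, r_hi: float, per_area: bool = True) -> float:
        """Detected weight in [r_lo, r_hi), optionally per unit detector area.

        Per-area intensity (weight / annulus area / launched photon) is the
        quantity whose radial profile the diffusion model describes; use it
        for spatial slopes.
        """
        w = self.interval_weight(r_lo, r_hi)
        if per_area:
            w /= np.pi * (r_hi**2 - r_lo**2)
        return w / self.launched

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("detected_weight_by_ring", data=self.detected_weight_by_ring)
            fh.create_dataset(
                "path_weight_by_ring",
                data=self.path_weight_by_ring,
                compression="gzip",
                compression_opts=4,
            )
            fh.create_dataset("ring_edges", data=self.annuli.ring_edges)
            if self.detected_weight_sq_by_ring is not None:
                fh.create_dataset(
                    "detected_weight_sq_by_ring",
                    data=self.detected_weight_sq_by_ring,
                )
            fh.attrs["launched"] = self.launched
            fh.attrs["absorbed_weight"] = self.absorbed_weight
            fh.attrs["transmitted_weight"] = self.transmitted_weight
            fh.attrs["escaped_outside_weight"] = self.escaped_outside_weight
            fh.attrs["terminated_weight"] = self.terminated_weight
            fh.attrs["rouletted_weight"] = self.rouletted_weight
            fh.attrs["model_hash"] = self.model_hash
            fh.attrs["config_json"] = json.dumps(self.config.to_dict())
            fh.attrs["grid_origin"] = list(self.grid_origin)

    @classmethod
    def from_hdf5(cls, path) -> "TallySet":
        with h5py.File(path, "r") as fh:
            cfg_d = json.loads(fh.attrs["config_json"])
            cfg_d["grid_x"] = tuple(cfg_d["grid_x"])
            cfg_d["grid_y"] = tuple(cfg_d["grid_y"])
            w2 = (
                fh["detected_weight_sq_by_ring"][...]
                if "detected_weight_sq_by_ring" in fh
                else None
            )
            return cls(
                detected_weight_by_ring=fh["detected_weight_by_ring"][...],
                detected_weight_sq_by_ring=w2,
                path_weight_by_ring=fh["path_weight_by_ring"][...],
                launched=float(fh.attrs["launched"]),
                absorbed_weight=float(fh.attrs["absorbed_weight"]),
                transmitted_weight=float(fh.attrs["transmitted_weight"]),
                escaped_outside_weight=float(fh.attrs["escaped_outside_weight"]),
                terminated_weight=float(fh.attrs["terminated_weight"]),
                rouletted_weight=float(fh.attrs["rouletted_weight"]),
                annuli=DetectorAnnuli(fh["ring_edges"][...]),
                config=RunConfig(**cfg_d),
                model_hash=str(fh.attrs["model_hash"]),
                grid_origin=tuple(fh.attrs["grid_origin"]),
            )


@dataclass
class PhotonOutcome:
    """Terminal record of a single propagated photon."""

    status: str
    weight: float
    exit_radius: float
    ring: int
    total_path: float
    path_record: np.ndarray  # geometric path per depth slab, mm

    @property
    def detected(self) -> bool:
        return self.status == "detected"


@dataclass
class RecordedRun:
    """Per-photon terminal records plus the usual tallies.

    ``slab_paths`` holds each photon's geometric path per recording slab
    (``rec_dz`` mm wide) with a final overflow column for depth beyond the
    recorded range.  Used by the absorption-reweighting fast paths
    (slope LUTs, phantom sweeps); generated with ``weighting="continuous"``
    so trajectories are independent of mu_a.
    """

    status: np.ndarray
    ring: np.ndarray
    weight: np.ndarray
    exit_radius: np.ndarray
    total_path: np.ndarray
    slab_paths: np.ndarray
    rec_dz: float
    tallies: TallySet

    @property
    def detected_mask(self) -> np.ndarray:
        return self.status == K.ST_DETECTED


def _model_arrays(model: TissueModel, wavelength: int | None):
    wl = wavelength or model.wavelength
    nl = len(model.layers)
    zb = np.asarray(model.interface_depths, dtype=np.float64)
    mus = np.empty(nl)
    mua = np.empty(nl)
    g = np.empty(nl)
    n = np.empty(nl)
    for i in range(nl):
        p = model.props(i, wl)
        if not 0.0 <= p.g < 1.0:
            raise AnisotropyRangeError(f"layer {i}: g={p.g} outside [0, 1)")
        mus[i] = p.mu_s
        mua[i] = p.mu_a
        g[i] = p.g
        n[i] = p.n
    return zb, mus, mua, g, n


def _kernel_args(model, config, annuli, wavelength, mua_override=None):
    zb, mus, mua, g, n = _model_arrays(model, wavelength)
    if mua_override is not None:
        mua = np.full_like(mua, float(mua_override))
    dz = config.voxel_size
    n_slabs = int(np.ceil(model.total_thickness / dz - 1e-9))
    mode3d = 1 if config.tally_mode == "full_3d" else 0
    if mode3d:
        x0, x1 = config.grid_x
        y0, y1 = config.grid_y
        nx = int(np.ceil((x1 - x0) / dz))
        ny = int(np.ceil((y1 - y0) / dz))
        zmax = config.grid_z_max or model.total_thickness
        nz3 = int(np.ceil(zmax / dz))
        nbytes = annuli.n_rings * nx * ny * nz3 * 8
        if nbytes > FULL3D_MEMORY_BUDGET:
            raise MemoryGuardError(
                f"full_3d tally needs {nbytes / 1e9:.1f} GB "
                f"({annuli.n_rings} rings x {nx}x{ny}x{nz3} voxels); "
                "use depth_profile mode, coarser voxels, or fewer rings"
            )
        vox_w = np.zeros((annuli.n_rings, nx, ny, nz3))
        path_w = np.zeros((1, n_slabs))
        # segment buffer sized from the path cap and interaction rate
        max_rate = float(np.max(mus + mua))
        max_segs = int(config.max_total_path * (max_rate + 2.0 / dz)) + 64
        seg_buf = np.zeros((max_segs, 4))
    else:
        x0 = y0 = 0.0
        nx = ny = nz3 = 1
        vox_w = np.zeros((1, 1, 1, 1))
        path_w = np.zeros((annuli.n_rings, n_slabs))
        seg_buf = np.zeros((1, 4))
    det_w = np.zeros(annuli.n_rings)
    det_w2 = np.zeros(annuli.n_rings)
    ledger = np.zeros(K.N_LEDGER)
    depth_rec = np.zeros(n_slabs)
    weighting = (
        K.WEIGHT_DISCRETE if config.weighting == "discrete" else K.WEIGHT_CONTINUOUS
    )
    roulette_on = 1 if config.roulette_threshold > 0 else 0
    args = dict(
        zb=zb,
        det_w2=det_w2,
        mus=mus,
        mua=mua,
        g_arr=g,
        n_arr=n,
        n_top=model.ambient_n_top,
        n_bottom=model.ambient_n_bottom,
        edges=annuli.ring_edges,
        dz=dz,
        n_slabs=n_slabs,
        mode3d=mode3d,
        x0=x0,
        y0=y0,
        nx=nx,
        ny=ny,
        nz3=nz3,
        weighting=weighting,
        roulette_on=roulette_on,
        w_thresh=config.roulette_threshold,
        p_surv=config.roulette_survival,
        max_path=config.max_total_path,
        det_w=det_w,
        path_w=path_w,
        vox_w=vox_w,
        ledger=ledger,
        depth_rec=depth_rec,
        seg_buf=seg_buf,
    )
    return args


_DUMMY_REC = dict(
    record_mode=0,
    n_rec=0,
    rec_status=np.zeros(1, np.int8),
    rec_ring=np.zeros(1, np.int32),
    rec_w=np.zeros(1),
    rec_r=np.zeros(1),
    rec_tot=np.zeros(1),
    rec_paths=np.zeros((1, 1), np.float32),
)


def _build_tallies(args, config, annuli, model, mode3d):
    ledger = args["ledger"]
    return TallySet(
        detected_weight_by_ring=args["det_w"],
        path_weight_by_ring=args["vox_w"] if mode3d else args["path_w"],
        launched=ledger[K.LG_LAUNCHED],
        absorbed_weight=ledger[K.LG_ABSORBED],
        transmitted_weight=ledger[K.LG_TRANSMITTED],
        escaped_outside_weight=ledger[K.LG_ESCAPED],
        terminated_weight=ledger[K.LG_TERMINATED],
        rouletted_weight=ledger[K.LG_ROULETTED],
        annuli=annuli,
        config=config,
        model_hash=model.content_hash(),
        detected_weight_sq_by_ring=args["det_w2"],
        grid_origin=(args["x0"], args["y0"]),
    )


def run_simulation(
    model: TissueModel,
    config: RunConfig,
    annuli: DetectorAnnuli,
    wavelength: int | None = None,
) -> TallySet:
    """Run the transport simulation and return aggregated tallies.

    Identical (model, config, annuli) inputs yield bit-identical tallies.
    """
    args = _kernel_args(model, config, annuli, wavelength)
    K.transport(
        config.n_photons,
        0,
        config.seed,
        args["zb"], args["mus"], args["mua"], args["g_arr"], args["n_arr"],
        args["n_top"], args["n_bottom"],
        args["edges"],
        args["dz"], args["n_slabs"],
        args["mode3d"], args["x0"], args["y0"], args["nx"], args["ny"], args["nz3"],
        args["weighting"], args["roulette_on"], args["w_thresh"], args["p_surv"],
        args["max_path"],
        _DUMMY_REC["record_mode"], _DUMMY_REC["n_rec"],
        _DUMMY_REC["rec_status"], _DUMMY_REC["rec_ring"], _DUMMY_REC["rec_w"],
        _DUMMY_REC["rec_r"], _DUMMY_REC["rec_tot"], _DUMMY_REC["rec_paths"],
        args["det_w"], args["det_w2"], args["path_w"], args["vox_w"],
        args["ledger"],
        args["depth_rec"], args["seg_buf"],
    )
    return _build_tallies(args, config, annuli, model, args["mode3d"])


def run_recorded(
    model: TissueModel,
    config: RunConfig,
    annuli: DetectorAnnuli,
    rec_dz: float = 0.5,
    rec_depth: float = 20.0,
    wavelength: int | None = None,
    keep: str = "detected",
    mua_override: float | None = None,
) -> RecordedRun:
    """Run transport while recording per-photon terminal path records.

    ``keep="detected"`` drops non-detected photons from the returned arrays
    (the tallies still reflect every launched photon).  ``mua_override``
    replaces every layer's absorption with one value — used to build
    homogeneous reweighting bases.
    """
    if config.tally_mode != "depth_profile":
        raise ConfigValidationError("recorded runs use depth_profile mode")
    args = _kernel_args(model, config, annuli, wavelength, mua_override=mua_override)
    n = config.n_photons
    n_rec = int(np.ceil(rec_depth / rec_dz - 1e-9))
    if abs(rec_dz - config.voxel_size) > 1e-12:
        raise ConfigValidationError(
            "rec_dz must equal config.voxel_size (one shared depth grid)"
        )
    if n_rec > args["n_slabs"]:
        n_rec = args["n_slabs"]
    rec_status = np.zeros(n, np.int8)
    rec_ring = np.zeros(n, np.int32)
    rec_w = np.zeros(n)
    rec_r = np.zeros(n)
    rec_tot = np.zeros(n)
    rec_paths = np.zeros((n, n_rec + 1), np.float32)
    K.transport(
        n, 0, config.seed,
        args["zb"], args["mus"], args["mua"], args["g_arr"], args["n_arr"],
        args["n_top"], args["n_bottom"],
        args["edges"],
        args["dz"], args["n_slabs"],
        args["mode3d"], args["x0"], args["y0"], args["nx"], args["ny"], args["nz3"],
        args["weighting"], args["roulette_on"], args["w_thresh"], args["p_surv"],
        args["max_path"],
        1, n_rec,
        rec_status, rec_ring, rec_w, rec_r, rec_tot, rec_paths,
        args["det_w"], args["det_w2"], args["path_w"], args["vox_w"],
        args["ledger"],
        args["depth_rec"], args["seg_buf"],
    )
    tallies = _build_tallies(args, config, annuli, model, 0)
    if keep == "detected":
        m = rec_status == K.ST_DETECTED
        rec_status = rec_status[m]
        rec_ring = rec_ring[m]
        rec_w = rec_w[m]
        rec_r = rec_r[m]
        rec_tot = rec_tot[m]
        rec_paths = np.ascontiguousarray(rec_paths[m])
    return RecordedRun(
        status=rec_status,
        ring=rec_ring,
        weight=rec_w,
        exit_radius=rec_r,
        total_path=rec_tot,
        slab_paths=rec_paths,
        rec_dz=rec_dz,
        tallies=tallies,
    )


def propagate_photon(
    model: TissueModel,
    config: RunConfig,
    annuli: DetectorAnnuli | None = None,
    photon_index: int = 0,
) -> PhotonOutcome:
    """Propagate a single photon and return its terminal record.

    The photon is the ``photon_index``-th substream of ``config.seed``, so the
    outcome matches what a full run would have produced for that photon.
    """
    if annuli is None:
        annuli = DetectorAnnuli.uniform(0.5, 31.0)
    cfg = replace(config, n_photons=1)
    args = _kernel_args(model, cfg, annuli, None)
    n_rec = args["n_slabs"]
    rec_status = np.zeros(1, np.int8)
    rec_ring = np.zeros(1, np.int32)
    rec_w = np.zeros(1)
    rec_r = np.zeros(1)
    rec_tot = np.zeros(1)
    # float64 so the path-splitting conservation check holds to 1e-9 mm
    rec_paths = np.zeros((1, n_rec + 1), np.float64)
    K.transport(
        1, photon_index, cfg.seed,
        args["zb"], args["mus"], args["mua"], args["g_arr"], args["n_arr"],
        args["n_top"], args["n_bottom"],
        args["edges"],
        args["dz"], args["n_slabs"],
        args["mode3d"], args["x0"], args["y0"], args["nx"], args["ny"], args["nz3"],
        args["weighting"], args["roulette_on"], args["w_thresh"], args["p_surv"],
        args["max_path"],
        1, n_rec,
        rec_status, rec_ring, rec_w, rec_r, rec_tot, rec_paths,
        args["det_w"], args["det_w2"], args["path_w"], args["vox_w"],
        args["ledger"],
        args["depth_rec"], args["seg_buf"],
    )
    return PhotonOutcome(
        status=STATUS_NAMES[int(rec_status[0])],
        weight=float(rec_w[0]),
        exit_radius=float(rec_r[0]),
        ring=int(rec_ring[0]),
        total_path=float(rec_tot[0]),
        path_record=rec_paths[0, :-1].astype(np.float64),
    )


def sample_scatter_hg(n: int, g: float, seed: int = 0):
    """Sample Henyey-Greenstein deflection cosines and uniform azimuths.

    Returns (cos_theta, phi) arrays of length n.  Raises
    AnisotropyRangeError for g outside [0, 1).
    """
    if not 0.0 <= g < 1.0:
        raise AnisotropyRangeError(f"g must be in [0, 1), got {g}")
    if n < 1:
        raise ConfigValidationError("n must be >= 1")
    ct = np.empty(n)
    phi = np.empty(n)
    K.hg_sample_batch(n, float(g), int(seed), ct, phi)
    return ct, phi


def hg_inverse_cdf(p, g: float):
    """Closed-form HG quantile function (oracle for the sampler).

    For g=0 the distribution is uniform on [-1, 1].
    """
    p = np.asarray(p, dtype=float)
    if g < 1e-6:
        return 2.0 * p - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * p)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)
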