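"""Synthetic ex vivo heart phantom: co-registered CT volumes with ground truth.

Emulates the contrast-injected porcine-heart preparation used to study how
tube voltage (kVp) and reconstruction regime shift pericoronary fat
attenuation: a contrast-filled coronary lumen wrapped in a perivascular fat
sheath, embedded in myocardium next to a contrast-filled left ventricle,
inside a plastic container packed with expanded polystyrene, scanned at
80/100/120/140 kVp under an FBP-like and an IR-like noise regime.

The emulation is deliberately statistical, not physical: each tissue has a
per-kVp mean HU, a per-regime Gaussian noise SD, and an optional additive
IR bias; there is no sinogram, beam hardening or scatter. Geometry (the
ground-truth label volume) depends only on the spec, never on kVp/recon or
the random stream, so all volumes from one spec are co-registered by
construction and a VOI transfers across them by index identity.

Default fat means are chosen so the true HU ratios fat(i)/fat(120 kVp)
equal the averaged conversion factors 1.267 / 1.080 / 1 / 0.947 — this
makes parameter-recovery simulations directly interpretable. No default HU
mean is a measured ground-truth value; all are configurable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .geom import min_polyline_distance
from .grid import CTVolume, GridGeometry

KVP_SET = (80, 100, 120, 140)
RECON_LABELS = ("FBP", "IR")
_RECON_CODE = {"FBP": 0, "IR": 1}

#: Averaged tube-voltage conversion factors (ratio to 120 kVp) used as the
#: generator's true fat-attenuation ratios in the default specs.
AVERAGED_FACTORS = {80: 1.267, 100: 1.080, 120: 1.0, 140: 0.947}

#: Label values in the ground-truth label volume, in paint order
#: (later entries overwrite earlier ones where regions overlap).
TISSUE_LABELS = ("air", "container", "polystyrene", "myocardium", "lv", "fat", "lumen")


class PhantomError(ValueError):
    """Raised for invalid phantom specifications or generation requests."""


@dataclass
class TissueModel:
    """Attenuation model for one tissue: per-kVp mean, per-regime noise, IR bias."""

    name: str
    mean_hu_per_kvp: dict[int, float]
    noise_sd_fbp: float = 0.0
    noise_sd_ir: float = 0.0
    ir_bias: float = 0.0

    def __post_init__(self) -> None:
        self.mean_hu_per_kvp = {int(k): float(v) for k, v in self.mean_hu_per_kvp.items()}
        if self.noise_sd_fbp < 0 or self.noise_sd_ir < 0:
            raise PhantomError(f"tissue {self.name!r}: noise SDs must be >= 0")

    def mean_at(self, kvp: int, recon: str) -> float:
        if kvp not in self.mean_hu_per_kvp:
            raise PhantomError(
                f"tissue {self.name!r} has no mean-HU calibration entry for {kvp} kVp "
                f"(entries: {sorted(self.mean_hu_per_kvp)})"
            )
        mean = self.mean_hu_per_kvp[kvp]
        if recon == "IR":
            mean += self.ir_bias
        return mean

    def noise_sd(self, recon: str) -> float:
        return self.noise_sd_ir if recon == "IR" else self.noise_sd_fbp


def _constant_means(value: float, kvp_list=KVP_SET) -> dict[int, float]:
    return {int(k): float(value) for k in kvp_list}


@dataclass
class PhantomSpec:
    """Full description of one synthetic heart phantom (one vessel).

    ``vessel_path`` is an ordered polyline in physical mm. ``tube_load_mas``
    is carried as acquisition metadata only (it does not enter the noise
    model; noise SDs are set per tissue directly).
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    vessel_path: np.ndarray
    lumen_radius_mm: float
    fat_sheath_outer_radius_mm: float
    tissues: dict[str, TissueModel]
    kvp_list: tuple[int, ...] = KVP_SET
    recon_list: tuple[str, ...] = RECON_LABELS
    position_bias_hu: float = 0.0
    tube_load_mas: float = 56.0
    seed: int = 0
    vessel_id: str = "V1"
    scanner_profile: str = "custom"
    # secondary anatomy (defaults sized to the default grids)
    myocardium_radius_mm: float = 12.0
    lv_offset_mm: tuple[float, float] = (12.0, 0.0)
    lv_radius_mm: float = 4.0
    container_outer_radius_mm: float = 18.0
    container_wall_mm: float = 1.5

    def __post_init__(self) -> None:
        self.vessel_path = np.atleast_2d(np.asarray(self.vessel_path, dtype=float))
        if self.vessel_path.ndim != 2 or self.vessel_path.shape[1] != 3 or self.vessel_path.shape[0] < 2:
            raise PhantomError("vessel_path must be an (N>=2, 3) polyline in mm")
        if self.lumen_radius_mm <= 0:
            raise PhantomError("lumen_radius_mm must be > 0")
        if self.fat_sheath_outer_radius_mm <= self.lumen_radius_mm:
            raise PhantomError("fat_sheath_outer_radius_mm must exceed lumen_radius_mm")
        self.kvp_list = tuple(int(k) for k in self.kvp_list)
        self.recon_list = tuple(self.recon_list)
        for name in TISSUE_LABELS:
            if name not in self.tissues:
                raise PhantomError(f"missing tissue model {name!r}")
        for t in self.tissues.values():
            for kvp in self.kvp_list:
                if kvp not in t.mean_hu_per_kvp:
                    raise PhantomError(
                        f"tissue {t.name!r} lacks a mean-HU entry for {kvp} kVp"
                    )
        fat = self.tissues["fat"].mean_hu_per_kvp
        order = sorted(self.kvp_list)
        if any(fat[a] > fat[b] for a, b in zip(order, order[1:])):
            raise PhantomError("fat mean HU must be non-decreasing in kVp")
        grid = self.grid
        inflated = self.fat_sheath_outer_radius_mm
        if not bool(np.all(grid.contains_point(self.vessel_path - inflated))
                    and np.all(grid.contains_point(self.vessel_path + inflated))):
            raise PhantomError(
                "grid too small: vessel path plus fat sheath exceeds the voxel grid"
            )

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(shape=tuple(self.grid_shape), spacing=tuple(self.voxel_size_mm))

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vessel_path"] = self.vessel_path.tolist()
        d["tissues"] = {k: asdict(v) for k, v in self.tissues.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = copy.deepcopy(d)
        d["tissues"] = {k: TissueModel(**v) for k, v in d["tissues"].items()}
        d["vessel_path"] = np.asarray(d["vessel_path"], dtype=float)
        for key in ("grid_shape", "voxel_size_mm", "kvp_list", "recon_list", "lv_offset_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Phantom:
    """A generated volume plus its ground-truth tissue label field."""

    volume: CTVolume
    labels: np.ndarray  # int8 index into TISSUE_LABELS
    label_names: tuple[str, ...] = TISSUE_LABELS

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == self.label_names.index(tissue)

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return {name: self.mask(name) for name in self.label_names}


def _label_volume(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth labels by voxel-center membership, painted in priority order.

    Vessel-attached tissues (myocardium, fat sheath, lumen) are capsule
    shells around the vessel path *clipped by the end planes*: a straight
    vessel's lumen is an exact cylinder (no bulbous end caps), so analytic
    volume checks apply.
    """
    grid = spec.grid
    x, y, z = grid.voxel_centers()
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    cx = grid.origin[0] + (grid.shape[0] - 1) * grid.spacing[0] / 2.0
    cy = grid.origin[1] + (grid.shape[1] - 1) * grid.spacing[1] / 2.0
    r_xy = np.hypot(x - cx, y - cy)

    labels = np.zeros(grid.shape, dtype=np.int8)  # air
    r_out = spec.container_outer_radius_mm
    labels[r_xy <= r_out] = TISSUE_LABELS.index("container")
    labels[r_xy <= r_out - spec.container_wall_mm] = TISSUE_LABELS.index("polystyrene")

    path = spec.vessel_path
    d_vessel = min_polyline_distance(pts, path)
    t0 = path[1] - path[0]
    t0 = t0 / np.linalg.norm(t0)
    tN = path[-1] - path[-2]
    tN = tN / np.linalg.norm(tN)
    in_slab = ((pts - path[0]) @ t0 >= 0.0) & ((pts - path[-1]) @ tN <= 0.0)
    d_vessel = np.where(in_slab, d_vessel, np.inf).reshape(grid.shape)
    labels[d_vessel <= spec.myocardium_radius_mm] = TISSUE_LABELS.index("myocardium")

    lvx, lvy = cx + spec.lv_offset_mm[0], cy + spec.lv_offset_mm[1]
    zmin, zmax = path[:, 2].min(), path[:, 2].max()
    in_lv = (np.hypot(x - lvx, y - lvy) <= spec.lv_radius_mm) & (z >= zmin) & (z <= zmax)
    labels[in_lv] = TISSUE_LABELS.index("lv")

    labels[d_vessel <= spec.fat_sheath_outer_radius_mm] = TISSUE_LABELS.index("fat")
    labels[d_vessel <= spec.lumen_radius_mm] = TISSUE_LABELS.index("lumen")
    return labels


# Geometry is identical for every (kvp, recon) of one spec, so the label
# volume is memoised on a geometry fingerprint (bounded FIFO cache).
_LABEL_CACHE: dict[bytes, np.ndarray] = {}
_LABEL_CACHE_MAX = 32


def _geometry_fingerprint(spec: PhantomSpec) -> bytes:
    import hashlib

    h = hashlib.sha256()
    h.update(repr((
        spec.grid_shape, spec.voxel_size_mm, spec.lumen_radius_mm,
        spec.fat_sheath_outer_radius_mm, spec.myocardium_radius_mm,
        spec.lv_offset_mm, spec.lv_radius_mm,
        spec.container_outer_radius_mm, spec.container_wall_mm,
    )).encode())
    h.update(np.ascontiguousarray(spec.vessel_path).tobytes())
    return h.digest()


def ground_truth_labels(spec: PhantomSpec) -> np.ndarray:
    """The spec's ground-truth label volume (cached; shared across conditions)."""
    key = _geometry_fingerprint(spec)
    labels = _LABEL_CACHE.get(key)
    if labels is None:
        labels = _label_volume(spec)
        labels.flags.writeable = False  # shared across conditions
        if len(_LABEL_CACHE) >= _LABEL_CACHE_MAX:
            _LABEL_CACHE.pop(next(iter(_LABEL_CACHE)))
        _LABEL_CACHE[key] = labels
    return labels


def _rng_for(spec: PhantomSpec, kvp: int, recon: str) -> np.random.Generator:
    # Independent stream per (seed, kvp, recon): adding a condition never
    # perturbs the noise of the others.
    return np.random.default_rng([int(spec.seed), int(kvp), _RECON_CODE[recon]])


def generate_phantom(spec: PhantomSpec, kvp: int, recon: str) -> Phantom:
    """Generate one co-registered acquisition of the phantom.

    Each voxel's value is its tissue's mean HU at ``kvp`` (plus the IR bias
    under the IR regime and any position bias) plus Gaussian noise with the
    tissue's per-regime SD, drawn reproducibly from a stream derived from
    ``spec.seed`` and (kvp, recon).
    """
    if kvp not in spec.kvp_list:
        raise PhantomError(
            f"no calibration entry for {kvp} kVp in this spec (kvp_list={spec.kvp_list})"
        )
    if recon not in spec.recon_list:
        raise PhantomError(f"recon {recon!r} not in spec.recon_list {spec.recon_list}")

    labels = ground_truth_labels(spec)
    mean_lut = np.array(
        [spec.tissues[name].mean_at(kvp, recon) for name in TISSUE_LABELS]
    ) + spec.position_bias_hu
    sd_lut = np.array([spec.tissues[name].noise_sd(recon) for name in TISSUE_LABELS])

    data = mean_lut[labels]
    if np.any(sd_lut > 0):
        rng = _rng_for(spec, kvp, recon)
        data = data + sd_lut[labels] * rng.standard_normal(labels.shape)

    vol = CTVolume(
        data=data,
        grid=spec.grid,
        kvp=int(kvp),
        recon=recon,
        volume_id=f"{spec.vessel_id}_{kvp}kVp_{recon}",
        extra={"tube_load_mas": spec.tube_load_mas, "scanner_profile": spec.scanner_profile},
    )
    return Phantom(volume=vol, labels=labels)


# ---------------------------------------------------------------------------
# Default specs (the two scanner grids as named presets)
# ---------------------------------------------------------------------------

SCANNER_PROFILES = {
    "wide-detector-256": {
        "voxel_size_mm": (0.5859, 0.5859, 0.6),
        "grid_shape": (64, 64, 92),
        "tube_load_mas": 56.0,
    },
    "dual-source": {
        "voxel_size_mm": (0.5352, 0.5352, 0.625),
        "grid_shape": (70, 70, 90),
        "tube_load_mas": 50.0,
    },
}


def default_tissues(
    fat_hu_at_reference: float = -75.0,
    fat_ratios: dict[int, float] | None = None,
    ir_bias_fat: float = 3.0,
    kvp_list=KVP_SET,
) -> dict[str, TissueModel]:
    """Default tissue table.

    Fat means are ``fat_hu_at_reference * ratio(kvp)`` so the generator's
    true fat-HU ratios are exactly the supplied conversion factors. HU
    means are emulation defaults, not measured values. Noise SDs are
    placeholder regime levels (the source scanners' noise at each kVp/mAs
    is unknown): soft tissue 24 HU FBP / 15 HU IR.
    """
    ratios = dict(AVERAGED_FACTORS if fat_ratios is None else fat_ratios)
    soft = dict(noise_sd_fbp=24.0, noise_sd_ir=15.0)
    light = dict(noise_sd_fbp=12.0, noise_sd_ir=8.0)
    return {
        "air": TissueModel("air", _constant_means(-1000.0, kvp_list), **light),
        "container": TissueModel("container", _constant_means(100.0, kvp_list), **light),
        "polystyrene": TissueModel("polystyrene", _constant_means(-950.0, kvp_list), **light),
        "myocardium": TissueModel("myocardium", _constant_means(45.0, kvp_list), **soft),
        # iodinated agar: HU falls with kVp as the beam hardens away from
        # iodine's k-edge
        "lv": TissueModel("lv", {80: 560.0, 100: 465.0, 120: 400.0, 140: 355.0}, **soft),
        "lumen": TissueModel("lumen", {80: 560.0, 100: 465.0, 120: 400.0, 140: 355.0}, **soft),
        "fat": TissueModel(
            "fat",
            {int(k): fat_hu_at_reference * ratios[int(k)] for k in kvp_list},
            ir_bias=ir_bias_fat,
            **soft,
        ),
    }


def straight_vessel_path(length_mm: float, grid: GridGeometry, margin_mm: float = 2.5,
                         n_points: int = 21) -> np.ndarray:
    """A straight vessel along z through the grid's xy center."""
    cx = grid.origin[0] + (grid.shape[0] - 1) * grid.spacing[0] / 2.0
    cy = grid.origin[1] + (grid.shape[1] - 1) * grid.spacing[1] / 2.0
    z = np.linspace(margin_mm, margin_mm + length_mm, n_points)
    return np.column_stack([np.full_like(z, cx), np.full_like(z, cy), z])


def default_spec(
    scanner_profile: str,
    *,
    seed: int = 0,
    fat_hu_at_reference: float = -75.0,
    fat_ratios: dict[int, float] | None = None,
    noise: bool = True,
    vessel_length_mm: float = 40.0,
    lumen_radius_mm: float = 1.5,
    vessel_id: str = "V1",
) -> PhantomSpec:
    """Fully populated spec for one of the two emulated scanner presets.

    With ``noise=False`` every tissue SD is zeroed, giving exact
    ground-truth voxel values for oracle tests.
    """
    if scanner_profile not in SCANNER_PROFILES:
        raise PhantomError(
            f"unknown scanner profile {scanner_profile!r}; "
            f"valid profiles: {sorted(SCANNER_PROFILES)}"
        )
    prof = SCANNER_PROFILES[scanner_profile]
    grid = GridGeometry(shape=prof["grid_shape"], spacing=prof["voxel_size_mm"])
    fat_outer = 7.0
    tissues = default_tissues(fat_hu_at_reference, fat_ratios)
    if not noise:
        for t in tissues.values():
            t.noise_sd_fbp = 0.0
            t.noise_sd_ir = 0.0
    return PhantomSpec(
        grid_shape=prof["grid_shape"],
        voxel_size_mm=prof["voxel_size_mm"],
        vessel_path=straight_vessel_path(vessel_length_mm, grid, margin_mm=fat_outer + 0.5),
        lumen_radius_mm=lumen_radius_mm,
        fat_sheath_outer_radius_mm=fat_outer,
        tissues=tissues,
        tube_load_mas=prof["tube_load_mas"],
        seed=seed,
        vessel_id=vessel_id,
        scanner_profile=scanner_profile,
    )


def cohort_specs(
    scanner_profile: str,
    n_vessels: int = 6,
    seed: int = 0,
    *,
    fat_ratios: dict[int, float] | None = None,
    noise: bool = True,
    fat_hu_reference_range: tuple[float, float] = (-80.0, -70.0),
    lumen_radius_range_mm: tuple[float, float] = (1.25, 1.9),
    curvature_max_mm: float = 2.0,
) -> list[PhantomSpec]:
    """A cohort of vessels with varied geometry and fat baseline.

    Vessels differ in lumen radius, gentle in-plane curvature and baseline
    fat HU; the fat HU *ratios* across kVp are identical for all vessels
    (they are a beam-spectrum property, not a vessel property), so the
    cohort shares one set of true conversion factors.
    """
    rng = np.random.default_rng([int(seed), 911])
    specs = []
    for v in range(n_vessels):
        fat_ref = float(rng.uniform(*fat_hu_reference_range))
        lumen_r = float(rng.uniform(*lumen_radius_range_mm))
        amp = float(rng.uniform(0.0, curvature_max_mm))
        phase = float(rng.uniform(0.0, 2 * np.pi))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = default_spec(
            scanner_profile,
            seed=sub_seed,
            fat_hu_at_reference=fat_ref,
            fat_ratios=fat_ratios,
            noise=noise,
            lumen_radius_mm=lumen_r,
            vessel_id=f"V{v + 1}",
        )
        path = spec.vessel_path.copy()
        t = np.linspace(0.0, np.pi, path.shape[0])
        path[:, 0] += amp * np.sin(t + phase) - amp * np.sin(phase)
        spec.vessel_path = path
        specs.append(spec)
    return specs
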