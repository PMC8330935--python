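"""Seeded synthetic OCTA scenes with the statistical structure of an
iAMD / control choriocapillaris study.

No public imaging dataset accompanies this kind of study, so the package
ships a generative stand-in.  Each synthetic eye consists of a co-registered
angiographic + structural en-face slab pair, ground-truth masks (large
choroidal vessels, drusen, superficial-plexus projections) and choroidal
boundary surfaces, drawn from explicit, configurable laws:

* granular flow texture from smoothed white noise, quantile-thresholded per
  sector so the true dark (flow-deficit) fraction is exact by construction;
* per-sector choroidal thickness (CT) from sector-specific normal laws
  coupled to the eye's sub-foveal thickness (cCT), reproducing the
  nasal-temporal thinning gradient;
* large-choroidal-vessel (LCV) visibility per sector from a mixed logistic
  law in CT with a nasal shift and an eye-level random intercept, rendered
  as smooth dark Bezier tubes that *replace* the underlying flow texture in
  both the angio and the structural image (thinner choroid -> more visible);
* drusen as disk-shaped attenuation blotches shared between the two images,
  and superficial-vessel streaks recorded for exclusion masking.

Everything is driven by one integer seed; identical configurations yield
bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RBFInterpolator
from scipy.special import expit
from skimage.morphology import disk

from . import io
from .choroid_metrics import CTSurfaces
from .core import SLAB_10_AT_31, BinaryMask, EnFaceImage, SlabSpec
from .fd_quant import corner_sector_layout

#: sector index -> topographic orientation (2 and 3 are the nasal squares,
#: matching the thinner default CT means)
SECTOR_ORIENTATION = {1: "temporal", 2: "nasal", 3: "nasal", 4: "temporal"}

EYE_COLORS = ("brown", "green", "blue")
EYE_COLOR_P = (0.30, 0.29, 0.41)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic cohort.

    CT defaults follow the sector-wise means/SDs and the sub-foveal values
    typical of elderly iAMD/control cohorts; the LCV logistic defaults are
    an odds ratio of 0.94 per um CT and a 6.23-fold nasal odds shift, with
    the intercept and eye-level heterogeneity calibrated so that roughly a
    quarter of sectors and half of eyes show LCV.  The true flow-deficit
    fractions (9% vs 6%) are calibration constants; only their ordering
    (iAMD > control) is claimed.
    """

    seed: int
    n_iamd: int
    n_control: int
    image_size_px: int = 1024
    scan_size_um: float = 6000.0
    fd_fraction_iamd: float = 0.09
    fd_fraction_control: float = 0.06
    fd_fraction_sd: float = 0.02
    lcv_intercept: float = 5.30
    lcv_ct_slope: float = math.log(0.94)
    lcv_nasal_shift: float = math.log(6.23)
    lcv_sigma_u: float = 2.0
    ct_sector_means_um: tuple[float, float, float, float] = (194.0, 148.0, 121.0, 157.0)
    ct_sector_sd_um: float = 63.0
    cct_mean_um: float = 197.0
    cct_sd_um: float = 82.0
    ct_cct_corr: float = 0.85
    noise_sd: float = 0.01
    lcv_width_um_range: tuple[float, float] = (50.0, 150.0)
    lcv_contrast: float = 0.2
    lcv_render: bool = True
    drusen_rate: float = 0.4
    texture_scale_um: float = 18.0
    slab: SlabSpec = SLAB_10_AT_31

    def __post_init__(self) -> None:
        for name in ("fd_fraction_iamd", "fd_fraction_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("image_size_px", "scan_size_um", "ct_sector_sd_um", "cct_mean_um",
                     "cct_sd_um", "texture_scale_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(m <= 0 for m in self.ct_sector_means_um) or len(self.ct_sector_means_um) != 4:
            raise ValueError("ct_sector_means_um needs four positive lengths")
        if self.n_iamd < 0 or self.n_control < 0 or self.n_iamd + self.n_control < 2:
            raise ValueError("cohort needs at least two eyes")
        if not 0.0 <= self.lcv_contrast <= 0.2:
            raise ValueError("LCV contrast must suppress signal to <= 20% of local flow")
        if self.lcv_width_um_range[0] <= 0 or self.lcv_width_um_range[1] < self.lcv_width_um_range[0]:
            raise ValueError("invalid LCV width range")
        if self.lcv_sigma_u < 0 or self.drusen_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise levels must be non-negative")
        if not -1.0 < self.ct_cct_corr < 1.0:
            raise ValueError("ct_cct_corr must lie in (-1, 1)")

    @property
    def pitch_um(self) -> float:
        return self.scan_size_um / self.image_size_px

    @property
    def n_eyes(self) -> int:
        return self.n_iamd + self.n_control


@dataclass
class GroundTruth:
    """Per-eye simulated truth: masks, boundary surfaces and sector flags."""

    sector_fd_fraction: dict[int, float]
    lcv_mask: BinaryMask
    drusen_mask: BinaryMask
    vessel_mask: BinaryMask
    ct_surfaces: CTSurfaces
    ct_um: dict[int, float]
    lcv_flags: dict[int, bool]
    drusen_flags: dict[int, bool]


@dataclass
class EyeScene:
    eye_id: str
    group: str
    laterality: str
    angio: EnFaceImage
    structural: EnFaceImage
    truth: GroundTruth
    metadata: dict


def _eye_rng(config: SimulationConfig, eye_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(eye_index)]))


def _draw_eye_truth(config: SimulationConfig, rng: np.random.Generator, group: str) -> dict:
    """Sample the non-image truth of one eye (CT, LCV flags, drusen, metadata).

    The draw order here is the authoritative random stream shared by the
    image renderer and the fast truth-only cohort path.
    """
    cct = max(30.0, rng.normal(config.cct_mean_um, config.cct_sd_um))
    z = rng.standard_normal(4)
    rho = config.ct_cct_corr
    means = np.asarray(config.ct_sector_means_um)
    ct = np.clip(
        means
        + rho * (config.ct_sector_sd_um / config.cct_sd_um) * (cct - config.cct_mean_um)
        + math.sqrt(1.0 - rho * rho) * config.ct_sector_sd_um * z,
        30.0,
        None,
    )
    u_eye = rng.normal(0.0, config.lcv_sigma_u) if config.lcv_sigma_u > 0 else 0.0
    nasal = np.array([SECTOR_ORIENTATION[i] == "nasal" for i in (1, 2, 3, 4)], dtype=float)
    p_lcv = expit(config.lcv_intercept + config.lcv_ct_slope * ct + config.lcv_nasal_shift * nasal + u_eye)
    lcv = rng.random(4) < p_lcv

    base_frac = config.fd_fraction_iamd if group == "iamd" else config.fd_fraction_control
    if base_frac == 0.0:
        frac = np.zeros(4)
    else:
        frac = np.clip(rng.normal(base_frac, config.fd_fraction_sd, 4), 0.0, 0.5)

    n_drusen = rng.poisson(config.drusen_rate)
    drusen_sectors = rng.integers(1, 5, size=n_drusen) if n_drusen else np.empty(0, dtype=int)

    eye_color = EYE_COLORS[rng.choice(len(EYE_COLORS), p=EYE_COLOR_P)]
    spherical_equivalent = float(abs(rng.normal(1.6, 1.15)))
    return dict(
        cct_um=float(cct),
        ct_um={i: float(ct[i - 1]) for i in (1, 2, 3, 4)},
        lcv_flags={i: bool(lcv[i - 1]) for i in (1, 2, 3, 4)},
        fd_fraction={i: float(frac[i - 1]) for i in (1, 2, 3, 4)},
        background_fd_fraction=float(base_frac),
        drusen_sectors=[int(s) for s in drusen_sectors],
        eye_color=eye_color,
        spherical_equivalent=spherical_equivalent,
    )


def _rank_normalize(values: np.ndarray) -> np.ndarray:
    flat = values.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    return (ranks / (flat.size - 1)).reshape(values.shape)


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _stamp_tube(mask: np.ndarray, pts: np.ndarray, radius_px: int) -> None:
    h, w = mask.shape
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    r0, r1 = max(0, rr.min() - radius_px), min(h, rr.max() + radius_px + 1)
    c0, c1 = max(0, cc.min() - radius_px), min(w, cc.max() + radius_px + 1)
    window = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    window[rr - r0, cc - c0] = True
    if radius_px > 0:
        window = ndimage.binary_dilation(window, structure=disk(radius_px))
    mask[r0:r1, c0:c1] |= window


def _ct_surfaces(config: SimulationConfig, truth: dict, sectors) -> CTSurfaces:
    n = config.image_size_px
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    points = [center] + [s.center_px for s in sectors]
    values = [truth["cct_um"]] + [truth["ct_um"][s.index] for s in sectors]
    rbf = RBFInterpolator(np.asarray(points), np.asarray(values), kernel="thin_plate_spline")
    rows, cols = np.mgrid[0:n, 0:n]
    grid = np.column_stack([rows.ravel(), cols.ravel()]).astype(np.float64)
    sclera = np.clip(rbf(grid).reshape(n, n), 10.0, None).astype(np.float32)
    bm = np.zeros((n, n), dtype=np.float32)
    return CTSurfaces(
        bm_outer_depth=bm,
        sclera_inner_depth=sclera,
        fovea_center_px=center,
        pitch_um=config.pitch_um,
    )


def simulate_eye(config: SimulationConfig, eye_index: int, group: str) -> EyeScene:
    """Render one synthetic eye (angio + structural slab pair with truth)."""
    if group not in ("iamd", "control"):
        raise ValueError(f"unknown group label {group!r}")
    if eye_index >= config.n_eyes:
        raise ValueError("eye_index beyond the configured cohort size")
    rng = _eye_rng(config, eye_index)
    n = config.image_size_px
    pitch = config.pitch_um
    laterality = "OD" if eye_index % 2 == 0 else "OS"
    sectors = corner_sector_layout(n, pitch, laterality)

    truth = _draw_eye_truth(config, rng, group)

    # granular flow texture: smoothed white noise, rank-normalized
    noise = rng.standard_normal((n, n))
    smooth = ndimage.gaussian_filter(noise, sigma=max(config.texture_scale_um / pitch, 0.5))
    u = _rank_normalize(smooth)

    # true flow-deficit pixels: the k darkest per region, per-sector fraction
    fd_true = np.zeros((n, n), dtype=bool)
    in_sector = np.zeros((n, n), dtype=bool)
    for s in sectors:
        in_sector[s.slice()] = True
        frac = truth["fd_fraction"][s.index]
        block = u[s.slice()]
        k = int(round(frac * block.size))
        if k > 0:
            cut = np.partition(block.ravel(), k - 1)[k - 1]
            fd_true[s.slice()] = block <= cut
    bg = ~in_sector
    k = int(round(truth["background_fd_fraction"] * int(bg.sum())))
    if k > 0:
        vals = u[bg]
        cut = np.partition(vals, k - 1)[k - 1]
        fd_true[bg] = vals <= cut

    # flow signal is kept in a narrow bright band and deficits in a dark one,
    # so the Phansalkar threshold falls into the gap between the two modes
    brightness = min(1.0, 0.92 + 0.004 * config.slab.thickness_um)
    flow_signal = (0.70 + 0.15 * u) * brightness
    angio = np.where(fd_true, (0.04 + 0.10 * u) * brightness, flow_signal)

    # drusen: disk-shaped attenuation blotches inside the flagged sectors
    atten = np.ones((n, n))
    drusen_mask = np.zeros((n, n), dtype=bool)
    for sector_idx in truth["drusen_sectors"]:
        s = sectors[sector_idx - 1]
        cy = rng.uniform(*s.rows)
        cx = rng.uniform(*s.cols)
        r_um = rng.uniform(60.0, 150.0)
        depth = rng.uniform(0.3, 0.6)
        r_px = r_um / pitch
        r0, r1 = max(0, int(cy - 3 * r_px)), min(n, int(cy + 3 * r_px) + 1)
        c0, c1 = max(0, int(cx - 3 * r_px)), min(n, int(cx + 3 * r_px) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        atten[r0:r1, c0:c1] *= 1.0 - depth * np.exp(-d2 / (2.0 * (r_px / 2.0) ** 2))
        drusen_mask[r0:r1, c0:c1] |= d2 <= r_px**2

    # superficial-plexus projection streaks crossing the scan
    vessel_mask = np.zeros((n, n), dtype=bool)
    for _ in range(int(rng.integers(2, 5))):
        vertical = rng.random() < 0.5
        a, b = rng.uniform(0, n - 1, 2)
        mid = rng.uniform(0, n - 1, 2)
        p0 = np.array([0.0, a]) if vertical else np.array([a, 0.0])
        p2 = np.array([n - 1.0, b]) if vertical else np.array([b, n - 1.0])
        pts = _bezier_points(p0, mid, p2, 4 * n)
        width_um = rng.uniform(40.0, 80.0)
        _stamp_tube(vessel_mask, pts, max(1, int(round(width_um / 2.0 / pitch))))

    angio = angio * atten
    angio[vessel_mask] *= 0.45

    # LCV: smooth dark Bezier tubes replacing the flow texture per flagged
    # sector.  Tube geometry is always drawn (the random stream is identical
    # whether or not LCV are rendered, so renders pair exactly); the
    # ``lcv_render`` switch only controls whether they are applied.
    lcv_mask = np.zeros((n, n), dtype=bool)
    for s in sectors:
        if not truth["lcv_flags"][s.index]:
            continue
        for _ in range(int(rng.integers(2, 5))):
            vertical = rng.random() < 0.5
            (lo0, hi0), (lo1, hi1) = s.rows, s.cols
            a = rng.uniform(lo1, hi1 - 1)
            b = rng.uniform(lo1, hi1 - 1)
            mid = np.array([rng.uniform(lo0, hi0 - 1), rng.uniform(lo1, hi1 - 1)])
            if vertical:
                p0 = np.array([float(lo0), a])
                p2 = np.array([hi0 - 1.0, b])
            else:
                p0 = np.array([rng.uniform(lo0, hi0 - 1), float(lo1)])
                p2 = np.array([rng.uniform(lo0, hi0 - 1), hi1 - 1.0])
            pts = _bezier_points(p0, mid, p2, 4 * s.side_px)
            w_um = rng.uniform(*config.lcv_width_um_range)
            _stamp_tube(lcv_mask, pts, max(1, int(round(w_um / 2.0 / pitch))))
    if not config.lcv_render:
        lcv_mask = np.zeros((n, n), dtype=bool)

    # suppression is relative to the local *flow* signal (not the FD-darkened
    # mixture): an LCV replaces whatever texture lies beneath it.  The tube
    # profile is feathered at a scale no finer than the compensation
    # smoothing, so the structural dip is fully trackable and division-style
    # compensation cancels the shared suppression.
    if lcv_mask.any():
        dist_um = ndimage.distance_transform_edt(~lcv_mask) * pitch
        tube = np.clip(1.0 - dist_um / 20.0, 0.0, 1.0)  # saturated on the mask, 20 um feather
    else:
        tube = np.zeros((n, n))
    local_flow = ndimage.gaussian_filter(flow_signal * atten, sigma=max(50.0 / pitch, 1.0))
    angio = (1.0 - tube) * angio + tube * (config.lcv_contrast * local_flow)

    # structural slab: bright base x the shared attenuation field
    base_noise = rng.standard_normal((n, n))
    sm = ndimage.gaussian_filter(base_noise, sigma=max(150.0 / pitch, 1.0))
    sm_std = sm.std()
    base = 0.78 + (0.03 * sm / sm_std if sm_std > 0 else 0.0)
    structural = np.clip(base, 0.5, 0.95) * atten
    structural[vessel_mask] *= 0.85
    local_struct = ndimage.gaussian_filter(structural, sigma=max(50.0 / pitch, 1.0))
    structural = (1.0 - tube) * structural + tube * (config.lcv_contrast * local_struct)

    if config.noise_sd > 0:
        angio = angio + rng.normal(0.0, config.noise_sd, (n, n))
        structural = structural + rng.normal(0.0, config.noise_sd, (n, n))
    angio = io.quantize_u16(angio)
    structural = io.quantize_u16(structural)

    surfaces = _ct_surfaces(config, truth, sectors)
    ground = GroundTruth(
        sector_fd_fraction=truth["fd_fraction"],
        lcv_mask=BinaryMask(lcv_mask, "lcv"),
        drusen_mask=BinaryMask(drusen_mask, "drusen"),
        vessel_mask=BinaryMask(vessel_mask, "vessel-exclusion"),
        ct_surfaces=surfaces,
        ct_um=truth["ct_um"],
        # flags are deterministic functions of the masks (>=1 pixel in sector)
        lcv_flags={s.index: bool(lcv_mask[s.slice()].any()) for s in sectors},
        drusen_flags={s.index: bool(drusen_mask[s.slice()].any()) for s in sectors},
    )
    prefix = "iamd" if group == "iamd" else "ctrl"
    scene = EyeScene(
        eye_id=f"{prefix}-{eye_index:03d}",
        group=group,
        laterality=laterality,
        angio=EnFaceImage(angio, pitch, laterality, "angio", config.slab),
        structural=EnFaceImage(structural, pitch, laterality, "structural", config.slab),
        truth=ground,
        metadata=dict(
            cct_um=truth["cct_um"],
            eye_color=truth["eye_color"],
            spherical_equivalent=truth["spherical_equivalent"],
        ),
    )
    return scene


def simulate_cohort(config: SimulationConfig) -> list[EyeScene]:
    """All configured eyes, iAMD first, laterality alternating OD/OS."""
    groups = ["iamd"] * config.n_iamd + ["control"] * config.n_control
    return [simulate_eye(config, i, g) for i, g in enumerate(groups)]


def simulate_truth_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sector/eye truth tables without rendering any image.

    Shares the random stream with :func:`simulate_eye`, so the CT values and
    LCV flags equal those of the fully rendered cohort; useful for
    statistical calibration studies where images are not needed.
    """
    groups = ["iamd"] * config.n_iamd + ["control"] * config.n_control
    sector_rows, eye_rows = [], []
    for i, group in enumerate(groups):
        rng = _eye_rng(config, i)
        truth = _draw_eye_truth(config, rng, group)
        laterality = "OD" if i % 2 == 0 else "OS"
        prefix = "iamd" if group == "iamd" else "ctrl"
        eye_id = f"{prefix}-{i:03d}"
        drusen_flags = {j: j in truth["drusen_sectors"] for j in (1, 2, 3, 4)}
        for j in (1, 2, 3, 4):
            sector_rows.append(
                dict(
                    eye_id=eye_id,
                    group=group,
                    laterality=laterality,
                    sector=j,
                    orientation=SECTOR_ORIENTATION[j],
                    ct_um=truth["ct_um"][j],
                    true_fd_fraction=truth["fd_fraction"][j],
                    lcv=truth["lcv_flags"][j],
                    drusen=drusen_flags[j],
                )
            )
        eye_rows.append(
            dict(
                eye_id=eye_id,
                group=group,
                laterality=laterality,
                lcv_any=any(truth["lcv_flags"].values()),
                cct_um=truth["cct_um"],
                eye_color=truth["eye_color"],
                spherical_equivalent=truth["spherical_equivalent"],
            )
        )
    return pd.DataFrame(sector_rows), pd.DataFrame(eye_rows)


class ChecksumError(ValueError):
    """A fixture file does not match its manifest checksum."""


def write_fixture_set(scenes: list[EyeScene], directory: Path) -> dict:
    """Persist scenes as TIFF/PNG/CSV with a checksummed JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"eyes": {}}
    sector_rows, eye_rows = [], []
    for scene in scenes:
        eye_dir = directory / scene.eye_id
        eye_dir.mkdir(exist_ok=True)
        files = {
            "angio": (eye_dir / "angio.tif", io.write_image_tiff, scene.angio.pixels),
            "structural": (eye_dir / "structural.tif", io.write_image_tiff, scene.structural.pixels),
            "lcv_mask": (eye_dir / "lcv.png", io.write_mask_png, scene.truth.lcv_mask.pixels),
            "drusen_mask": (eye_dir / "drusen.png", io.write_mask_png, scene.truth.drusen_mask.pixels),
            "vessel_mask": (eye_dir / "vessel.png", io.write_mask_png, scene.truth.vessel_mask.pixels),
            "bm_depth": (eye_dir / "bm_depth.tif", io.write_depth_tiff, scene.truth.ct_surfaces.bm_outer_depth),
            "sclera_depth": (
                eye_dir / "sclera_depth.tif",
                io.write_depth_tiff,
                scene.truth.ct_surfaces.sclera_inner_depth,
            ),
        }
        entry = {"group": scene.group, "laterality": scene.laterality, "files": {}}
        for name, (path, writer, data) in files.items():
            writer(path, data)
            entry["files"][name] = {
                "path": str(path.relative_to(directory)),
                "sha256": io.sha256_file(path),
            }
        entry["pitch_um"] = scene.angio.pitch_um
        entry["slab"] = {"offset_um": scene.angio.slab.offset_um, "thickness_um": scene.angio.slab.thickness_um}
        entry["metadata"] = scene.metadata
        manifest["eyes"][scene.eye_id] = entry
        for j in (1, 2, 3, 4):
            sector_rows.append(
                dict(
                    eye_id=scene.eye_id,
                    group=scene.group,
                    laterality=scene.laterality,
                    sector=j,
                    orientation=SECTOR_ORIENTATION[j],
                    ct_um=scene.truth.ct_um[j],
                    true_fd_fraction=scene.truth.sector_fd_fraction[j],
                    lcv=scene.truth.lcv_flags[j],
                    drusen=scene.truth.drusen_flags[j],
                )
            )
        eye_rows.append(dict(eye_id=scene.eye_id, group=scene.group, laterality=scene.laterality, **scene.metadata))
    pd.DataFrame(sector_rows).to_csv(directory / "truth.csv", index=False)
    pd.DataFrame(eye_rows).to_csv(directory / "eyes.csv", index=False)
    for name in ("truth.csv", "eyes.csv"):
        manifest[name] = {"sha256": io.sha256_file(directory / name)}
    io.write_json(directory / "manifest.json", manifest)
    return manifest


def read_fixture_set(directory: Path, validate: bool = True) -> list[EyeScene]:
    """Reload a fixture set, verifying every checksum in the manifest."""
    directory = Path(directory)
    manifest = io.read_json(directory / "manifest.json")
    if validate:
        for name in ("truth.csv", "eyes.csv"):
            if io.sha256_file(directory / name) != manifest[name]["sha256"]:
                raise ChecksumError(f"{name} fails checksum validation")
        for eye_id, entry in manifest["eyes"].items():
            for name, rec in entry["files"].items():
                if io.sha256_file(directory / rec["path"]) != rec["sha256"]:
                    raise ChecksumError(f"{eye_id}/{name} fails checksum validation")
    truth_df = pd.read_csv(directory / "truth.csv")
    scenes = []
    for eye_id, entry in manifest["eyes"].items():
        paths = {name: directory / rec["path"] for name, rec in entry["files"].items()}
        pitch = entry["pitch_um"]
        slab = SlabSpec(**entry["slab"])
        laterality = entry["laterality"]
        angio = io.read_image_tiff(paths["angio"])
        structural = io.read_image_tiff(paths["structural"])
        n = angio.shape[0]
        surfaces = CTSurfaces(
            bm_outer_depth=io.read_depth_tiff(paths["bm_depth"]),
            sclera_inner_depth=io.read_depth_tiff(paths["sclera_depth"]),
            fovea_center_px=((n - 1) / 2.0, (n - 1) / 2.0),
            pitch_um=pitch,
        )
        rows = truth_df[truth_df.eye_id == eye_id].set_index("sector")
        scenes.append(
            EyeScene(
                eye_id=eye_id,
                group=entry["group"],
                laterality=laterality,
                angio=EnFaceImage(angio, pitch, laterality, "angio", slab),
                structural=EnFaceImage(structural, pitch, laterality, "structural", slab),
                truth=GroundTruth(
                    sector_fd_fraction=rows.true_fd_fraction.to_dict(),
                    lcv_mask=BinaryMask(io.read_mask_png(paths["lcv_mask"]), "lcv"),
                    drusen_mask=BinaryMask(io.read_mask_png(paths["drusen_mask"]), "drusen"),
                    vessel_mask=BinaryMask(io.read_mask_png(paths["vessel_mask"]), "vessel-exclusion"),
                    ct_surfaces=surfaces,
                    ct_um=rows.ct_um.to_dict(),
                    lcv_flags=rows.lcv.astype(bool).to_dict(),
                    drusen_flags=rows.drusen.astype(bool).to_dict(),
                ),
                metadata=dict(entry["metadata"]),
            )
        )
    return scenes
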