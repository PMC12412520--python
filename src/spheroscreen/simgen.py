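"""Synthetic droplet spheroid assays with known ground-truth dose response.

The generator emulates a droplet-based drug screen: spheroids exposed to a
dose ladder (including no-drug controls), imaged as brightfield focal stacks
at 0/24/48 h, and read out with a resazurin-type metabolic assay.  Latent
viability follows a Hill dose-response curve whose half-inhibition
concentration (IC50) and slope are configurable, so every downstream stage
(segmentation, features, classification, IC50 inference) can be checked
against an exact oracle.

Morphology is coupled to viability: dying spheroids shrink, darken, and get
rougher texture, while healthy ones grow — the qualitative phenomenology of
drug-treated spheroids in brightfield.  Per-experiment batch effects are
additive on image intensity and multiplicative on fluorescence gain.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .errors import ConfigurationError, RenderingError
from .imaging import ImageStack

__all__ = [
    "SimConfig",
    "SpheroidObservation",
    "simulate_assay",
    "render_spheroid_stack",
    "simulate_metabolic_readout",
    "hill_viability",
    "write_assay",
    "load_assay",
]

BACKGROUND_LEVEL = 200.0  # 8-bit brightfield background


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic assay.

    Defaults follow the droplet screen layout: eight drug conditions spanning
    0.1-50 uM plus no-drug controls, three independent experiments, imaging at
    0/24/48 h with focal planes every 25 um, and a pixel size of 3.26 um.
    """

    concentrations: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    replicates_per_concentration: int = 6
    n_experiments: int = 3
    true_ic50: float = 3.2
    true_hillslope: float = -5.0
    timepoints: tuple[float, ...] = (0.0, 24.0, 48.0)
    pixel_size: float = 3.26
    focal_step: float = 25.0
    n_focal_frames: int = 5
    frame_shape: tuple[int, int] = (160, 160)
    basal_fluorescence: float = 100.0
    control_fluorescence: float = 1000.0
    intensity_sd: float = 3.0
    metabolic_sd: float = 60.0
    batch_intensity_sd: float = 6.0
    batch_gain_sd: float = 0.10
    latent_viability_sd: float = 5.0
    multi_spheroid_fraction: float = 0.075
    n_basal_droplets: int = 8
    # Drug action at 24 h is weaker than at 48 h: the effective IC50 at 24 h
    # is the true (48 h) IC50 times this factor.
    early_response_ic50_factor: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        if not any(c == 0 for c in self.concentrations):
            raise ConfigurationError("concentrations must include 0 (controls)")
        if any(c < 0 for c in self.concentrations):
            raise ConfigurationError("concentrations must be non-negative")
        if self.true_hillslope >= 0:
            raise ConfigurationError("true_hillslope must be negative")
        if self.true_ic50 <= 0:
            raise ConfigurationError("true_ic50 must be positive")
        if self.replicates_per_concentration < 1:
            raise ConfigurationError("replicates_per_concentration must be >= 1")
        if not (0.0 <= self.multi_spheroid_fraction <= 1.0):
            raise ConfigurationError("multi_spheroid_fraction must be in [0, 1]")
        if self.basal_fluorescence < 0:
            raise ConfigurationError("basal_fluorescence must be non-negative")
        if self.control_fluorescence <= self.basal_fluorescence:
            raise ConfigurationError("control_fluorescence must exceed basal")
        if self.pixel_size <= 0 or self.n_focal_frames < 1:
            raise ConfigurationError("invalid imaging geometry")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        for key in ("concentrations", "timepoints", "frame_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SpheroidObservation:
    """One spheroid droplet at one timepoint: image stack plus metadata."""

    spheroid_id: str
    experiment_id: str
    concentration: float
    timepoint: float
    stack: ImageStack


def hill_viability(c, ic50: float, hillslope: float):
    """Hill dose-response Y = 100 / (1 + (IC50/X)**HillSlope), with Y(0)=100.

    ``hillslope`` is negative for an inhibitory response, so Y decreases from
    100 toward 0 as the dose X grows past the IC50.
    """
    c = np.asarray(c, dtype=float)
    out = np.full(c.shape, 100.0)
    pos = c > 0
    out[pos] = 100.0 / (1.0 + (ic50 / c[pos]) ** hillslope)
    return out if out.ndim else float(out)


def _latent_viability(c: float, t: float, config: SimConfig, rng: np.random.Generator) -> float:
    """Latent viability (%) of one spheroid at dose c and time t, with jitter."""
    if t <= 0 or c <= 0:
        v = 100.0
    else:
        frac = min(t / 48.0, 1.0)
        ic50_t = config.true_ic50 * config.early_response_ic50_factor ** (1.0 - frac)
        v = float(hill_viability(np.array([c]), ic50_t, config.true_hillslope)[0])
    v += rng.normal(0.0, config.latent_viability_sd)
    return float(np.clip(v, 0.0, 100.0))


def _morphology(v: float, t: float, r0: float, batch_offset: float,
                rng: np.random.Generator) -> tuple[float, float, float]:
    """Rendered (radius_um, mean_intensity, roughness) for viability v at time t.

    Monotone in viability: healthy spheroids grow, dying ones shrink, darken
    and roughen, with Gaussian jitter on top.
    """
    e = 1.0 - v / 100.0
    frac = min(t / 48.0, 1.0)
    radius = r0 * (1.0 + frac * (0.5 * v / 100.0 - 0.30 * e))
    radius += rng.normal(0.0, 3.0)
    intensity = 150.0 - 55.0 * e * frac + batch_offset + rng.normal(0.0, 2.0)
    roughness = 0.06 + 0.22 * e * frac + rng.normal(0.0, 0.01)
    return max(radius, 20.0), float(np.clip(intensity, 30.0, 220.0)), max(roughness, 0.0)


def render_spheroid_stack(
    radius_um: float,
    mean_intensity: float,
    roughness: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    in_focus_index: int | None = None,
    centers: list[tuple[float, float]] | None = None,
    radii_um: list[float] | None = None,
) -> ImageStack:
    """Render one droplet as a focal stack of 8-bit brightfield frames.

    Exactly one frame (``in_focus_index``, default the middle one) is rendered
    in focus; the others are blurred proportionally to their focal distance.
    The spheroid is a dark disk on a bright background; ``roughness`` sets the
    relative amplitude of a smooth multiplicative texture grain.  Several
    disks can be rendered (multi-spheroid droplets) via ``centers``/``radii_um``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.frame_shape
    if radii_um is None:
        radii_um = [radius_um]
        centers = [(h / 2.0, w / 2.0)]
    if centers is None or len(centers) != len(radii_um):
        raise RenderingError("centers and radii_um must align")
    radii_px = [r / config.pixel_size for r in radii_um]
    for (cy, cx), r_px in zip(centers, radii_px):
        if r_px <= 0:
            raise RenderingError("radius must be positive")
        if cy - r_px < 1 or cy + r_px > h - 1 or cx - r_px < 1 or cx + r_px > w - 1:
            raise RenderingError(
                f"spheroid radius {r_px:.1f} px does not fit the {h}x{w} frame"
            )

    yy, xx = np.mgrid[0:h, 0:w]
    alpha = np.zeros((h, w))
    for (cy, cx), r_px in zip(centers, radii_px):
        dist = np.hypot(yy - cy, xx - cx)
        alpha = np.maximum(alpha, np.clip(0.5 + (r_px - dist), 0.0, 1.0))

    interior = np.full((h, w), float(mean_intensity))
    if roughness > 0:
        grain = ndi.gaussian_filter(rng.normal(size=(h, w)), sigma=2.0)
        sd = grain.std()
        if sd > 0:
            interior *= 1.0 + roughness * grain / sd
    sharp = BACKGROUND_LEVEL * (1.0 - alpha) + interior * alpha

    if in_focus_index is None:
        in_focus_index = config.n_focal_frames // 2
    blur_px_per_frame = 1.5
    frames = np.empty((config.n_focal_frames, h, w), dtype=np.uint8)
    for i in range(config.n_focal_frames):
        sigma = blur_px_per_frame * abs(i - in_focus_index)
        frame = ndi.gaussian_filter(sharp, sigma=sigma) if sigma > 0 else sharp.copy()
        if config.intensity_sd > 0:
            frame = frame + rng.normal(0.0, config.intensity_sd, size=(h, w))
        frames[i] = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    return ImageStack(frames, focal_step=config.focal_step, pixel_size=config.pixel_size)


def simulate_metabolic_readout(
    viability_pct: float,
    config: SimConfig,
    control_mean: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Raw droplet fluorescence for a given viability percentage.

    Inverse of the metabolic-activity normalization: returns
    ``B + (v/100) * (I_control - B)`` plus Gaussian noise when an ``rng`` is
    given; with no rng the mapping is exact, so normalizing the output
    recovers ``viability_pct``.
    """
    if viability_pct < 0:
        raise ValueError("viability_pct must be >= 0")
    if config.basal_fluorescence < 0:
        raise ConfigurationError("basal_fluorescence must be non-negative")
    b = config.basal_fluorescence
    ctrl = config.control_fluorescence if control_mean is None else control_mean
    value = b + (viability_pct / 100.0) * (ctrl - b)
    if rng is not None and config.metabolic_sd > 0:
        value += rng.normal(0.0, config.metabolic_sd)
    return float(value)


def simulate_assay(
    config: SimConfig,
) -> tuple[list[SpheroidObservation], pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic assay.

    Returns
    -------
    observations : list of SpheroidObservation
        One entry per spheroid per timepoint (image stacks in memory).
    readouts : DataFrame
        Droplet fluorescence table with columns ``droplet_id, experiment_id,
        concentration_um, raw_fluorescence, is_control, is_basal``; includes
        basal-only (no-cell) droplets and the no-drug control droplets.
    truth : DataFrame
        Ground-truth table: latent viability at 48 h, true class labels, and
        the rendered 48 h radius/intensity/roughness per spheroid.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    observations: list[SpheroidObservation] = []
    readout_rows: list[dict] = []
    truth_rows: list[dict] = []

    for e in range(config.n_experiments):
        exp_id = f"exp{e + 1}"
        batch_offset = rng.normal(0.0, config.batch_intensity_sd)
        batch_gain = float(np.exp(rng.normal(0.0, config.batch_gain_sd)))
        control_mean = config.basal_fluorescence + batch_gain * (
            config.control_fluorescence - config.basal_fluorescence
        )

        for b in range(config.n_basal_droplets):
            readout_rows.append(
                {
                    "droplet_id": f"{exp_id}_basal{b + 1}",
                    "experiment_id": exp_id,
                    "concentration_um": np.nan,
                    "raw_fluorescence": config.basal_fluorescence
                    + rng.normal(0.0, 0.1 * config.metabolic_sd),
                    "is_control": False,
                    "is_basal": True,
                }
            )

        idx = 0
        for c in config.concentrations:
            for _ in range(config.replicates_per_concentration):
                idx += 1
                sid = f"{exp_id}_s{idx:03d}"
                r0 = rng.normal(140.0, 8.0)
                is_multi = rng.random() < config.multi_spheroid_fraction
                split = rng.uniform(0.35, 0.65) if is_multi else 1.0

                v48 = np.nan
                for t in config.timepoints:
                    v = _latent_viability(c, t, config, rng)
                    if t == max(config.timepoints):
                        v48 = v
                    radius, intensity, rough = _morphology(v, t, r0, batch_offset, rng)
                    h, w = config.frame_shape
                    max_radius_um = (min(h, w) / 2.0 - 2.0) * config.pixel_size
                    radius = min(radius, max_radius_um)
                    focus = int(rng.integers(0, config.n_focal_frames))
                    if is_multi and t == 0:
                        # two sibling spheroids that fuse by the next day;
                        # radii split conserves volume (r^3), matching the
                        # area-fusion rule used downstream.  Placed on the
                        # frame diagonal, shrunk proportionally if needed.
                        r1 = radius * split ** (1.0 / 3.0)
                        r2 = radius * (1.0 - split) ** (1.0 / 3.0)
                        px = config.pixel_size
                        for _try in range(20):
                            sep = (r1 + r2) / px + 4.0
                            dd = sep / (2.0 * np.sqrt(2.0))
                            rmax = max(r1, r2) / px
                            if min(h, w) / 2.0 - dd - rmax >= 2.0:
                                break
                            r1 *= 0.95
                            r2 *= 0.95
                        centers = [
                            (h / 2.0 - dd, w / 2.0 - dd),
                            (h / 2.0 + dd, w / 2.0 + dd),
                        ]
                        stack = render_spheroid_stack(
                            radius, intensity, rough, config, rng=rng,
                            in_focus_index=focus, centers=centers,
                            radii_um=[r1, r2],
                        )
                    else:
                        stack = render_spheroid_stack(
                            radius, intensity, rough, config, rng=rng,
                            in_focus_index=focus,
                        )
                    observations.append(
                        SpheroidObservation(sid, exp_id, c, t, stack)
                    )
                    if t == max(config.timepoints):
                        truth_rows.append(
                            {
                                "spheroid_id": sid,
                                "experiment_id": exp_id,
                                "concentration_um": c,
                                "viability_pct": v48,
                                "class2": "low" if v48 < 50 else "high",
                                "class3": (
                                    "low" if v48 < 25
                                    else "high" if v48 > 75
                                    else "intermediate"
                                ),
                                "is_multi": is_multi,
                                "radius_um_48h": radius,
                                "mean_intensity_48h": intensity,
                                "roughness_48h": rough,
                            }
                        )

                readout_rows.append(
                    {
                        "droplet_id": sid,
                        "experiment_id": exp_id,
                        "concentration_um": c,
                        "raw_fluorescence": simulate_metabolic_readout(
                            v48, config, control_mean=control_mean, rng=rng
                        ),
                        "is_control": c == 0,
                        "is_basal": False,
                    }
                )

    return observations, pd.DataFrame(readout_rows), pd.DataFrame(truth_rows)


def write_assay(
    observations: list[SpheroidObservation],
    readouts: pd.DataFrame,
    truth: pd.DataFrame,
    out_dir: str | Path,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Write an assay to disk: per-spheroid multi-page TIFFs plus CSV tables.

    Returns the metadata table (spheroid_id, experiment_id, concentration_um,
    timepoint_h, stack_path).
    """
    out = Path(out_dir)
    stacks_dir = out / "stacks"
    stacks_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for obs in observations:
        name = f"{obs.spheroid_id}_t{int(obs.timepoint):02d}h.tif"
        tifffile.imwrite(stacks_dir / name, obs.stack.frames)
        meta_rows.append(
            {
                "spheroid_id": obs.spheroid_id,
                "experiment_id": obs.experiment_id,
                "concentration_um": obs.concentration,
                "timepoint_h": obs.timepoint,
                "stack_path": str(Path("stacks") / name),
            }
        )
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out / "metadata.csv", index=False)
    readouts.to_csv(out / "fluorescence.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    if config is not None:
        (out / "sim_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return meta


def load_assay(
    in_dir: str | Path,
) -> tuple[list[SpheroidObservation], pd.DataFrame, pd.DataFrame]:
    """Load an assay written by :func:`write_assay`."""
    root = Path(in_dir)
    meta = pd.read_csv(root / "metadata.csv")
    cfg_path = root / "sim_config.json"
    focal_step, pixel_size = 25.0, 3.26
    if cfg_path.exists():
        cfg = json.loads(cfg_path.read_text())
        focal_step = cfg.get("focal_step", focal_step)
        pixel_size = cfg.get("pixel_size", pixel_size)
    observations = []
    for row in meta.itertuples():
        frames = tifffile.imread(root / row.stack_path)
        observations.append(
            SpheroidObservation(
                row.spheroid_id,
                row.experiment_id,
                float(row.concentration_um),
                float(row.timepoint_h),
                ImageStack(frames, focal_step=focal_step, pixel_size=pixel_size),
            )
        )
    readouts = pd.read_csv(root / "fluorescence.csv")
    truth = pd.read_csv(root / "ground_truth.csv")
    return observations, readouts, truth
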