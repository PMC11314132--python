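"""Synthetic frond images and experiment designs.

The generator emulates the statistical structure the analysis pipeline
assumes, not the optics: a near-black background whose DCVs pile up below
10; a frond-shaped foreground region whose per-channel intensities are
truncated normals (red dominant, as chlorophyll fluorescence is captured
in the red emission band); and a Cu-dose response expressed as a mean
shift of the blue-channel foreground distribution, strongest at the
moment of dosing and decaying at the later samplings.

Per-frond biological variability enters as a small random jitter of the
frond's channel means, which is what gives the control population a
non-degenerate distance spread for the 3-sigma envelope.

The default design mirrors the study layout: 3 trays x 10 partitions x 4
samplings (one pre-dose control sampling at negative time offsets, then
0, 24 and 48 h), with trays 1/2/3 dosed at 1/10/100 nmol/cm^2.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .chemistry import CHL_A_COEF, CHL_B_COEF, nmol_per_g_to_mg_per_kg
from .image_io import FrondSample, METADATA_COLUMNS, RGBImage

#: Per-tray Cu dose, nmol/cm^2.
TRAY_DOSES = {1: 1.0, 2: 10.0, 3: 100.0}

#: Sampling schedule, hours relative to dosing; controls cycle the negatives.
CONTROL_OFFSETS = (-8.0, -16.0, -24.0)
POST_OFFSETS = (0.0, 24.0, 48.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Tray/partition/sampling layout of a synthetic experiment."""

    trays: tuple[int, ...] = (1, 2, 3)
    n_partitions: int = 10
    doses: dict[int, float] = field(default_factory=lambda: dict(TRAY_DOSES))
    laser: str = "Chl-SL—B 462 nm"
    filter: str = "650—chl-b"


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the image generator; defaults are the study-like conditions."""

    height: int = 96
    width: int = 128
    background_mean: float = 3.0
    background_sd: float = 2.0
    frond_area_fraction: float = 0.25
    n_branches: int = 2
    # red-dominant fluorescence foreground, DCV
    fg_mean: tuple[float, float, float] = (150.0, 60.0, 45.0)
    fg_sd: tuple[float, float, float] = (25.0, 15.0, 12.0)
    #: per-frond jitter of channel means (biological variability), DCV
    frond_jitter_sd: float = 3.0
    #: blue-channel mean shift at the highest dose (100 nmol/cm^2), DCV
    dose_shift_max: float = 0.0
    #: fractional widening of the blue foreground sd at the highest dose;
    #: dosing quenches fluorescence unevenly across the frond, so the
    #: intensity distribution broadens (and its peak drops) as it shifts
    dose_sd_gain: float = 0.0
    dose_channels: tuple[str, ...] = ("B",)
    #: multiplier on the shift at each post-dose sampling
    time_decay: tuple[tuple[float, float], ...] = ((0.0, 1.0), (24.0, 0.1), (48.0, 0.03))
    # chemistry effect sizes (0 = null)
    ab_ratio_drop: float = 0.0   # fractional a/b depression at dose 100, time 0
    cu_gain_nmol_per_g: float = 0.0  # dw Cu per unit dose added post-dosing


#: Named study conditions.
PRESETS = {
    "null": SyntheticParams(),
    "weak": SyntheticParams(dose_shift_max=25.0, dose_sd_gain=0.3,
                            ab_ratio_drop=0.2, cu_gain_nmol_per_g=0.05),
    "strong": SyntheticParams(dose_shift_max=90.0, dose_sd_gain=1.0,
                              ab_ratio_drop=0.5, cu_gain_nmol_per_g=0.15),
}


def dose_level(params: SyntheticParams, dose: float, time_offset_h: float) -> float:
    """Effect level in [0, 1] for a given dose and time since dosing.

    Doses 1/10/100 map to levels 1/3, 2/3 and 1 (log scale); pre-dose
    samples and dose 0 have level 0; the level decays with time after
    dosing (the response is transient).
    """
    if dose <= 0 or time_offset_h < 0:
        return 0.0
    level = (1.0 + np.log10(dose)) / 3.0
    decay = dict(params.time_decay).get(time_offset_h, 0.0)
    return level * decay


def dose_shift(params: SyntheticParams, dose: float, time_offset_h: float) -> float:
    """Blue-channel mean-shift magnitude, DCV."""
    return params.dose_shift_max * dose_level(params, dose, time_offset_h)


def _frond_mask(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Elliptical frond body plus small branch lobes; boolean H x W mask."""
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    # main ellipse sized to the requested area fraction (pi*a*b = f*h*w)
    aspect = 2.5  # fronds are elongated
    b = np.sqrt(params.frond_area_fraction * h * w / (np.pi * aspect))
    a = aspect * b
    ang = rng.uniform(-0.3, 0.3)
    ca, sa = np.cos(ang), np.sin(ang)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    for _ in range(params.n_branches):
        off_u = rng.uniform(-0.6, 0.6) * a
        off_v = rng.uniform(1.0, 1.8) * b * rng.choice([-1.0, 1.0])
        bu, bv = 0.35 * a, 0.8 * b
        mask |= ((u - off_u) / bu) ** 2 + ((v - off_v) / bv) ** 2 <= 1.0
    if not mask.any():
        raise ValueError("frond mask has zero area; enlarge the image or area fraction")
    return mask


def _image_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Stable per-image stream: the run seed mixed with the sample id."""
    return np.random.default_rng((seed, zlib.crc32(sample_id.encode())))


def generate_frond_image(
    params: SyntheticParams, sample: FrondSample, seed: int
) -> RGBImage:
    """Draw one frond image; byte-identical for identical (seed, sample_id)."""
    rng = _image_rng(seed, sample.sample_id)
    h, w = params.height, params.width
    img = rng.normal(params.background_mean, params.background_sd, size=(h, w, 3))
    mask = _frond_mask(params, rng)
    level = dose_level(params, sample.dose_nmol_per_cm2, sample.time_offset_h)
    for k, ch in enumerate(("R", "G", "B")):
        mean = params.fg_mean[k] + rng.normal(0.0, params.frond_jitter_sd)
        sd = params.fg_sd[k]
        if ch in params.dose_channels:
            mean += params.dose_shift_max * level
            sd *= 1.0 + params.dose_sd_gain * level
        img[:, :, k][mask] = rng.normal(mean, sd, size=int(mask.sum()))
    img = np.clip(np.round(img), 0, 255).astype(np.int64)
    return RGBImage(pixels=img, source_id=sample.sample_id)


def design_samples(design: ExperimentDesign | None = None) -> list[FrondSample]:
    """Enumerate the FrondSample records of a design (no images yet)."""
    design = design or ExperimentDesign()
    samples = []
    for tray in design.trays:
        dose = design.doses.get(tray, 0.0)
        for part in range(1, design.n_partitions + 1):
            offsets = [CONTROL_OFFSETS[(part - 1) % len(CONTROL_OFFSETS)]]
            offsets += list(POST_OFFSETS)
            for t in offsets:
                samples.append(
                    FrondSample(
                        sample_id=f"T{tray}P{part:02d}H{int(t):+04d}",
                        tray=tray,
                        partition=part,
                        time_offset_h=t,
                        dose_nmol_per_cm2=dose if t >= 0 else 0.0,
                        sample_type="single",
                        laser=design.laser,
                        filter=design.filter,
                    )
                )
    return samples


def generate_experiment(
    params: SyntheticParams,
    seed: int,
    design: ExperimentDesign | None = None,
) -> list[tuple[FrondSample, RGBImage]]:
    """Full synthetic experiment: one image per design record."""
    return [
        (s, generate_frond_image(params, s, seed)) for s in design_samples(design)
    ]


def metadata_frame(samples: list[FrondSample]) -> pd.DataFrame:
    """Sidecar-schema metadata table for a list of samples."""
    return pd.DataFrame(
        [
            {
                "source_id": s.sample_id,
                "tray": s.tray,
                "partition": s.partition,
                "time_offset_h": s.time_offset_h,
                "dose_nmol_per_cm2": s.dose_nmol_per_cm2,
                "sample_type": s.sample_type,
                "laser": s.laser,
                "filter": s.filter,
            }
            for s in samples
        ],
        columns=list(METADATA_COLUMNS),
    )


def write_experiment(
    outdir: str | Path,
    params: SyntheticParams,
    seed: int,
    design: ExperimentDesign | None = None,
) -> Path:
    """Write PNGs plus metadata.csv; returns the metadata path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    images = generate_experiment(params, seed, design)
    for s, img in images:
        iio.imwrite(outdir / f"{s.sample_id}.png", img.pixels.astype(np.uint8))
    meta = metadata_frame([s for s, _ in images])
    meta_path = outdir / "metadata.csv"
    meta.to_csv(meta_path, index=False)
    return meta_path


def _extinctions_for(chl_a_ug_ml: float, chl_b_ug_ml: float) -> tuple[float, float]:
    """Invert the chlorophyll equations: concentrations -> absorbances."""
    a11, a12 = CHL_A_COEF
    a21, a22 = CHL_B_COEF
    det = a11 * a22 - a12 * a21
    e663 = (a22 * chl_a_ug_ml - a12 * chl_b_ug_ml) / det
    e646 = (a11 * chl_b_ug_ml - a21 * chl_a_ug_ml) / det
    return e663, e646


def generate_chemistry(
    params: SyntheticParams,
    seed: int,
    design: ExperimentDesign | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic chlorophyll and SET tables, schema-identical to the fixtures.

    Dosing at time 0 depresses the a/b ratio by ``ab_ratio_drop`` (scaled
    by the dose level like the image shift) and raises the dry-weight Cu
    content by ``cu_gain_nmol_per_g`` per nmol/cm^2 of dose, with
    lognormal measurement noise throughout.
    """
    design = design or ExperimentDesign()
    rng = np.random.default_rng((seed, 0xC0FFEE))
    chl_rows, set_rows = [], []
    for s in design_samples(design):
        wet_mg = rng.uniform(6.0, 14.0)
        chl_a_conc = rng.lognormal(np.log(3.3 * wet_mg), 0.35)
        ratio = rng.lognormal(np.log(1.5), 0.25)
        if s.dose_nmol_per_cm2 > 0 and s.time_offset_h == 0 and params.ab_ratio_drop > 0:
            level = (1.0 + np.log10(s.dose_nmol_per_cm2)) / 3.0
            ratio *= 1.0 - params.ab_ratio_drop * level
        chl_b_conc = chl_a_conc / ratio
        e663, e646 = _extinctions_for(chl_a_conc, chl_b_conc)
        chl_rows.append(
            {
                "tray": s.tray,
                "sample": s.sample_id,
                "e663_8": e663,
                "e646_8": e646,
                "wet_weight_mg": wet_mg,
                "chl_a_per_mg": chl_a_conc / wet_mg,
                "chl_b_per_mg": chl_b_conc / wet_mg,
                "total_per_mg": (chl_a_conc + chl_b_conc) / wet_mg,
                "ab_ratio_printed": ratio,
            }
        )
        # SET records: 5 controls per tray, all 10 partitions post-dose
        is_set = (s.is_control and s.partition <= 5) or not s.is_control
        if not is_set:
            continue
        wet_g = rng.uniform(0.02, 0.08)
        dry_g = wet_g * rng.uniform(0.08, 0.15)
        base = rng.lognormal(np.log(0.25), 0.4)  # background dw Cu, nmol/g
        gain = 0.0
        if s.dose_nmol_per_cm2 > 0 and s.time_offset_h >= 0:
            gain = params.cu_gain_nmol_per_g * s.dose_nmol_per_cm2 * rng.lognormal(0.0, 0.3)
        dw_content = base + gain
        set_rows.append(
            {
                "tray": s.tray,
                "sample": s.sample_id,
                "cu_ww": dw_content * dry_g / wet_g,
                "cu_dw": dw_content,
                "cu_dw_mg_per_kg": nmol_per_g_to_mg_per_kg(dw_content),
                "wet_weight_g": wet_g,
                "dry_weight_g": dry_g,
            }
        )
    return pd.DataFrame(chl_rows), pd.DataFrame(set_rows)
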