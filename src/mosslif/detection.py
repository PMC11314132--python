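"""Control-envelope anomaly detection.

Each tray carries its own pre-dose control population.  For every metric
and channel (or channel pair) the controls are scored against each other
leave-one-out, giving a control distance distribution whose mean +/- 3
standard deviations forms the deviation envelope.  A sample whose
distance-to-controls falls outside that envelope is flagged as deviating
— the study's criterion for "this frond looks contaminated".

Values exactly on an envelope bound are, by convention, not deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .curves import AbundanceCurve, EmptyCurveError, PairedCurve, abundance, histogram, pair
from .distances import DistanceValue, density_difference, dtw_distance, dtw_two_color
from .image_io import CHANNELS, FrondSample, RGBImage, split_channels
from .preprocess import ThresholdSpec, apply_threshold

logger = logging.getLogger(__name__)

#: Channel-pair label -> the two single channels it joins.
PAIR_MEMBERS = {"RvG": ("R", "G"), "GvB": ("G", "B"), "RvB": ("R", "B")}

# A CurveSet maps "R"/"G"/"B" to AbundanceCurve and "RvG"/... to PairedCurve.
CurveSet = dict


class InsufficientControlsError(ValueError):
    """An envelope needs at least two controls; a score needs at least one."""


@dataclass
class ControlEnvelope:
    metric: str
    channels: str
    mean: float
    sd: float
    n_controls: int
    tray: int | None = None

    @property
    def upper_3sigma(self) -> float:
        return self.mean + 3.0 * self.sd

    @property
    def lower_3sigma(self) -> float:
        return self.mean - 3.0 * self.sd


@dataclass
class DeviationRecord:
    sample: FrondSample
    metric: str
    channels: str
    value: float
    deviates: bool
    envelope: ControlEnvelope


def prepare_curves(img: RGBImage, spec: ThresholdSpec) -> CurveSet:
    """Threshold an image and build its single- and two-color curves."""
    chans = split_channels(img)
    curves: CurveSet = {}
    for ch in CHANNELS:
        res = apply_threshold(chans[ch], spec)
        if res.all_removed:
            raise EmptyCurveError(
                f"threshold removed every pixel of channel {ch} in {img.source_id}"
            )
        curves[ch] = abundance(histogram(res.retained), res.threshold_used)
    for label, (a, b) in PAIR_MEMBERS.items():
        curves[label] = pair(curves[a], curves[b])
    return curves


def _distance(metric: str, channels: str, s: CurveSet, c: CurveSet,
              normalize: str = "none") -> float:
    if metric == "density_diff":
        return density_difference(s[channels], c[channels]).value
    if metric == "dtw1":
        return dtw_distance(s[channels], c[channels], normalize=normalize).value
    if metric == "dtw2":
        return dtw_two_color(s[channels], c[channels], normalize=normalize).value
    raise ValueError(f"unknown metric {metric!r}")


def sample_vs_controls(
    sample_curves: CurveSet,
    control_curves: list[CurveSet],
    metric: str,
    channels: str,
    aggregate: str = "mean",
    normalize: str = "none",
    sample_id: str = "",
) -> DistanceValue:
    """Score one sample against the control population.

    The reported value aggregates the pairwise distances from the sample
    to each control curve; the mean is the default, the minimum is the
    conservative alternative.
    """
    if not control_curves:
        raise InsufficientControlsError("no control curves to compare against")
    vals = [
        _distance(metric, channels, sample_curves, c, normalize)
        for c in control_curves
    ]
    agg = float(np.mean(vals)) if aggregate == "mean" else float(np.min(vals))
    return DistanceValue(
        metric=metric,
        channels=channels,
        value=agg,
        sample_id=sample_id,
        control_id=f"controls(n={len(control_curves)})",
    )


def envelope_from_values(
    loo_values: list[float] | np.ndarray,
    metric: str = "",
    channels: str = "",
    tray: int | None = None,
) -> ControlEnvelope:
    """Envelope arithmetic over precomputed leave-one-out control values:
    mean, sample sd (n-1 denominator), and the implied 3-sigma bounds."""
    vals = np.asarray(loo_values, dtype=np.float64)
    if len(vals) < 2:
        raise InsufficientControlsError("an envelope needs >= 2 values")
    return ControlEnvelope(
        metric=metric,
        channels=channels,
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)),
        n_controls=len(vals),
        tray=tray,
    )


def build_envelope(
    control_curves: list[CurveSet],
    metric: str,
    channels: str,
    aggregate: str = "mean",
    normalize: str = "none",
    tray: int | None = None,
) -> ControlEnvelope:
    """Leave-one-out control scoring -> mean, sample sd, 3-sigma bounds.

    Each control is scored against the remaining controls exactly as a
    sample would be, so the envelope describes the distance distribution a
    healthy frond produces under the configured aggregation rule.
    """
    n = len(control_curves)
    if n < 2:
        raise InsufficientControlsError("an envelope needs >= 2 controls")
    loo = [
        sample_vs_controls(
            control_curves[i],
            control_curves[:i] + control_curves[i + 1:],
            metric,
            channels,
            aggregate=aggregate,
            normalize=normalize,
        ).value
        for i in range(n)
    ]
    return envelope_from_values(loo, metric=metric, channels=channels, tray=tray)


def flag(
    sample: FrondSample,
    value: float,
    envelope: ControlEnvelope,
) -> DeviationRecord:
    """Deviation iff the value lies strictly outside the closed 3-sigma band."""
    deviates = value > envelope.upper_3sigma or value < envelope.lower_3sigma
    return DeviationRecord(
        sample=sample,
        metric=envelope.metric,
        channels=envelope.channels,
        value=value,
        deviates=deviates,
        envelope=envelope,
    )


def analyze_experiment(
    images: list[tuple[FrondSample, RGBImage]],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and flag every sample of an experiment against its tray's controls.

    Controls (negative time offsets) are scored too, via leave-one-out, so
    they appear in the output at their pre-dose offsets.  Trays with no
    controls are skipped with a logged error.  Returns (deviations,
    envelopes) tables sorted by tray, time offset, partition.
    """
    prepared = [
        (meta, prepare_curves(img, config.threshold)) for meta, img in images
    ]
    metric_channel_pairs = [
        (m, c)
        for m in config.metrics
        for c in (config.pairs if m == "dtw2" else config.channels)
    ]
    prov = config.provenance()
    dev_rows, env_rows = [], []
    for tray in sorted({meta.tray for meta, _ in prepared}):
        tray_items = [(m, cs) for m, cs in prepared if m.tray == tray]
        controls = [(m, cs) for m, cs in tray_items if m.is_control]
        if len(controls) < 2:
            logger.error("tray %s has <2 control images; skipped", tray)
            continue
        control_sets = [cs for _, cs in controls]
        for metric, channels in metric_channel_pairs:
            env = build_envelope(
                control_sets,
                metric,
                channels,
                aggregate=config.control_aggregate,
                normalize=config.normalize,
                tray=tray,
            )
            env_rows.append(
                {
                    "tray": tray,
                    "metric": metric,
                    "channels": channels,
                    "mean": env.mean,
                    "sd": env.sd,
                    "lower_3sigma": env.lower_3sigma,
                    "upper_3sigma": env.upper_3sigma,
                    "n_controls": env.n_controls,
                    **prov,
                }
            )
            for meta, cs in tray_items:
                others = (
                    [c for c in control_sets if c is not cs]
                    if meta.is_control
                    else control_sets
                )
                dv = sample_vs_controls(
                    cs,
                    others,
                    metric,
                    channels,
                    aggregate=config.control_aggregate,
                    normalize=config.normalize,
                    sample_id=meta.sample_id,
                )
                rec = flag(meta, dv.value, env)
                dev_rows.append(
                    {
                        "sample_id": meta.sample_id,
                        "tray": meta.tray,
                        "partition": meta.partition,
                        "time_offset_h": meta.time_offset_h,
                        "dose_nmol_per_cm2": meta.dose_nmol_per_cm2,
                        "sample_type": meta.sample_type,
                        "laser": meta.laser,
                        "filter": meta.filter,
                        "metric": metric,
                        "channels": channels,
                        "value": rec.value,
                        "upper_3sigma": env.upper_3sigma,
                        "lower_3sigma": env.lower_3sigma,
                        "deviates": rec.deviates,
                        **prov,
                    }
                )
    deviations = pd.DataFrame(dev_rows)
    envelopes = pd.DataFrame(env_rows)
    if not deviations.empty:
        deviations = deviations.sort_values(
            ["tray", "time_offset_h", "partition", "metric", "channels"]
        ).reset_index(drop=True)
    return deviations, envelopes
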