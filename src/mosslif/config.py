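"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import ThresholdSpec

ALL_CHANNELS = ("R", "G", "B")
ALL_PAIRS = ("RvG", "GvB", "RvB")
ALL_METRICS = ("density_diff", "dtw1", "dtw2")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on besides the images themselves."""

    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    curve_scale: str = "fraction"  # fraction | percent (display only)
    metrics: tuple[str, ...] = ALL_METRICS
    channels: tuple[str, ...] = ALL_CHANNELS
    pairs: tuple[str, ...] = ALL_PAIRS
    control_aggregate: str = "mean"  # mean | min
    normalize: str = "none"  # none | path_length (DTW only)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError("at least one metric must be selected")
        needs_single = {"density_diff", "dtw1"} & set(self.metrics)
        if needs_single and not self.channels:
            raise ValueError("single-color metrics need at least one channel")
        if "dtw2" in self.metrics and not self.pairs:
            raise ValueError("dtw2 needs at least one channel pair")
        for m in self.metrics:
            if m not in ALL_METRICS:
                raise ValueError(f"unknown metric {m!r}")
        if self.control_aggregate not in ("mean", "min"):
            raise ValueError("control_aggregate must be 'mean' or 'min'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = raw.pop("threshold", {})
        spec = ThresholdSpec(
            mode=thr.get("mode", "manual"),
            cutoff=int(thr.get("cutoff", 10)),
            scope=thr.get("scope", "per_channel"),
        )
        for key in ("metrics", "channels", "pairs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(threshold=spec, **raw)

    def provenance(self) -> dict:
        """Flat key/value provenance stamped onto every output row."""
        return {
            "threshold_mode": self.threshold.mode,
            "threshold_cutoff": self.threshold.cutoff,
            "threshold_scope": self.threshold.scope,
            "control_aggregate": self.control_aggregate,
            "normalize": self.normalize,
            "seed": self.seed,
        }
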