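"""Study configuration: one YAML-serializable object drives the pipeline.

The defaults encode the study conditions the analysis is designed for:
ten imaging platforms, two image types (VUE and VMI70keV), two repeated
scans, ~10 HU noise, ~15 HU per-insert platform spread on monoenergetic
images with twice that spread on virtual unenhanced images, and 25 HU
discretization bins.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .phantom_synth import IMAGE_TYPES

__all__ = ["StudyConfig", "DEFAULT_SHORTLIST"]

# 14 commonly reported, biomarker-grade feature names.  The set tracked in
# the physical study is cited, not listed, there; this default is a
# documented placeholder and fully configurable.
DEFAULT_SHORTLIST: tuple[tuple[str, str], ...] = (
    ("firstorder", "Mean"),
    ("firstorder", "Median"),
    ("firstorder", "Entropy"),
    ("firstorder", "Uniformity"),
    ("firstorder", "RootMeanSquared"),
    ("firstorder", "Skewness"),
    ("firstorder", "Kurtosis"),
    ("glcm", "Contrast"),
    ("glcm", "Correlation"),
    ("glcm", "JointEntropy"),
    ("glcm", "Idm"),
    ("glrlm", "ShortRunEmphasis"),
    ("glrlm", "RunLengthNonUniformity"),
    ("glszm", "SizeZoneNonUniformity"),
)


@dataclass(frozen=True)
class StudyConfig:
    """All tunable parameters of one robustness study."""

    # study design
    n_platforms: int = 10
    image_types: tuple[str, ...] = IMAGE_TYPES
    n_repeats: int = 2
    # platform surrogates
    spread_hu: float = 15.0           # per-insert deviation SD on VMI70keV
    vue_spread_factor: float = 2.0    # VUE deviation SD multiplier
    bias_sd_hu: float = 5.0
    noise_sd_hu: float = 10.0
    kernel_fwhm_px: float = 2.0
    kernel_jitter: float = 0.25
    insert_spread_scale: dict[int, float] = field(default_factory=dict)
    # extraction
    bin_width: float = 25.0
    roi_diameter_px: int = 26
    gldm_alpha: float = 0.0
    # analysis
    repeat_policy: str = "first"      # {"first", "second", "mean"}
    repeatability_cutoff: float = 0.90
    dispersion_cutoff_pct: float = 10.0
    agreement_cutoff: float = 0.90
    top_k: int = 10
    shortlist: tuple[tuple[str, str], ...] = DEFAULT_SHORTLIST

    def __post_init__(self) -> None:
        if self.n_platforms < 2:
            raise ValueError("n_platforms must be >= 2")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2 for test–retest analysis")
        if self.repeat_policy not in ("first", "second", "mean"):
            raise ValueError(f"unknown repeat_policy {self.repeat_policy!r}")
        for t in self.image_types:
            if t not in IMAGE_TYPES:
                raise ValueError(f"unknown image type {t!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_types"] = list(self.image_types)
        d["shortlist"] = [list(p) for p in self.shortlist]
        d["insert_spread_scale"] = {int(k): float(v)
                                    for k, v in self.insert_spread_scale.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "image_types" in d:
            d["image_types"] = tuple(d["image_types"])
        if "shortlist" in d:
            d["shortlist"] = tuple((c, n) for c, n in d["shortlist"])
        if "insert_spread_scale" in d and d["insert_spread_scale"] is not None:
            d["insert_spread_scale"] = {int(k): float(v)
                                        for k, v in d["insert_spread_scale"].items()}
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Stable digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)
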