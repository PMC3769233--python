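"""Analysis configuration: a flat, YAML-round-trippable parameter set.

Unknown keys are rejected on load so a typo in a config file fails loudly
instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .psf import PSFModel
from .simulate import SpineGeometry

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Every tunable of the simulate→deconvolve→detect→size→NN→quantify chain."""

    # acquisition
    pixel_size_nm: float = 20.0
    # PSF / deconvolution
    psf_shape: str = "lorentzian"
    psf_fwhm_nm: float = 40.0
    psf_support_px: int = 11
    deconvolution_iterations: int = 20
    # detection
    min_peak_snr: float = 5.0
    # Euclidean exclusion radius between detections; one cluster-sized
    # profile width, so sub-structure inside a cluster stays one detection.
    # Spacing analyses near the resolution limit lower this to 40 nm (the
    # resolution floor of the deconvolved data).
    min_separation_nm: float = 60.0
    # raw-image brightness floor for accepted peaks, in counts above
    # background: half the 32-count single-antibody calibration peak —
    # a dimmer maximum cannot correspond to even one labelled complex
    min_peak_counts: float = 16.0
    # sizing
    n_angles: int = 20
    profile_half_length_nm: float = 200.0
    # nearest neighbor
    nn_bin_width_nm: float = 20.0
    # stoichiometry
    concentration_uM: float = 50.0
    head_diameter_nm: float = 300.0
    neck_length_nm: float = 300.0
    neck_width_nm: float = 100.0
    # reproducibility
    seed: int = 0

    def psf(self) -> PSFModel:
        return PSFModel(self.psf_shape, self.psf_fwhm_nm, self.pixel_size_nm,
                        self.psf_support_px)

    def geometry(self) -> SpineGeometry:
        return SpineGeometry(self.head_diameter_nm, self.neck_length_nm,
                             self.neck_width_nm)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
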