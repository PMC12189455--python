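"""Pipeline configuration: every tunable in one serializable object.

Defaults reproduce the analysis settings of the motivating study: 0.01-0.1 Hz
band, 6 mm FWHM smoothing applied to the normalized maps, voxel p < 0.001
cluster-forming threshold, cluster FDR < 0.05, 18-neighbour connectivity,
one-voxel / 0.5-degree motion limits and the 23-outlier-regressor exclusion
rule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # paths (any may be None for in-memory use)
    runs_dir: str | None = None
    confounds_dir: str | None = None
    design_path: str | None = None
    mask_path: str | None = None
    atlas_path: str | None = None
    output_dir: str | None = None

    band_hz: tuple[float, float] = (0.01, 0.1)
    smoothing_fwhm_mm: float = 6.0
    #: "normalized" smooths the rank-Gaussianized maps (default); "falff"
    #: smooths the raw ratio maps before normalization.
    smoothing_target: str = "normalized"
    #: "residual" uses the confound-regressed unfiltered signal as the fALFF
    #: denominator (default); "raw" uses the mean-removed raw signal.
    falff_denominator: str = "residual"

    voxel_p: float = 0.001
    cluster_fdr: float = 0.05
    connectivity: int = 18
    fdr_pool_signs: bool = True

    qc_translation_voxels: float = 1.0
    qc_rotation_deg: float = 0.5
    outlier_limit: int = 23
    fd_threshold_mm: float = 0.9
    global_z_threshold: float = 5.0

    tr_s: float | None = None  # overrides header TR when set
    n_perm: int = 0  # >0 additionally runs the permutation oracle
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        lo, hi = self.band_hz
        if not 0 <= lo < hi:
            raise ValueError("band_hz must satisfy 0 <= low < high")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must be in (0, 1)")
        if not 0 < self.cluster_fdr < 1:
            raise ValueError("cluster_fdr must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.smoothing_target not in ("normalized", "falff"):
            raise ValueError("smoothing_target must be 'normalized' or 'falff'")
        if self.falff_denominator not in ("residual", "raw"):
            raise ValueError("falff_denominator must be 'residual' or 'raw'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)
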