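"""Run configuration: analysis parameters echoed into every output."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml


@dataclass
class RunConfig:
    """Tunable analysis parameters.

    Every output table/file records these verbatim so a run is fully
    described by (config, seed).
    """

    window_length_wavelengths: float = 10.0
    window_overlap: float = 0.5
    n_levels: int = 16
    distances: tuple = (1,)
    range_policy: str = "per-map"
    roi_fraction: float = 2.0 / 3.0
    guard_epsilon_mean: float = 0.5  # dBr
    guard_epsilon_texture: float = 0.05
    lda_eval_mode: str = "loo"
    lda_ridge: float = 1e-6
    seed: int = 0
    output_dir: str = "qustex_out"

    def __post_init__(self) -> None:
        self.distances = tuple(int(d) for d in self.distances)
        if not 0 <= self.window_overlap < 1:
            raise ValueError("window_overlap must lie in [0, 1)")
        if self.lda_eval_mode not in ("loo", "resubstitution"):
            raise ValueError("lda_eval_mode must be 'loo' or 'resubstitution'")

    def as_metadata(self) -> dict:
        d = asdict(self)
        d["distances"] = list(self.distances)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_metadata(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def updated(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
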