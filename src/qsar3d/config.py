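"""Pipeline configuration: one structured file, every stage parameter.

Defaults follow the conventional field-QSAR settings: 2 A grid spacing,
30 kcal/mol CoMFA truncation, CoMSIA attenuation 0.3 with a 1 A all-(+1)
probe, 80%/20% contour contribution levels. Every stochastic step derives
its seed from one master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # inputs
    structures: str = ""
    activities: str = ""
    charge_policy: str = "recompute"
    ic50_unit: str = "uM"
    # alignment
    pattern: str | list[int] | None = None
    template_id: str | None = None
    # fields
    method: str = "comfa"  # comfa | comsia | both
    spacing: float = 2.0
    margin: float = 4.0
    alpha: float = 0.3
    truncation: float = 30.0
    dielectric: str = "distance"
    filter_sigma: dict = field(default_factory=dict)
    scaling: str = "block-standard"
    # PLS
    c_max: int = 10
    onc_threshold: float = 0.10
    region_focusing: bool = False
    focus_power: float = 1.0
    cv_groups: int = 10
    cv_repeats: int = 25
    bootstrap_B: int = 100
    run_group_cv: bool = True
    run_bootstrap: bool = True
    # contours
    favourable_pct: float = 80.0
    unfavourable_pct: float = 20.0
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def model_kwargs(self) -> dict:
        pattern = self.pattern
        if isinstance(pattern, list):
            pattern = tuple(int(i) for i in pattern)
        return dict(method=self.method, pattern=pattern,
                    template_id=self.template_id, spacing=self.spacing,
                    margin=self.margin, alpha=self.alpha,
                    filter_sigma={str(k): float(v)
                                  for k, v in (self.filter_sigma or {}).items()},
                    scaling=self.scaling, c_max=self.c_max,
                    onc_threshold=self.onc_threshold,
                    region_focusing=self.region_focusing,
                    focus_power=self.focus_power, cv_groups=self.cv_groups,
                    cv_repeats=self.cv_repeats, bootstrap_B=self.bootstrap_B,
                    run_group_cv=self.run_group_cv,
                    run_bootstrap=self.run_bootstrap, seed=self.seed)
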