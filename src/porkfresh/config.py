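"""Run configuration: one declarative YAML file covering the study
design, the synthetic generator and the cascade settings.

`RunConfig.from_yaml(RunConfig().to_yaml())` round-trips identically; the
single top-level ``seed`` is authoritative and is pushed into the
generator on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cascade import CascadeConfig
from .design import GeneratorConfig, Signature, StudyDesign, TrendSpec
from .errors import ConfigurationError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.generator.seed != self.seed:
            object.__setattr__(
                self,
                "generator",
                dataclasses.replace(self.generator, seed=self.seed),
            )

    def to_dict(self) -> dict:
        gen = self.generator
        trends = gen.metabolite_trends
        return {
            "seed": int(self.seed),
            "output_dir": self.output_dir,
            "design": {
                "storage_days": list(self.design.storage_days),
                "chem_replicates_per_day": self.design.chem_replicates_per_day,
                "observations_per_replicate": (
                    self.design.observations_per_replicate
                ),
                "animals": self.design.animals,
                "sides": self.design.sides,
            },
            "generator": {
                "metabolite_trends": None
                if trends is None
                else {
                    name: (
                        [t.direction, t.baseline, t.effect]
                        if t.noise_sd is None
                        else [t.direction, t.baseline, t.effect, t.noise_sd]
                    )
                    for name, t in trends.items()
                },
                "metabolite_noise_frac": gen.metabolite_noise_frac,
                "equation_noise_sd": dict(gen.equation_noise_sd),
                "signature_library": [
                    [s.center_nm, s.width_nm, s.variable, s.amplitude]
                    for s in gen.signature_library
                ],
                "scatter_sd": gen.scatter_sd,
                "baseline_slope_sd": gen.baseline_slope_sd,
                "baseline_offset_sd": gen.baseline_offset_sd,
                "sensor_noise_sd": gen.sensor_noise_sd,
                "latent_sd": gen.latent_sd,
                "wavelength_start_nm": gen.wavelength_start_nm,
                "wavelength_end_nm": gen.wavelength_end_nm,
                "n_bands": gen.n_bands,
                "n_pixels": gen.n_pixels,
            },
            "cascade": {
                f.name: (
                    list(v) if isinstance(v := getattr(self.cascade, f.name), tuple) else v
                )
                for f in dataclasses.fields(self.cascade)
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            seed = int(data.get("seed", 0))
            d = data.get("design", {})
            design = StudyDesign(
                storage_days=tuple(d.get("storage_days", (1, 4, 13, 20, 27))),
                chem_replicates_per_day=d.get("chem_replicates_per_day", 5),
                observations_per_replicate=d.get(
                    "observations_per_replicate", 4
                ),
                animals=d.get("animals", 3),
                sides=d.get("sides", 2),
            )
            g = dict(data.get("generator", {}))
            trends = g.pop("metabolite_trends", None)
            if trends is not None:
                trends = {
                    name: TrendSpec(
                        str(v[0]),
                        float(v[1]),
                        float(v[2]),
                        float(v[3]) if len(v) > 3 else None,
                    )
                    for name, v in trends.items()
                }
            sigs = g.pop("signature_library", None)
            kwargs = dict(g)
            if sigs is not None:
                kwargs["signature_library"] = tuple(
                    Signature(float(s[0]), float(s[1]), str(s[2]), float(s[3]))
                    for s in sigs
                )
            generator = GeneratorConfig(
                seed=seed, metabolite_trends=trends, **kwargs
            )
            c = dict(data.get("cascade", {}))
            if "preprocessing_grid" in c:
                c["preprocessing_grid"] = tuple(c["preprocessing_grid"])
            cascade = CascadeConfig(**c)
        except (TypeError, KeyError, IndexError, ValueError) as exc:
            raise ConfigurationError(f"malformed configuration: {exc}") from exc
        return cls(
            seed=seed,
            design=design,
            generator=generator,
            cascade=cascade,
            output_dir=str(data.get("output_dir", "runs")),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigurationError("config file must hold a mapping")
        return cls.from_dict(data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())
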