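"""Run configuration, manifests and reproducible experiment assembly.

A run is described by a small YAML (or JSON) mapping with the keys

    experiment:      pair2d | triangular | von_mises | images
    stimulus:        generator parameters for that experiment
    plasticity:      PlasticityConfig fields (rule, u, tau_w, ...)
    n_presentations: total stimulus presentations
    record_every:    sampling stride of the trajectory
    seed:            master seed (overrides plasticity.rng_seed)
    output_dir:      where products and the manifest are written

Every command echoes the fully resolved configuration, the seed and the
package version into ``manifest.json`` so a run can be reproduced
byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .dynamics import PlasticityConfig, TransferSpec
from .stimuli import (
    ImagePipelineConfig,
    StimulusEnsemble,
    generate_synthetic_images,
    load_images,
    make_image_patches,
    make_pair2d,
    make_triangular,
    make_von_mises,
)

_EXPERIMENTS = ("pair2d", "triangular", "von_mises", "images")


@dataclass
class RunConfig:
    experiment: str = "pair2d"
    stimulus: dict = field(default_factory=dict)
    plasticity: dict = field(default_factory=dict)
    n_presentations: int = 50_000
    record_every: int = 100
    seed: int = 0
    output_dir: str = "wdbcm_out"

    def __post_init__(self):
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {_EXPERIMENTS}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def plasticity_config(self) -> PlasticityConfig:
        params = dict(self.plasticity)
        transfer = params.pop("transfer", None)
        if isinstance(transfer, dict):
            params["transfer"] = TransferSpec(**transfer)
        elif isinstance(transfer, str):
            params["transfer"] = TransferSpec(kind=transfer)
        params.setdefault("rng_seed", self.seed)
        return PlasticityConfig(**params)

    def build_ensemble(self) -> StimulusEnsemble:
        p = dict(self.stimulus)
        if self.experiment == "pair2d":
            return make_pair2d(p.get("phi", 0.4))
        if self.experiment == "triangular":
            return make_triangular(p.get("N", 20), p.get("K", 20), p.get("omega", 0.5))
        if self.experiment == "von_mises":
            return make_von_mises(p.get("N", 20), p.get("K", 20))
        # images
        zero_mean = p.pop("zero_mean", False)
        paths = p.pop("image_files", None)
        n_images = p.pop("n_images", 10)
        image_size = p.pop("image_size", 256)
        cfg = ImagePipelineConfig(
            patch_pixels=p.get("patch_pixels", 400),
            dog_center_width=p.get("dog_center_width", 1.0),
            dog_surround_width=p.get("dog_surround_width", 3.0),
            n_patches=p.get("n_patches", 40_000),
            rng_seed=p.get("rng_seed", self.seed),
        )
        if paths:
            images = load_images(paths)
        else:
            images = generate_synthetic_images(n_images, image_size, seed=self.seed)
        return make_image_patches(images, cfg, zero_mean=zero_mean)


def write_manifest(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "wdbcm_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
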