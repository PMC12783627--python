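"""Run configuration: YAML loading, validation, defaults, snapshots.

Defaults follow the reference training configuration (learning rate 2e-4,
Adam betas 0.5/0.999, 200 epochs with decay at 100, batch 16, pulp weight
0.35, gradient penalty 10, latent dimension 128, dropout 0.3, augmentation
intensity 0.75). Unknown keys are rejected with the offending key path so a
typo never silently falls back to a default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import yaml

from .gan import DiscriminatorSpec, GeneratorSpec
from .phantom import PhantomConfig
from .pulp_loss import PulpLossConfig
from .regularizers import REGULARIZER_NAMES, BilateralConfig
from .segpipe import PipelineConfig
from .training import LossWeights, QualityGateConfig, TrainConfig

__all__ = ["RunConfig", "load_config", "default_config_dict", "save_snapshot"]

_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "runs",
    "phantom": {
        "height": 128, "width": 128, "n_teeth": 4, "lesion_rate": 0.5,
        "boundary_thickness": 2, "noise_sd": 0.02, "bit_depth": 8,
    },
    "pulp": {
        "lambda": 0.35, "sigma": 1.5, "alpha": 0.5, "beta": 0.3,
        "gamma": 0.2, "normalization": "mean_over_pixels",
        "neighborhood": 8, "pair_rule": "and",
        "use_distance_weighting": True, "use_mask": True, "penalty": "l2",
    },
    "bilateral": {"sigma_r": 0.1, "sigma_s": 1.0, "lambda": 0.35,
                  "weighted_difference": False},
    "gan": {
        "latent_dim": 128, "image_size": 128, "output_channels": 3,
        "width_multiplier": 1.0, "identity_skips": False,
        "dropout_rate": 0.3, "base_resolution": 4,
    },
    "training": {
        "batch_size": 16, "learning_rate": 2.0e-4, "beta1": 0.5,
        "beta2": 0.999, "epochs": 200, "decay_epoch": 100,
        "decay_factor": 0.5, "augmentation_intensity": 0.75,
        "adversarial_mode": "bce_gp", "regularizer": "pulp",
        "is_every": 5, "paired": False,
    },
    "weights": {
        "adversarial": 0.4, "pixel": 0.25, "pulp": 0.35,
        "gradient_penalty": 10.0, "feature_matching": 0.0,
        "perceptual": 0.0, "psnr_term": 0.0, "ssim_term": 0.0,
    },
    "gate": {"mode": "percentile_of_real", "tau": 95.0},
    "segpipe": {"patch_size": 256, "overlap": 0.5, "threshold": 0.5,
                "closing_radius": 2, "min_component_px": 16},
    "metrics": {"is_classes": 8},
}


def default_config_dict() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (user or {}).items():
        full = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ValueError(f"unknown configuration key {full!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"{full!r} must be a mapping")
            out[key] = _merge(defaults[key], value, full)
        else:
            if isinstance(defaults[key], bool) and not isinstance(value, bool):
                raise ValueError(f"{full!r} must be a boolean")
            if isinstance(defaults[key], (int, float)) \
                    and not isinstance(value, (int, float)):
                raise ValueError(f"{full!r} must be numeric")
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Resolved, validated configuration for one run."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def phantom_config(self, seed: int | None = None) -> PhantomConfig:
        p = self.data["phantom"]
        return PhantomConfig(seed=self.seed if seed is None else seed, **p)

    def pulp_config(self) -> PulpLossConfig:
        p = dict(self.data["pulp"])
        p["lam"] = p.pop("lambda")
        return PulpLossConfig(**p)

    def bilateral_config(self) -> BilateralConfig:
        b = dict(self.data["bilateral"])
        b["lam"] = b.pop("lambda")
        return BilateralConfig(**b)

    def generator_spec(self) -> GeneratorSpec:
        g = self.data["gan"]
        return GeneratorSpec(
            latent_dim=g["latent_dim"],
            base_resolution=g["base_resolution"],
            output_resolution=g["image_size"],
            output_channels=g["output_channels"],
            width_multiplier=g["width_multiplier"],
            identity_skips=g["identity_skips"],
        )

    def discriminator_spec(self) -> DiscriminatorSpec:
        g = self.data["gan"]
        return DiscriminatorSpec(
            input_resolution=g["image_size"],
            input_channels=g["output_channels"],
            dropout_rate=g["dropout_rate"],
            width_multiplier=g["width_multiplier"],
        )

    def train_config(self) -> TrainConfig:
        t = dict(self.data["training"])
        reg = t.pop("regularizer")
        if reg not in REGULARIZER_NAMES:
            raise ValueError(f"training.regularizer must be one of "
                             f"{REGULARIZER_NAMES}, got {reg!r}")
        return TrainConfig(seed=self.seed,
                           image_size=self.data["gan"]["image_size"],
                           is_classes=self.data["metrics"]["is_classes"], **t)

    @property
    def regularizer(self) -> str:
        return self.data["training"]["regularizer"]

    def loss_weights(self) -> LossWeights:
        return LossWeights(**self.data["weights"])

    def gate_config(self) -> QualityGateConfig:
        return QualityGateConfig(**self.data["gate"])

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(**self.data["segpipe"])

    def validate(self) -> "RunConfig":
        """Instantiate every typed section so invalid values fail loudly."""
        self.phantom_config()
        self.pulp_config()
        self.bilateral_config()
        self.generator_spec()
        self.discriminator_spec()
        self.train_config()
        self.loss_weights()
        self.gate_config()
        self.pipeline_config()
        return self


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the defaults."""
    user: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("configuration root must be a mapping")
    merged = _merge(_DEFAULTS, user)
    if overrides:
        merged = _merge(merged, overrides)
    return RunConfig(merged).validate()


def save_snapshot(config: RunConfig, path) -> None:
    """Write the fully resolved configuration; reloading it reproduces the
    identical resolved config."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.data, fh, sort_keys=True)
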