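"""Configuration schema, profiles and validation.

Two named profiles bundle coherent hyperparameter sets: ``paper`` carries
the published training setup (embedding 100, model dim 200, 4 heads, 6
layers, 64-D latent, T = 500, lr 2e-5, batch 512, 500 epochs) and ``desk``
a scaled-down configuration sized for CPU runs on short synthetic
families.  A JSON document may override any field inside the ``jtae``,
``diffusion`` and ``train`` sections; unknown keys are rejected with a
message listing every violation at once.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .diffusion import DiffusionConfig
from .generate import TrainConfig
from .jtae import JTAEConfig


class ConfigError(ValueError):
    pass


PROFILES: dict[str, dict] = {
    "paper": {
        "jtae": {},          # JTAEConfig defaults are the published values
        "diffusion": {},     # T=500, linear 1e-4..0.02, p_uncond 0.1
        "train": {},         # 500 epochs, batch 512, lr 2e-5
    },
    "desk": {
        "jtae": {"embed_dim": 32, "model_dim": 64, "n_heads": 4, "n_layers": 2,
                 "latent_dim": 16, "decoder_layers": 3, "decoder_channels": 64,
                 "regressor_hidden": 64},
        # beta ramp rescaled by 1000/T so alpha_bar_T is ~0 (the sampler
        # starts from N(0, I); the forward chain must actually reach it)
        "diffusion": {"T": 100, "beta_lo": 1e-3, "beta_hi": 0.2,
                      "base_channels": 32, "n_levels": 3, "cond_dim": 64},
        "train": {"epochs": 60, "batch_size": 128, "lr": 2e-3,
                  "weight_decay": 1e-4, "detach_latents": True,
                  "diffusion_refine_epochs": 40},
    },
}

#: Origin of each non-obvious default, for the provenance report.
PROVENANCE: dict[str, str] = {
    "jtae.embed_dim=100": "published embedding dimension",
    "jtae.model_dim=200": "published transformer hidden dimension",
    "jtae.n_heads=4": "published head count",
    "jtae.n_layers=6": "published layer count",
    "jtae.latent_dim=64": "published default latent dimensionality",
    "jtae.regressor_dropout=0.2": "published regressor dropout",
    "diffusion.T=500": "published diffusion step count",
    "diffusion.kind=linear": "design decision: fixed (not learned) beta ramp",
    "diffusion.p_uncond=0.1": "design decision: standard guidance dropout",
    "train.lr=2e-05": "published cosine-annealed starting rate",
    "train.batch_size=512": "published batch size",
    "train.epochs=500": "published epoch count",
    "profile=desk": "design decision: CPU-scale profile for synthetic families",
}


@dataclass
class RunConfig:
    profile: str = "desk"
    seed: int = 0
    jtae: JTAEConfig = field(default_factory=JTAEConfig)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_bins: int = 8
    log_path: str | None = None

    def provenance(self) -> dict[str, str]:
        return dict(PROVENANCE)


_SECTIONS = {"jtae": JTAEConfig, "diffusion": DiffusionConfig,
             "train": TrainConfig}
_TOP_KEYS = {"profile", "seed", "n_bins", "log_path", *_SECTIONS}


def validate_config(raw: dict | str | Path) -> RunConfig:
    """Validate a JSON document (or dict) into a fully defaulted RunConfig.

    The profile's values seed each section, explicit keys override them,
    and all schema violations are reported together.
    """
    if isinstance(raw, (str, Path)):
        raw = json.loads(Path(raw).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config document must be a JSON object")

    errors: list[str] = []
    profile = raw.get("profile", "desk")
    if profile not in PROFILES:
        errors.append(f"unknown profile {profile!r} (choose from {sorted(PROFILES)})")
        profile = "desk"
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")

    sections: dict[str, object] = {}
    for name, cls in _SECTIONS.items():
        values = dict(PROFILES[profile][name])
        override = raw.get(name, {})
        if not isinstance(override, dict):
            errors.append(f"section {name!r} must be an object")
            override = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for k in override:
            if k not in known:
                errors.append(f"unknown key {name}.{k}")
        values.update({k: v for k, v in override.items() if k in known})
        try:
            sections[name] = cls(**values)
        except (TypeError, ValueError) as exc:
            errors.append(f"section {name!r}: {exc}")
            sections[name] = cls()

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")
        seed = 0
    n_bins = raw.get("n_bins", 8)
    if not isinstance(n_bins, int) or n_bins < 1:
        errors.append("n_bins must be a positive integer")
        n_bins = 8

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(profile=profile, seed=seed, jtae=sections["jtae"],
                     diffusion=sections["diffusion"], train=sections["train"],
                     n_bins=n_bins, log_path=raw.get("log_path"))
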