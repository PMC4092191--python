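"""Named parameter profiles shipped with the package.

A profile is a YAML file with a ``model`` section (fields of
:class:`~epirepair.abm.ModelParams`) and a ``geometry`` section (lattice
rows/cols, default gap length and anchored margin).  The packaged
``calibrated`` profile is tuned so a long-ablation run reproduces the
observed closure kinetics (initial edge speed ≈ 7.4 µm/h) and the
short/long proliferation dichotomy; see ``docs/methods.md``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .abm import ModelParams
from .exceptions import ProfileError

DEFAULT_PROFILE = "calibrated"


def _packaged_profiles():
    return resources.files("epirepair") / "profiles"


def list_profiles() -> list[str]:
    return sorted(
        p.name.removesuffix(".yaml")
        for p in _packaged_profiles().iterdir()
        if p.name.endswith(".yaml")
    )


def load_profile(name_or_path: str = DEFAULT_PROFILE) -> dict:
    """Load a packaged profile by name, or any YAML file by path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        res = _packaged_profiles() / f"{name_or_path}.yaml"
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise ProfileError(
                f"unknown profile {name_or_path!r}; packaged profiles: "
                f"{list_profiles()}"
            ) from None
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "model" not in cfg:
        raise ProfileError(f"profile {name_or_path!r} has no 'model' section")
    cfg.setdefault("geometry", {})
    return cfg


def params_from_profile(
    cfg: dict, seed: int | None = None, **overrides
) -> ModelParams:
    """Build :class:`ModelParams` from a loaded profile plus overrides."""
    fields = dict(cfg["model"])
    fields.update(overrides)
    if seed is not None:
        fields["seed"] = seed
    try:
        return ModelParams(**fields)
    except TypeError as exc:
        raise ProfileError(f"bad model parameter in profile: {exc}") from exc
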