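"""Bundled literature parameter presets (see ``tissues.yaml``)."""

from importlib import resources

import yaml

from ..optical_models import model_from_dict

__all__ = ["load_tissue_presets", "get_model", "get_constant"]

_cache: dict | None = None


def load_tissue_presets() -> dict:
    """Parsed contents of the bundled ``tissues.yaml`` (cached)."""
    global _cache
    if _cache is None:
        text = resources.files(__package__).joinpath("tissues.yaml").read_text()
        _cache = yaml.safe_load(text)
    return _cache


def get_model(name: str):
    """Instantiate a bundled optical model by preset name."""
    models = load_tissue_presets()["models"]
    if name not in models:
        raise KeyError(f"unknown tissue model preset {name!r}; have {sorted(models)}")
    return model_from_dict(models[name])


def get_constant(name: str) -> float:
    return float(load_tissue_presets()["constants"][name])
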