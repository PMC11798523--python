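"""YAML run configuration: priors, MCMC settings, observation handling."""

from __future__ import annotations

import yaml

from .io import DEFAULT_SOURCE_PRECEDENCE
from .model import PriorConfig
from .sampler import DEFAULT_MCMC

__all__ = ["RunConfig", "load_config"]


class RunConfig:
    """Parsed run settings.

    Recognised top-level keys (all optional):

    ``priors``: ``init_sd``, ``sigma_prior`` (halfnormal|flat),
    ``sigma_scale``; ``mcmc``: ``chains``, ``iterations``, ``burnin``,
    ``thin``, ``seed``; ``precedence``: ordered source list;
    ``observation_mask``: list of inclusive ``[first, last]`` year ranges
    whose observations are withheld.
    """

    def __init__(self, raw: dict | None = None):
        raw = raw or {}
        unknown = set(raw) - {"priors", "mcmc", "precedence", "observation_mask"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        self.prior = PriorConfig(**(raw.get("priors") or {}))
        self.mcmc = dict(DEFAULT_MCMC)
        self.mcmc.update(raw.get("mcmc") or {})
        self.precedence = tuple(raw.get("precedence") or DEFAULT_SOURCE_PRECEDENCE)
        mask = raw.get("observation_mask") or []
        self.observation_mask = [(int(a), int(b)) for a, b in mask]


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(raw)
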