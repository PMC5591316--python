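"""Loader for the packaged kinetic fixture schemes (see fixtures/schemes.yaml)."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .simulate import KineticScheme, PhotophysicsParams

__all__ = ["FixtureSpec", "available_fixtures", "load_fixture"]


@dataclass
class FixtureSpec:
    name: str
    description: str
    scheme: KineticScheme
    photo: PhotophysicsParams
    protocol: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return int(self.protocol.get("n_pairs", 500))

    @property
    def n_frames(self) -> int:
        return 2 * self.n_pairs

    @property
    def t_inject(self) -> float:
        return float(self.protocol.get("t_inject", 0.0))

    @property
    def max_events(self):
        return self.protocol.get("max_events", None)


def _raw() -> dict:
    text = resources.files("ribofret.fixtures").joinpath("schemes.yaml").read_text()
    return yaml.safe_load(text)


def available_fixtures() -> list[str]:
    return sorted(_raw())


def load_fixture(name: str) -> FixtureSpec:
    raw = _raw()
    if name not in raw:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(raw)}")
    cfg = raw[name]
    scheme = KineticScheme(
        state_efficiencies={
            s: (v["e57"], v["e35"], v["e37"]) for s, v in cfg["states"].items()
        },
        rates_pre=cfg["rates_pre"],
        rates_post=cfg.get("rates_post"),
        k_on=cfg.get("k_on", 0.0),
        k_off=cfg.get("k_off", 0.0),
        state_dependent_binding=cfg.get("state_dependent_binding"),
    )
    photo = PhotophysicsParams(**cfg.get("photophysics", {}))
    return FixtureSpec(
        name=name,
        description=cfg.get("description", ""),
        scheme=scheme,
        photo=photo,
        protocol=cfg.get("protocol", {}),
    )
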