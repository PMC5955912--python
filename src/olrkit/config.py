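"""Run configuration: YAML files with assay defaults filled in.

An empty config file yields the full default protocol: speeds 0–72 deg/s
in steps of 9, the five contrast labels and five dot radii, 200
bootstrap replicates, alpha 0.05, 100 ms boxcar, 500 ms baseline, OLR
window 1–2 s.  Unknown keys and invalid levels raise
:class:`~olrkit.exceptions.ConfigError` naming the offending key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import design as _design
from .exceptions import ConfigError
from .synth import CohortSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated run configuration with assay defaults."""

    experiment: str = "speed"
    speeds: tuple[float, ...] = _design.SPEEDS_SPEED_EXP
    contrasts: tuple[float, ...] = _design.CONTRAST_LABELS
    dot_radii: tuple[float, ...] = _design.DOT_RADII
    repeats_per_session: int | None = None  # None: the experiment's own plan
    n_sessions: int | None = None
    n_mice: int = 6
    seed: int = 0
    boot: int = 200
    alpha: float = 0.05
    smoothing_ms: float = 100.0
    baseline_ms: float = 500.0
    olr_window_s: tuple[float, float] = (1.0, 2.0)
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def __post_init__(self) -> None:
        if self.experiment not in ("speed", "contrast", "dotsize"):
            raise ConfigError(f"experiment: unknown experiment {self.experiment!r}")
        if any(s < 0 for s in self.speeds):
            raise ConfigError("speeds: speeds must be >= 0")
        if any(not 0 < c <= 1 for c in self.contrasts):
            raise ConfigError("contrasts: must be in (0, 1]")
        if any(r <= 0 for r in self.dot_radii):
            raise ConfigError("dot_radii: must be positive")
        for key in ("repeats_per_session", "n_sessions", "n_mice", "boot"):
            val = getattr(self, key)
            if val is not None and val < 1:
                raise ConfigError(f"{key}: must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha: must be in (0, 1)")
        if not self.olr_window_s[0] < self.olr_window_s[1]:
            raise ConfigError("olr_window_s: start must precede end")

    def resolve_design(self):
        """Experiment design with the config's session-plan overrides applied."""
        import dataclasses as _dc

        from .design import make_design

        design = make_design(self.experiment)
        overrides = {}
        if self.repeats_per_session is not None:
            overrides["repeats_per_session"] = self.repeats_per_session
        if self.n_sessions is not None:
            overrides["n_sessions"] = self.n_sessions
        return _dc.replace(design, **overrides) if overrides else design

    def hash(self) -> str:
        """Stable short hash of the configuration, for run logging."""
        payload = dataclasses.asdict(self)
        payload["cohort"] = dataclasses.asdict(self.cohort)
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_SEQ_KEYS = {"speeds", "contrasts", "dot_radii", "olr_window_s"}


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; missing keys take assay defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in raw.items():
        if key == "cohort":
            if not isinstance(val, dict):
                raise ConfigError("cohort: must be a mapping")
            spec_known = {f.name for f in dataclasses.fields(CohortSpec)}
            bad = set(val) - spec_known
            if bad:
                raise ConfigError(f"cohort: unknown keys: {sorted(bad)}")
            try:
                kwargs["cohort"] = CohortSpec(**val)
            except Exception as exc:
                raise ConfigError(f"cohort: {exc}") from exc
        elif key in _SEQ_KEYS:
            if not isinstance(val, (list, tuple)):
                raise ConfigError(f"{key}: must be a list")
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
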