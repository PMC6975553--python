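"""Run configuration: defaults of every stage and a strict flat-text parser.

The configuration file is plain ``key = value`` text (one pair per line,
``#`` comments allowed).  Unknown keys are errors so that a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    # marker filtering / association
    maf_threshold: float = 0.05
    significance_neglogp: float = 7.0
    alpha: float = 0.05
    n_pcs: int = 3
    # population structure windows
    ld_max_distance: int = 500_000
    window_size: int = 100_000
    window_step: int = 10_000
    # homology filtering
    homology_min_identity: float = 80.0
    homology_min_length: int = 70
    # epistasis search
    mcmc_iterations: int = 1_000_000
    mcmc_burnin: int = 990_000
    posterior_threshold: float = 0.5
    max_block_size: int = 5
    dm_concentration: float = 1.0
    # reproducibility
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < 0.5):
            raise ValueError("maf_threshold must lie in (0, 0.5)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.mcmc_burnin >= self.mcmc_iterations:
            raise ValueError("burn-in must be smaller than iteration count")
        if not (0.0 < self.posterior_threshold < 1.0):
            raise ValueError("posterior_threshold must lie in (0, 1)")
        if self.window_step < 1 or self.window_size < 1:
            raise ValueError("window size/step must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        values: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise KeyError(f"{path}:{lineno}: unknown configuration key {key!r}")
            ftype = fields[key].type
            try:
                if ftype == "int":
                    values[key] = int(value.replace("_", ""))
                elif ftype == "float":
                    values[key] = float(value)
                else:  # pragma: no cover - all current fields are numeric
                    values[key] = value
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse {key}={value!r}") from exc
        return cls(**values)  # type: ignore[arg-type]

    def to_text(self) -> str:
        """Render as the same flat key=value format (config echo for logs)."""
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())
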