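"""Run configuration and logging plumbing."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

logger = logging.getLogger("structloc")

#: Förster distance of the AF488/Cy3NTA donor-acceptor pair (Å).
DEFAULT_FORSTER_RADIUS = 59.0


@dataclass
class RunConfig:
    """Pipeline-wide settings; the seed is recorded in every output artifact."""

    random_seed: int = 0
    angular_step: float = 20.0       # degrees, docking orientation grid
    voxel_size: float = 1.5          # Å
    resolution: float = 6.0          # Å
    forster_radius: float = DEFAULT_FORSTER_RADIUS  # Å
    grid_step_locus: float = 2.0     # Å, trilateration locus grid
    output_dir: str = "."

    def __post_init__(self):
        for name in ("angular_step", "voxel_size", "resolution",
                     "forster_radius", "grid_step_locus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def setup_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
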