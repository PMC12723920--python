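"""Structured run configuration with the reference parameterization."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import constants as C
from .genome import GenomeSpec
from .world import EngineParameters


@dataclass
class RunConfig:
    """Everything a reproducible run needs; defaults are the reference
    parameterization (L = 70, kappa = 3.217 kT, k = 100 kT, N_f = 120,
    OriginRate = 1e-9 / MCS, ramp (0.13, 90 s), v = 2.2 kb/min,
    r_c = 80 nm, th = 50 nm, J_sister = 100 kT, J_f = 0,
    dt = 0.075 ms/MCS)."""

    genome: str = "builtin"
    ipls: str | None = None           # path; None -> synthetic generator
    synthetic_ipls: dict = field(default_factory=dict)
    scenario: str = "interacting"     # interacting | non-interacting
    box_cells: int = C.BOX_EDGE
    kappa: float = C.KAPPA
    k_tether: float = C.K_TETHER
    time_per_mcs_ms: float = C.TIME_PER_MCS_MS
    n_factors: float = C.N_FACTORS
    origin_rate: float = C.ORIGIN_RATE
    ramp_amplitude: float = C.RAMP_AMPLITUDE
    ramp_tau_s: float = C.RAMP_TAU_S
    fork_speed_kb_min: float = C.FORK_SPEED_KB_MIN
    j_sister: float = C.J_SISTER
    th_sister_nm: float = C.TH_SISTER_NM
    j_forks: float = C.J_FORKS
    r_c_nm: float = C.R_CONTACT_NM
    seed: int = 0
    g1_sweeps: int = 20000
    frame_every_mcs: int = 2000
    max_minutes: float = 90.0
    time_rescale: float = 1.0         # >1 speeds replication up (scaled runs)
    out_dir: str = "."

    def __post_init__(self):
        if self.scenario not in ("interacting", "non-interacting"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    # ------------------------------------------------------------------
    def genome_spec(self) -> GenomeSpec:
        if self.genome == "builtin":
            return GenomeSpec.builtin()
        return GenomeSpec.from_tsv(self.genome)

    def engine_parameters(self) -> EngineParameters:
        p = EngineParameters(
            kappa=self.kappa, k_tether=self.k_tether,
            time_per_mcs_ms=self.time_per_mcs_ms,
            n_factors=self.n_factors, origin_rate=self.origin_rate,
            ramp_amplitude=self.ramp_amplitude, ramp_tau_s=self.ramp_tau_s,
            fork_speed_kb_min=self.fork_speed_kb_min,
            j_sister=self.j_sister, th_sister_nm=self.th_sister_nm,
            j_forks=self.j_forks,
            interacting=(self.scenario == "interacting"))
        if self.time_rescale != 1.0:
            p = p.rescaled(self.time_rescale)
        return p

    def manifest(self, **extra) -> dict:
        m = {"config": self.to_dict()}
        m.update(extra)
        return m

    def write_manifest(self, path, **extra) -> None:
        Path(path).write_text(json.dumps(self.manifest(**extra), indent=2,
                                         default=str))
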