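"""Protocol configuration: defaults, validation, file loading.

Field names mirror the simulator's published argument list (sim_name,
cellpop, exp_time, drug, dose, egf, ins, hgf, nrg, pdgf, igf, fgf) plus the
replicate/seed/detector settings the protocol needs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .cellmodel import DEFAULT_CV, DEFAULT_DT


@dataclass
class ProtocolConfig:
    sim_name: str = "sim"
    cellpop: int = 100            # starting cells
    exp_time: float = 72.0        # hours of drug exposure
    drug: str | None = None
    dose: float = 0.0             # uM
    doses: list = field(default_factory=list)   # uM, for dose-response runs
    egf: float = 3.3              # nM (growth media)
    ins: float = 1721.0           # nM (growth media)
    hgf: float = 0.0
    nrg: float = 0.0
    pdgf: float = 0.0
    igf: float = 0.0
    fgf: float = 0.0
    replicates: int = 10
    seed: int = 0
    cv: float = DEFAULT_CV
    dt: float = DEFAULT_DT
    burn_in: float = 48.0
    gen0_duration: float = 48.0
    backend: str = "serial"
    store_trajectories: bool = False
    detector: dict = field(default_factory=dict)  # DetectorConfig overrides

    def __post_init__(self):
        if self.cellpop < 1:
            raise ValueError("cellpop must be >= 1")
        if self.exp_time <= 0:
            raise ValueError("exp_time must be > 0")
        if self.dose < 0 or any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def detector_config(self):
        from .events import DetectorConfig

        return DetectorConfig(**self.detector)

    def stimuli(self, dose=None):
        from .cellmodel import Stimuli

        d = self.dose if dose is None else dose
        return Stimuli(egf=self.egf, ins=self.ins, hgf=self.hgf,
                       nrg=self.nrg, pdgf=self.pdgf, igf=self.igf,
                       fgf=self.fgf, drug=self.drug if d > 0 else None,
                       dose=d if d > 0 else 0.0)

    def dose_list(self):
        doses = list(self.doses) if self.doses else ([self.dose] if self.dose > 0 else [])
        return sorted(set([0.0, *doses]))

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, data):
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path):
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path):
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))
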