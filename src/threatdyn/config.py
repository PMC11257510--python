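"""Run configuration with the paradigm's canonical constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design import BLOCK_LEN_S, PHASIC_DUR_S
from .groupstats import DEFAULT_RSCALE
from .paradigm import N_VOLUMES_DEFAULT, TR_DEFAULT_S

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Canonical constants plus per-stage seeds and paths.

    The defaults reproduce the paradigm's stated constants: TR 1.25 s,
    478 volumes/scan, 6.15-s phasic regressors, 6.25-s convolved blocks,
    FDR q = 0.05, and the conventional Cauchy prior scale sqrt(2)/2 for the
    Bayes factor.
    """

    tr_s: float = TR_DEFAULT_S
    n_volumes: int = N_VOLUMES_DEFAULT
    n_scans: int = 3
    trials_per_cond: int = 6
    phasic_dur_s: float = PHASIC_DUR_S
    block_len_s: float = BLOCK_LEN_S
    fdr_q: float = 0.05
    bf_rscale: float = DEFAULT_RSCALE
    seeds: dict = field(default_factory=lambda: {"design": 1, "bold": 1})
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))
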