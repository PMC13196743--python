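"""Design configuration: enzyme geometry, oligo layout, and annealing
schedule.  Loadable from YAML or JSON."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["Enzyme", "BSAI", "LayoutConfig", "SAParams", "DesignConfig"]


@dataclass(frozen=True)
class Enzyme:
    """Type IIS restriction enzyme descriptor.

    The enzyme recognizes ``recognition`` and cuts outside it: after
    ``spacer_len`` intervening bases the next ``overhang_len`` bases form the
    single-stranded overhang.  BsaI (GGTCTC N1, 4-nt overhang) is the
    default; other Type IIS enzymes plug in via this descriptor.
    """

    name: str = "BsaI"
    recognition: str = "GGTCTC"
    spacer_len: int = 1
    overhang_len: int = 4

    @property
    def recognition_rc(self) -> str:
        from .ligation import revcomp

        return revcomp(self.recognition)


BSAI = Enzyme()


@dataclass
class LayoutConfig:
    """Geometry and budget parameters for one oligo library.

    ``payload`` is the gene-derived span of an oligo after subtracting the
    two primers, two recognition sites and two spacers:
    ``oligo_len - 2*(primer_len + len(recognition) + spacer_len)``.
    With 300-nt oligos and defaults this is 246 nt (~250 bp of coding
    sequence per 300-bp oligo).
    """

    oligo_len: int = 300
    primer_len: int = 20
    gg_budget: int = 50
    n_backbone: int = 2
    budget_includes_backbone: bool = True
    fidelity_includes_backbone: bool = True
    backbone: tuple[str, str] = ("AATG", "TTAG")
    min_fragment_len: int = 20
    max_fragments: int = 15
    max_pools: int = 92
    max_pool_size: int = 70  # cap for single-fragment (junction-free) genes
    fragments_override: int | None = None
    bsai_severity: str = "error"  # "warn" | "error" for internal-site hits
    enzyme: Enzyme = field(default_factory=Enzyme)

    @property
    def overhang_len(self) -> int:
        return self.enzyme.overhang_len

    @property
    def payload(self) -> int:
        return self.oligo_len - 2 * (
            self.primer_len + len(self.enzyme.recognition) + self.enzyme.spacer_len
        )

    def validate(self) -> None:
        if self.payload <= self.overhang_len + self.min_fragment_len:
            raise ValueError(
                f"payload {self.payload} nt leaves no room for fragments "
                f"(need > {self.overhang_len + self.min_fragment_len})"
            )
        if self.n_backbone not in (0, 2):
            raise ValueError("n_backbone must be 0 or 2")
        if self.bsai_severity not in ("warn", "error"):
            raise ValueError("bsai_severity must be 'warn' or 'error'")


@dataclass
class SAParams:
    """Simulated-annealing schedule.

    Defaults follow the published schedule: a geometric ("logarithmic")
    temperature gradient from 5e-3 down to 1e-5 over a few thousand steps,
    repeated from independent seeds and keeping the best run.  Larger
    junction budgets benefit from more steps and restarts (e.g. 25x3000 for
    50-site pools, 50x5000 for 70-site pools).
    """

    t_high: float = 5e-3
    t_low: float = 1e-5
    n_steps: int = 5000
    n_restarts: int = 25
    base_seed: int = 0

    def validate(self) -> None:
        if not (self.t_high > self.t_low > 0):
            raise ValueError("require t_high > t_low > 0")
        if self.n_steps < 1 or self.n_restarts < 1:
            raise ValueError("n_steps and n_restarts must be >= 1")


@dataclass
class DesignConfig:
    """Top-level bundle: layout + annealing, as read from a config file."""

    layout: LayoutConfig = field(default_factory=LayoutConfig)
    sa: SAParams = field(default_factory=SAParams)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        layout_d = dict(d.get("layout", {}))
        enzyme = Enzyme(**layout_d.pop("enzyme", {})) if "enzyme" in layout_d else Enzyme()
        if "backbone" in layout_d:
            layout_d["backbone"] = tuple(layout_d["backbone"])
        layout = LayoutConfig(enzyme=enzyme, **layout_d)
        sa = SAParams(**d.get("sa", {}))
        layout.validate()
        sa.validate()
        return cls(layout=layout, sa=sa)

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return {"layout": asdict(self.layout), "sa": asdict(self.sa)}

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=list))
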