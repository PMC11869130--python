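"""Solvent descriptors used for conditioning and for the property oracle."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SolventInfo", "SolventTable", "DEFAULT_SOLVENTS", "onsager_polarity"]


@dataclass(frozen=True)
class SolventInfo:
    """A solvent: canonical key, relative permittivity and a rough
    hydrophilicity index in [0, 1] (1 = water-like)."""

    solvent_id: str
    dielectric: float
    hydrophilicity: float

    def __post_init__(self) -> None:
        if self.dielectric <= 1:
            raise ValueError("relative permittivity must exceed 1")


def onsager_polarity(dielectric: float) -> float:
    """Onsager reaction-field factor (eps-1)/(eps+2): a bounded, increasing
    function of the permittivity, ~0.3 for toluene and ~0.96 for water."""
    return (dielectric - 1.0) / (dielectric + 2.0)


class SolventTable:
    """Ordered lookup of known solvents by canonical id."""

    def __init__(self, solvents: list[SolventInfo]):
        self.solvents = list(solvents)
        self._by_id = {s.solvent_id: s for s in self.solvents}
        if len(self._by_id) != len(self.solvents):
            raise ValueError("duplicate solvent ids")

    def __contains__(self, solvent_id: str) -> bool:
        return solvent_id in self._by_id

    def __getitem__(self, solvent_id: str) -> SolventInfo:
        return self._by_id[solvent_id]

    def __iter__(self):
        return iter(self.solvents)

    def __len__(self) -> int:
        return len(self.solvents)

    @property
    def ids(self) -> list[str]:
        return [s.solvent_id for s in self.solvents]

    def to_json(self) -> list[dict]:
        return [
            {"solvent_id": s.solvent_id, "dielectric": s.dielectric,
             "hydrophilicity": s.hydrophilicity}
            for s in self.solvents
        ]

    @classmethod
    def from_json(cls, data: list[dict]) -> "SolventTable":
        return cls([SolventInfo(**d) for d in data])


#: The five solvents of the study conditions: water, acetonitrile,
#: dichloromethane, tetrahydrofuran, toluene.
DEFAULT_SOLVENTS = SolventTable(
    [
        SolventInfo("water", 78.36, 1.00),
        SolventInfo("acetonitrile", 37.5, 0.60),
        SolventInfo("dichloromethane", 8.93, 0.25),
        SolventInfo("thf", 7.58, 0.45),
        SolventInfo("toluene", 2.38, 0.00),
    ]
)
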