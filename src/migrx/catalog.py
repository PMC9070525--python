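"""Treatment catalog: the preventative classes, evaluation durations and tariffs.

Ten classes of migraine preventatives are modelled by default.  Each trial of a
class occupies a fixed evaluation period (3 months for every class except
onabotulinumtoxinA, whose response can only be adjudicated after two injection
cycles, i.e. 6 months) and carries a 3-monthly cost under a low and a high
drug-tariff estimate.

The default tariffs shipped here are synthetic placeholders on a plausible
pound-sterling scale; real formulary tariffs are a configuration input and can
be supplied through :meth:`TreatmentCatalog.from_json` /
:meth:`TreatmentCatalog.from_yaml`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = ["Treatment", "TreatmentCatalog", "DEFAULT_CLASSES", "BOTULINUM_TOXIN"]

BOTULINUM_TOXIN = "botulinum_toxin"

#: Canonical class names, ordered by published modelled effect size.
DEFAULT_CLASSES: tuple[str, ...] = (
    BOTULINUM_TOXIN,
    "flunarizine",
    "candesartan",
    "tca",
    "valproate",
    "topiramate",
    "snri",
    "acupuncture",
    "betablockers",
    "serotonergic",
)

# Synthetic placeholder tariffs (pounds per 3-month trial).
_SYNTHETIC_TARIFFS_LOW = {
    BOTULINUM_TOXIN: 700.0,
    "flunarizine": 15.0,
    "candesartan": 8.0,
    "tca": 6.0,
    "valproate": 10.0,
    "topiramate": 12.0,
    "snri": 9.0,
    "acupuncture": 300.0,
    "betablockers": 5.0,
    "serotonergic": 20.0,
}
_SYNTHETIC_TARIFFS_HIGH = {
    BOTULINUM_TOXIN: 1400.0,
    "flunarizine": 40.0,
    "candesartan": 20.0,
    "tca": 15.0,
    "valproate": 25.0,
    "topiramate": 30.0,
    "snri": 22.0,
    "acupuncture": 450.0,
    "betablockers": 12.0,
    "serotonergic": 50.0,
}


@dataclass(frozen=True)
class Treatment:
    """A preventative class with its evaluation duration and tariffs."""

    name: str
    eval_months: float
    tariff_low: float
    tariff_high: float

    def __post_init__(self) -> None:
        if self.eval_months <= 0:
            raise ValueError(f"eval_months must be positive for {self.name!r}")
        if self.tariff_low < 0 or self.tariff_high < 0:
            raise ValueError(f"tariffs must be non-negative for {self.name!r}")


class TreatmentCatalog:
    """Ordered, name-keyed collection of :class:`Treatment` entries."""

    def __init__(self, treatments: Iterable[Treatment]):
        self._by_name: dict[str, Treatment] = {}
        for t in treatments:
            if t.name in self._by_name:
                raise ValueError(f"duplicate treatment class {t.name!r}")
            self._by_name[t.name] = t
        if not self._by_name:
            raise ValueError("catalog must contain at least one treatment")

    # -- container protocol -------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self):
        return iter(self._by_name.values())

    def __getitem__(self, name: str) -> Treatment:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown treatment class {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def eval_months(self, name: str) -> float:
        return self[name].eval_months

    def tariff(self, name: str, level: str = "low") -> float:
        if level not in ("low", "high"):
            raise ValueError("tariff level must be 'low' or 'high'")
        t = self[name]
        return t.tariff_low if level == "low" else t.tariff_high

    def durations(self, sequence: Sequence[str]) -> list[float]:
        """Evaluation months for each class in ``sequence``, in order."""
        return [self.eval_months(name) for name in sequence]

    def subset(self, names: Sequence[str]) -> "TreatmentCatalog":
        return TreatmentCatalog(self[n] for n in names)

    # -- construction and IO ------------------------------------------------
    @classmethod
    def default(cls, classes: Sequence[str] | None = None) -> "TreatmentCatalog":
        """The ten default classes (6-month evaluation for onabotulinumtoxinA,
        3 months otherwise) with synthetic placeholder tariffs."""
        names = DEFAULT_CLASSES if classes is None else tuple(classes)
        treatments = []
        for name in names:
            if name not in _SYNTHETIC_TARIFFS_LOW:
                raise KeyError(f"unknown treatment class {name!r}")
            treatments.append(
                Treatment(
                    name=name,
                    eval_months=6.0 if name == BOTULINUM_TOXIN else 3.0,
                    tariff_low=_SYNTHETIC_TARIFFS_LOW[name],
                    tariff_high=_SYNTHETIC_TARIFFS_HIGH[name],
                )
            )
        return cls(treatments)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "TreatmentCatalog":
        return cls(
            Treatment(
                name=r["name"],
                eval_months=float(r["eval_months"]),
                tariff_low=float(r["tariff_low"]),
                tariff_high=float(r["tariff_high"]),
            )
            for r in records
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TreatmentCatalog":
        return cls.from_records(json.loads(Path(path).read_text()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TreatmentCatalog":
        return cls.from_records(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        records = [
            {
                "name": t.name,
                "eval_months": t.eval_months,
                "tariff_low": t.tariff_low,
                "tariff_high": t.tariff_high,
            }
            for t in self
        ]
        Path(path).write_text(json.dumps(records, indent=2))
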