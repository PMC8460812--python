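"""Cell-population models and clonal colony sampling.

The population model captures the two competing explanations for a plasmid
read-depth ratio below one per chromosome:

* **polyploidy** — every cell carries the plasmid (carriage c = 1) but the
  chromosome is present at P > 1 copies per cell, so a single-copy plasmid
  shows a depth ratio of 1/P;
* **unstable inheritance** — the chromosome is at one copy (P = 1) but only a
  fraction c < 1 of cells still carry the plasmid, so bulk depth is diluted
  to c.

Colonies founded by single cells disambiguate the two: under instability a
colony panel shows frequent plasmid losses (each founder lacks a plasmid with
probability 1 − c), under polyploidy losses are rare background events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .replicons import GenomeModel

__all__ = [
    "PopulationModel",
    "ColonyFounder",
    "ColonyPanel",
    "sample_founder",
    "sample_panel",
]


@dataclass
class PopulationModel:
    """A cell population over a multi-replicon genome.

    Parameters
    ----------
    genome:
        The replicon collection (sequences required only for read simulation).
    ploidy:
        Chromosome copies per cell, P > 0.  A population constant: the model
        describes medium-dependent ploidy, not cell-to-cell variance.
    plasmid_copy:
        Copies per *carrying* cell for each plasmid.  Fractional values (e.g.
        2.5) are average copy numbers over carrying cells and act as abundance
        weights at read-simulation time; they are never rounded to per-cell
        integers.
    carriage:
        Fraction of cells carrying each plasmid, in [0, 1]; defaults to 1.0
        (stable inheritance).
    """

    genome: GenomeModel
    ploidy: float = 1.0
    plasmid_copy: dict[str, float] = field(default_factory=dict)
    carriage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValueError("ploidy must be > 0")
        plasmid_names = [p.name for p in self.genome.plasmids]
        for key in list(self.plasmid_copy) + list(self.carriage):
            if key not in plasmid_names:
                raise ValueError(f"unknown plasmid {key!r}")
        self.plasmid_copy = {
            name: float(self.plasmid_copy.get(name, 1.0)) for name in plasmid_names
        }
        self.carriage = {
            name: float(self.carriage.get(name, 1.0)) for name in plasmid_names
        }
        for name, cn in self.plasmid_copy.items():
            if cn < 0:
                raise ValueError(f"plasmid_copy[{name!r}] must be >= 0")
        for name, c in self.carriage.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"carriage[{name!r}] must be in [0, 1]")

    def effective_copies(self, name: str) -> float:
        """Population-average copies per cell of a replicon.

        The chromosome contributes ``ploidy``; a plasmid contributes
        ``carriage × copy_number``.
        """
        rep = self.genome[name]
        if rep.role == "chromosome":
            return self.ploidy
        return self.carriage[name] * self.plasmid_copy[name]

    # -- JSON config round trip (genome travels separately, e.g. as FASTA) --

    def to_json(self, path) -> None:
        payload = {
            "ploidy": self.ploidy,
            "plasmid_copy": self.plasmid_copy,
            "carriage": self.carriage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, genome: GenomeModel, path) -> "PopulationModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genome=genome,
            ploidy=payload.get("ploidy", 1.0),
            plasmid_copy=payload.get("plasmid_copy", {}),
            carriage=payload.get("carriage", {}),
        )


@dataclass
class ColonyFounder:
    """The single cell founding a clonal colony: plasmid presence plus ploidy."""

    presence: dict[str, bool]
    ploidy: float

    def plasmids_lost(self) -> list[str]:
        return [name for name, present in self.presence.items() if not present]


@dataclass
class ColonyPanel:
    """n clonal colonies scored for presence/absence of every plasmid."""

    n: int
    losses: dict[str, int]
    founders: Optional[list[ColonyFounder]] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("panel must contain at least one colony")
        for name, k in self.losses.items():
            if not 0 <= k <= self.n:
                raise ValueError(f"losses[{name!r}]={k} outside [0, {self.n}]")

    @property
    def colonies_with_any_loss(self) -> Optional[int]:
        if self.founders is None:
            return None
        return sum(1 for f in self.founders if f.plasmids_lost())

    def to_frame(self) -> pd.DataFrame:
        """Colony × plasmid boolean presence matrix (requires founders)."""
        if self.founders is None:
            raise ValueError("panel has no per-colony founders")
        rows = [
            {"colony": i, **{k: int(v) for k, v in f.presence.items()}}
            for i, f in enumerate(self.founders)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ColonyPanel":
        df = pd.read_csv(path, sep="\t", comment="#")
        plasmids = [c for c in df.columns if c != "colony"]
        founders = [
            ColonyFounder(
                presence={p: bool(row[p]) for p in plasmids}, ploidy=float("nan")
            )
            for _, row in df.iterrows()
        ]
        losses = {p: int((df[p] == 0).sum()) for p in plasmids}
        return cls(n=len(df), losses=losses, founders=founders)


def sample_founder(
    model: PopulationModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ColonyFounder:
    """Draw one colony founder: each plasmid present with its carriage fraction.

    Presence events are independent across plasmids — the null model; possible
    plasmid codependence is available through ``sample_panel``'s
    ``shared_loss_prob`` hook but defaults off.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    presence = {
        name: bool(rng.random() < c) for name, c in model.carriage.items()
    }
    return ColonyFounder(presence=presence, ploidy=model.ploidy)


def sample_panel(
    model: PopulationModel,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    shared_loss_prob: float = 0.0,
) -> ColonyPanel:
    """Sample n independent colony founders and tally per-plasmid losses.

    ``shared_loss_prob`` is a correlation hook: with that probability a colony
    suffers a shared loss event in which every plasmid with carriage < 1 is
    lost together (coupled segregation failure).  Default 0 keeps plasmid
    losses independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= shared_loss_prob <= 1.0:
        raise ValueError("shared_loss_prob must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    founders = []
    for _ in range(n):
        if shared_loss_prob and rng.random() < shared_loss_prob:
            presence = {name: c >= 1.0 for name, c in model.carriage.items()}
            founders.append(ColonyFounder(presence=presence, ploidy=model.ploidy))
        else:
            founders.append(sample_founder(model, rng=rng))
    losses = {
        name: sum(not f.presence[name] for f in founders)
        for name in model.carriage
    }
    return ColonyPanel(n=n, losses=losses, founders=founders)
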