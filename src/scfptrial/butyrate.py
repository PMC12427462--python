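"""Rule-based screening of butyrate-producing species from genome annotations.

Butyryl-CoA can be reached by three routes — from acetyl-CoA, from
glutarate, or from 4-aminobutyrate — and a genome carrying a complete
route is taken as evidence that the species can produce butyrate. For the
acetyl-CoA route the two terminal reductases (EC 1.3.1.86 crotonyl-CoA
reductase and EC 1.3.1.44 trans-2-enoyl-CoA reductase) are decisive; for
the glutarate and 4-aminobutyrate routes every listed enzyme is required.
A species is called a likely producer if ANY of its genomes satisfies any
route. The terminal butyrate-forming genes buk (K00929), ptb (K00634) and
atoD (K01034) are not part of species classification; they name the KO
subset used for differential abundance of functional potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import AbundanceTable, GenomeAnnotation, ValidationError

__all__ = [
    "PathwayRoute",
    "ButyratePathwayCatalog",
    "ButyrateCall",
    "classify_genome",
    "classify_species",
    "producer_subset",
    "calls_to_frame",
]

ROUTE_NAMES = ("acetyl_coa", "glutarate", "aminobutyrate")


@dataclass(frozen=True)
class PathwayRoute:
    name: str
    required_ecs: tuple[str, ...]
    rule: str  # "terminal_pair" or "all_genes"


@dataclass(frozen=True)
class ButyratePathwayCatalog:
    """The enzyme catalog of the three butyrate routes, as data.

    ``terminal_pair`` routes are decided on their last two enzymes;
    ``all_genes`` routes require the full list.
    """

    routes: tuple[PathwayRoute, ...] = (
        PathwayRoute(
            name="acetyl_coa",
            required_ecs=("2.3.1.9", "2.8.3.5", "1.1.1.35", "1.1.1.36",
                          "1.1.1.157", "1.3.1.86", "1.3.1.44"),
            rule="terminal_pair",
        ),
        PathwayRoute(
            name="glutarate",
            required_ecs=("2.8.3.12", "4.1.1.70"),
            rule="all_genes",
        ),
        PathwayRoute(
            name="aminobutyrate",
            required_ecs=("1.1.1.6", "4.2.1.120", "5.3.3.3"),
            rule="all_genes",
        ),
    )
    terminal_kos: dict = field(default_factory=lambda: {
        "buk": "K00929", "ptb": "K00634", "atoD": "K01034"})

    def route(self, name: str) -> PathwayRoute:
        for r in self.routes:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def terminal_pair(self) -> tuple[str, str]:
        """Terminal enzymes of a terminal_pair route (its last two ECs)."""
        r = next(r for r in self.routes if r.rule == "terminal_pair")
        return r.required_ecs[-2:]

    def terminal_ko_ids(self) -> frozenset[str]:
        return frozenset(self.terminal_kos.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(r.name, ec, r.rule) for r in self.routes for ec in r.required_ecs]
        return pd.DataFrame(rows, columns=["route", "ec", "rule"])


@dataclass(frozen=True)
class ButyrateCall:
    """Per-species classification outcome."""

    species_id: str
    route_flags: dict
    likelihood: str  # "high" or "none"
    supporting_genomes: frozenset[str]

    def __post_init__(self):
        high = any(self.route_flags.values())
        if (self.likelihood == "high") != high:
            raise ValidationError("likelihood inconsistent with route flags")
        if high != bool(self.supporting_genomes):
            raise ValidationError("supporting genomes inconsistent with likelihood")


def classify_genome(annotation: GenomeAnnotation,
                    catalog: ButyratePathwayCatalog | None = None,
                    acetyl_rule: str = "both") -> dict[str, bool]:
    """Route flags for one genome.

    ``acetyl_rule`` controls the terminal-pair reading: ``both`` (default,
    strict — both terminal reductases present) or ``either`` (the two ECs
    treated as biochemical alternatives).
    """
    catalog = catalog or ButyratePathwayCatalog()
    if acetyl_rule not in ("both", "either"):
        raise ValueError(f"acetyl_rule must be 'both' or 'either', got {acetyl_rule!r}")
    ecs = annotation.ec_numbers
    flags = {}
    for route in catalog.routes:
        if route.rule == "terminal_pair":
            pair = route.required_ecs[-2:]
            if acetyl_rule == "both":
                flags[route.name] = set(pair) <= ecs
            else:
                flags[route.name] = any(e in ecs for e in pair)
        else:
            flags[route.name] = set(route.required_ecs) <= ecs
    return flags


def classify_species(annotations: list[GenomeAnnotation],
                     catalog: ButyratePathwayCatalog | None = None,
                     acetyl_rule: str = "both") -> list[ButyrateCall]:
    """Per-species OR over genome route flags; any route => likely producer."""
    catalog = catalog or ButyratePathwayCatalog()
    by_species: dict[str, list[GenomeAnnotation]] = {}
    for ann in annotations:
        by_species.setdefault(ann.species_id, []).append(ann)
    calls = []
    for species_id in sorted(by_species):
        flags = {r.name: False for r in catalog.routes}
        supporting: set[str] = set()
        for ann in by_species[species_id]:
            gflags = classify_genome(ann, catalog, acetyl_rule)
            if any(gflags.values()):
                supporting.add(ann.genome_id)
            for name, val in gflags.items():
                flags[name] = flags[name] or val
        high = any(flags.values())
        calls.append(ButyrateCall(
            species_id=species_id, route_flags=flags,
            likelihood="high" if high else "none",
            supporting_genomes=frozenset(supporting)))
    return calls


def producer_subset(table: AbundanceTable, calls: list[ButyrateCall]) -> AbundanceTable:
    """Restrict a species table to likely butyrate producers.

    Species without a call are treated as non-producers.
    """
    high = {c.species_id for c in calls if c.likelihood == "high"}
    keep = [t for t in table.taxon_ids if t in high]
    if not keep:
        raise ValidationError("no butyrate producers present in the table")
    return AbundanceTable(table.counts.loc[:, keep], rank=table.rank)


def calls_to_frame(calls: list[ButyrateCall]) -> pd.DataFrame:
    """Flatten calls to a writable result table."""
    rows = []
    for c in sorted(calls, key=lambda c: c.species_id):
        rows.append({
            "species_id": c.species_id,
            **{name: bool(flag) for name, flag in sorted(c.route_flags.items())},
            "likelihood": c.likelihood,
            "supporting_genomes": ",".join(sorted(c.supporting_genomes)),
        })
    return pd.DataFrame(rows)
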