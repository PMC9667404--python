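"""Declarative multi-population demographic models and the model zoo.

A :class:`ModelSpec` describes a species tree with haploid effective sizes,
divergence events (child lineages move into the parent backward in time),
piecewise-constant size changes, time-windowed directional migration and
pulse admixture.  Times are generations before present; all sizes are
haploid.  Migration arrows are **forward-time** ``source -> dest`` with rate
``m`` = per-lineage per-generation probability; the simulator moves lineages
``dest -> source`` backward in time.

The model zoo covers the standard three-population isolation-with-migration
families for a (REC, (ENA, EUR)) species tree: REC diverges first, then the
other lineage (FLEX, the ancestor of ENA and EUR) splits into the two
allopatric populations.  Eight gene-flow events are enumerated: six among
the three current populations and two between REC and the FLEX ancestor.
Ancestral events come in three timing modes: ``continuous`` (the whole
coexistence window), ``early`` (starting at the species divergence, ending
at a free stop time) and ``secondary_contact`` (starting at a free contact
time after an isolation period, ending at the next divergence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import yaml

DEFAULT_MUTATION_RATE = 2.8e-8  # per site per generation


@dataclass
class Population:
    name: str
    ne: float
    sample_size: int = 0


@dataclass
class Divergence:
    """At ``time`` (backward), lineages in ``child`` move into ``parent``."""

    time: float
    child: str
    parent: str


@dataclass
class SizeChange:
    """``population`` has size ``ne`` for times >= ``time``."""

    time: float
    population: str
    ne: float


@dataclass
class MigrationWindow:
    """Forward-time migration ``source -> dest`` active on [start, end)."""

    source: str
    dest: str
    rate: float
    start: float = 0.0
    end: float = math.inf


@dataclass
class AdmixturePulse:
    """At ``time``, ``dest`` receives a fraction ``proportion`` from ``source``
    (forward time).  Backward, each dest lineage moves to source w.p.
    ``proportion``."""

    time: float
    source: str
    dest: str
    proportion: float


@dataclass
class ModelSpec:
    populations: list[Population]
    divergences: list[Divergence] = field(default_factory=list)
    size_changes: list[SizeChange] = field(default_factory=list)
    migrations: list[MigrationWindow] = field(default_factory=list)
    pulses: list[AdmixturePulse] = field(default_factory=list)
    mutation_rate: float = DEFAULT_MUTATION_RATE
    locus_length: int = 90

    # -- structure helpers ------------------------------------------------

    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def pop(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"unknown population {name!r}")

    def sampled_pops(self) -> list[str]:
        return [p.name for p in self.populations if p.sample_size > 0]

    def sample_sizes(self) -> dict[str, int]:
        return {p.name: p.sample_size for p in self.populations if p.sample_size > 0}

    def divergence_time(self, pop: str) -> float:
        """Time at which ``pop`` merges into its parent (inf for the root)."""
        for d in self.divergences:
            if d.child == pop:
                return d.time
        return math.inf

    def occupied_start(self, pop: str) -> float:
        """Earliest (backward) time lineages can be present in ``pop``.

        0 for sampled populations; for purely ancestral populations, the
        earliest join time of a child.
        """
        if self.pop(pop).sample_size > 0:
            return 0.0
        joins = [d.time for d in self.divergences if d.parent == pop]
        if not joins:
            return 0.0
        return min(joins)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "populations": [
                {"name": p.name, "ne": p.ne, "sample_size": p.sample_size}
                for p in self.populations
            ],
            "divergences": [
                {"time": d.time, "child": d.child, "parent": d.parent}
                for d in self.divergences
            ],
            "size_changes": [
                {"time": s.time, "population": s.population, "ne": s.ne}
                for s in self.size_changes
            ],
            "migrations": [
                {
                    "source": m.source,
                    "dest": m.dest,
                    "rate": m.rate,
                    "start": m.start,
                    "end": m.end,
                }
                for m in self.migrations
            ],
            "pulses": [
                {
                    "time": p.time,
                    "source": p.source,
                    "dest": p.dest,
                    "proportion": p.proportion,
                }
                for p in self.pulses
            ],
            "mutation_rate": self.mutation_rate,
            "locus_length": self.locus_length,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        return cls(
            populations=[Population(**p) for p in data.get("populations", [])],
            divergences=[Divergence(**d) for d in data.get("divergences", [])],
            size_changes=[SizeChange(**s) for s in data.get("size_changes", [])],
            migrations=[MigrationWindow(**m) for m in data.get("migrations", [])],
            pulses=[AdmixturePulse(**p) for p in data.get("pulses", [])],
            mutation_rate=data.get("mutation_rate", DEFAULT_MUTATION_RATE),
            locus_length=data.get("locus_length", 90),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelSpec":
        try:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        except (OSError, TypeError):
            data = yaml.safe_load(source)
        return cls.from_dict(data)


def validate_model(spec: ModelSpec) -> list[str]:
    """Diagnostics for a ModelSpec; an empty list means valid.

    Checks parameter bounds, the tree structure of divergence events,
    migration-window / pulse consistency with the epochs in which both
    populations exist, and overall connectivity (a common ancestor must be
    reachable).
    """
    issues: list[str] = []
    names = spec.pop_names()
    if len(set(names)) != len(names):
        issues.append("duplicate population names")
    for p in spec.populations:
        if p.ne <= 0:
            issues.append(f"population {p.name!r} has non-positive Ne")
        if p.sample_size < 0:
            issues.append(f"population {p.name!r} has negative sample size")

    children = [d.child for d in spec.divergences]
    if len(set(children)) != len(children):
        issues.append("a population is the child of more than one divergence")
    for d in spec.divergences:
        if d.child not in names or d.parent not in names:
            issues.append(f"divergence references unknown population: {d}")
            continue
        if d.time < 0:
            issues.append(f"divergence at negative time: {d}")
        parent_end = spec.divergence_time(d.parent)
        if parent_end <= d.time:
            issues.append(
                f"parent {d.parent!r} merges at {parent_end} before or when "
                f"child {d.child!r} joins at {d.time}"
            )
    # cycle check by walking child -> parent
    parent_of = {d.child: d.parent for d in spec.divergences}
    for start in names:
        seen = set()
        cur = start
        while cur in parent_of:
            if cur in seen:
                issues.append(f"divergence events contain a cycle through {cur!r}")
                break
            seen.add(cur)
            cur = parent_of[cur]

    def alive(pop: str) -> tuple[float, float]:
        return spec.occupied_start(pop), spec.divergence_time(pop)

    for m in spec.migrations:
        if not 0 <= m.rate < 1:
            issues.append(f"migration rate out of [0, 1): {m}")
        if not m.start < m.end:
            issues.append(f"migration window empty or inverted: {m}")
        for pop in (m.source, m.dest):
            if pop not in names:
                issues.append(f"migration references unknown population {pop!r}")
                continue
            lo, hi = alive(pop)
            if m.start < lo - 1e-9 or m.end > hi + 1e-9:
                issues.append(
                    f"migration window [{m.start}, {m.end}) outside the epoch "
                    f"[{lo}, {hi}) in which {pop!r} exists"
                )
    for pu in spec.pulses:
        if not 0 <= pu.proportion <= 1:
            issues.append(f"pulse proportion outside [0, 1]: {pu}")
        for pop in (pu.source, pu.dest):
            if pop not in names:
                issues.append(f"pulse references unknown population {pop!r}")
                continue
            lo, hi = alive(pop)
            if pu.time < lo - 1e-9 or pu.time > hi + 1e-9:
                issues.append(
                    f"pulse at {pu.time} outside the epoch [{lo}, {hi}) in "
                    f"which {pop!r} exists"
                )

    # connectivity: all populations must be able to reach a common ancestor
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        if a in parent and b in parent:
            parent[find(a)] = find(b)

    for d in spec.divergences:
        union(d.child, d.parent)
    for m in spec.migrations:
        union(m.source, m.dest)
    for pu in spec.pulses:
        union(pu.source, pu.dest)
    roots = {find(n) for n in names}
    if len(roots) > 1:
        issues.append(
            "populations are not all connected by divergence or migration; "
            "a common ancestor is unreachable"
        )
    return issues


# ---------------------------------------------------------------------------
# model zoo
# ---------------------------------------------------------------------------

#: The eight enumerated gene-flow events (forward-time ``SOURCE>DEST``):
#: six among the current populations, two between REC and the FLEX ancestor.
GENE_FLOW_EVENTS: tuple[str, ...] = (
    "ENA>EUR",
    "EUR>ENA",
    "ENA>REC",
    "REC>ENA",
    "EUR>REC",
    "REC>EUR",
    "REC>FLEX",
    "FLEX>REC",
)

ANCESTRAL_EVENTS = ("REC>FLEX", "FLEX>REC")

TIMING_MODES = ("continuous", "early", "secondary_contact")

DEFAULT_BOUNDS = {
    "ne": (10.0, 1e5),
    "time": (100.0, 5e4),
    "rate": (1e-6, 3e-2),
    "fraction": (0.02, 0.98),
}


@dataclass
class ModelBuilder:
    """A named demographic-model family with free parameters.

    ``build(params)`` maps a complete parameter dict to a ModelSpec;
    ``bounds`` give the search range per free parameter.  ``k`` (the free
    parameter count used by AIC) is ``len(bounds)``.
    """

    name: str
    bounds: dict[str, tuple[float, float]]
    build: Callable[[dict], ModelSpec]
    events: tuple[str, ...] = ()
    timing: str = "continuous"

    @property
    def k(self) -> int:
        return len(self.bounds)

    @property
    def param_names(self) -> list[str]:
        return list(self.bounds)


def make_model(
    events: Sequence[str],
    params: dict[str, float],
    timing: str = "continuous",
    sample_sizes: dict[str, int] | None = None,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    locus_length: int = 90,
) -> ModelSpec:
    """Build a three-population zoo ModelSpec from gene-flow events.

    ``params`` must provide ``N_REC, N_ENA, N_EUR, N_FLEX, N_ANC, T_FLEX,
    DT_SPEC``, a rate ``M_<EVENT>`` per event, and — when ``timing`` is not
    ``continuous`` and an ancestral event is present — a window fraction
    ``F_TIMING`` in (0, 1).  The species divergence time is
    ``T_SPEC = T_FLEX + DT_SPEC`` so the tree is valid for any positive
    values.
    """
    unknown = set(events) - set(GENE_FLOW_EVENTS)
    if unknown:
        raise ValueError(f"unknown gene-flow events {sorted(unknown)}")
    if timing not in TIMING_MODES:
        raise ValueError(f"unknown timing mode {timing!r}")
    sizes = sample_sizes or {}
    t_flex = float(params["T_FLEX"])
    t_spec = t_flex + float(params["DT_SPEC"])
    pops = [
        Population("REC", float(params["N_REC"]), sizes.get("REC", 0)),
        Population("ENA", float(params["N_ENA"]), sizes.get("ENA", 0)),
        Population("EUR", float(params["N_EUR"]), sizes.get("EUR", 0)),
        Population("FLEX", float(params["N_FLEX"]), 0),
        Population("ANC", float(params["N_ANC"]), 0),
    ]
    divs = [
        Divergence(t_flex, "ENA", "FLEX"),
        Divergence(t_flex, "EUR", "FLEX"),
        Divergence(t_spec, "FLEX", "ANC"),
        Divergence(t_spec, "REC", "ANC"),
    ]
    migrations = []
    for ev in events:
        source, dest = ev.split(">")
        rate = float(params[f"M_{source}_{dest}"])
        if ev in ANCESTRAL_EVENTS:
            if timing == "continuous":
                start, end = t_flex, t_spec
            else:
                frac = float(params["F_TIMING"])
                t_mid = t_flex + frac * (t_spec - t_flex)
                if timing == "secondary_contact":
                    # isolation right after the species split; flow resumes
                    # at the contact time and lasts until the next divergence
                    start, end = t_flex, t_mid
                else:  # early: flow right after the split, stops later
                    start, end = t_mid, t_spec
        else:
            start, end = 0.0, t_flex
        migrations.append(MigrationWindow(source, dest, rate, start, end))
    return ModelSpec(
        populations=pops,
        divergences=divs,
        migrations=migrations,
        mutation_rate=mutation_rate,
        locus_length=locus_length,
    )


def _zoo_builder(
    name: str,
    events: tuple[str, ...],
    timing: str,
    sample_sizes: dict[str, int],
    mutation_rate: float,
    locus_length: int,
    bounds_overrides: dict | None = None,
) -> ModelBuilder:
    b = dict(DEFAULT_BOUNDS)
    if bounds_overrides:
        b.update(bounds_overrides)
    bounds: dict[str, tuple[float, float]] = {
        "N_REC": b["ne"],
        "N_ENA": b["ne"],
        "N_EUR": b["ne"],
        "N_FLEX": b["ne"],
        "N_ANC": b["ne"],
        "T_FLEX": b["time"],
        "DT_SPEC": b["time"],
    }
    for ev in events:
        source, dest = ev.split(">")
        bounds[f"M_{source}_{dest}"] = b["rate"]
    needs_timing = timing != "continuous" and any(
        ev in ANCESTRAL_EVENTS for ev in events
    )
    if needs_timing:
        bounds["F_TIMING"] = b["fraction"]

    def build(params: dict) -> ModelSpec:
        return make_model(
            events,
            params,
            timing=timing,
            sample_sizes=sample_sizes,
            mutation_rate=mutation_rate,
            locus_length=locus_length,
        )

    return ModelBuilder(name, bounds, build, events=events, timing=timing)


def model_zoo(
    sample_sizes: dict[str, int] | None = None,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    locus_length: int = 90,
    bounds_overrides: dict | None = None,
) -> dict[str, ModelBuilder]:
    """Named model builders for the three-population gene-flow families.

    Provides: ``no_migration``; ``full_migration`` (all eight events);
    ``current_pops_only`` (six events); the eight leave-one-out variants
    ``drop_<EVENT>``; ``model10`` (ENA>EUR, ENA>REC, REC>FLEX); and the
    ``early`` / ``secondary_contact`` timing variants of the ancestral event
    for model10 and full_migration.
    """
    sizes = sample_sizes or {"REC": 8, "ENA": 16, "EUR": 11}
    current = tuple(e for e in GENE_FLOW_EVENTS if e not in ANCESTRAL_EVENTS)
    model10_events = ("ENA>EUR", "ENA>REC", "REC>FLEX")

    def mk(name, events, timing="continuous"):
        return _zoo_builder(
            name, tuple(events), timing, sizes, mutation_rate, locus_length,
            bounds_overrides,
        )

    zoo = {
        "no_migration": mk("no_migration", ()),
        "full_migration": mk("full_migration", GENE_FLOW_EVENTS),
        "full_migration_early": mk("full_migration_early", GENE_FLOW_EVENTS, "early"),
        "full_migration_secondary": mk(
            "full_migration_secondary", GENE_FLOW_EVENTS, "secondary_contact"
        ),
        "current_pops_only": mk("current_pops_only", current),
        "model10": mk("model10", model10_events),
        "model10_early": mk("model10_early", model10_events, "early"),
        "model10_secondary": mk(
            "model10_secondary", model10_events, "secondary_contact"
        ),
    }
    for ev in GENE_FLOW_EVENTS:
        kept = tuple(e for e in GENE_FLOW_EVENTS if e != ev)
        zoo[f"drop_{ev.replace('>', '_to_')}"] = mk(
            f"drop_{ev.replace('>', '_to_')}", kept
        )
    return zoo


def two_population_im(
    sample_sizes: dict[str, int],
    direction: tuple[str, str] | None = ("A", "B"),
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    locus_length: int = 90,
    bounds_overrides: dict | None = None,
    bidirectional: bool = False,
) -> ModelBuilder:
    """Two-population isolation-with-migration family.

    Populations ``A`` and ``B`` split from ancestor ``ANC`` at ``T``.  The
    one-way family has forward migration ``direction[0] -> direction[1]`` at
    free rate ``M`` on [0, T); ``bidirectional=True`` frees both rates
    (``M_A_B``, ``M_B_A``) instead.  Free parameters: sizes ``N_A, N_B``,
    time ``T`` and the rate(s); the ancestral size is tied to ``N_A`` to
    keep the family small at desk scale.
    """
    b = dict(DEFAULT_BOUNDS)
    if bounds_overrides:
        b.update(bounds_overrides)
    bounds = {"N_A": b["ne"], "N_B": b["ne"], "T": b["time"]}
    if bidirectional:
        pairs = [("A", "B", "M_A_B"), ("B", "A", "M_B_A")]
        name = "im_bidirectional"
        for _, _, key in pairs:
            bounds[key] = b["rate"]
    else:
        src, dst = direction
        pairs = [(src, dst, "M")]
        name = f"im_{src}_to_{dst}"
        bounds["M"] = b["rate"]

    def build(params: dict) -> ModelSpec:
        t = float(params["T"])
        return ModelSpec(
            populations=[
                Population("A", float(params["N_A"]), sample_sizes.get("A", 0)),
                Population("B", float(params["N_B"]), sample_sizes.get("B", 0)),
                Population("ANC", float(params["N_A"]), 0),
            ],
            divergences=[Divergence(t, "A", "ANC"), Divergence(t, "B", "ANC")],
            migrations=[
                MigrationWindow(src, dst, float(params[key]), 0.0, t)
                for src, dst, key in pairs
            ],
            mutation_rate=mutation_rate,
            locus_length=locus_length,
        )

    return ModelBuilder(name, bounds, build)


def single_population(
    n_samples: int,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    locus_length: int = 90,
    ne_bounds: tuple[float, float] | None = None,
) -> ModelBuilder:
    """Constant-size single-population family with free ``NE``."""
    bounds = {"NE": ne_bounds or DEFAULT_BOUNDS["ne"]}

    def build(params: dict) -> ModelSpec:
        return ModelSpec(
            populations=[Population("POP", float(params["NE"]), n_samples)],
            mutation_rate=mutation_rate,
            locus_length=locus_length,
        )

    return ModelBuilder("single_population", bounds, build)
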