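"""Network assembly by repeated colonization and extinction.

Assembly starts from an empty network.  Every ``event_interval``
timesteps a colonization event introduces three candidate plants and
three candidate pollinators at the extinction-threshold abundance.  A
colonizer is a specialist (one randomly chosen partner) with the
configured guild-specific probability, otherwise a generalist whose
degree is drawn uniformly between two and the current size of the
opposite guild.  Between events the population dynamics run and species
falling to or below the extinction threshold are removed.  A colonizer
that survives longer than ``establishment_horizon`` timesteps counts as
established.

Within an event plants are introduced before pollinators so that
pollinators (including the very first cohort into an empty network) can
attach to them; a colonizer facing an empty opposite guild is introduced
unlinked and flagged, and typically perishes unless same-event
pollinators link to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .community import Community
from .dynamics import integrate
from .network import BinaryNetwork
from .parameters import (
    Moments,
    ParamDistributions,
    PlantParams,
    PollinatorParams,
    default_distributions,
)

__all__ = [
    "AssemblyConfig",
    "SpeciesRecord",
    "EventSnapshot",
    "AssemblyResult",
    "sample_colonizer",
    "attach_colonizer",
    "run_assembly",
    "run_grid",
    "grid_seeds",
]

PLANT = "plant"
POLLINATOR = "pollinator"
SPECIALIST = "specialist"
GENERALIST = "generalist"


@dataclass(frozen=True)
class AssemblyConfig:
    """Configuration of one assembly simulation."""

    p_spec_plant: float = 0.5
    p_spec_poll: float = 0.5
    n_events: int = 50
    event_interval: float = 2000.0
    colonizers_per_event: int = 3
    establishment_horizon: float = 4000.0
    extinction_threshold: float = 0.05
    adaptive: bool = True
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("p_spec_plant", "p_spec_poll"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.event_interval <= 0 or self.establishment_horizon <= 0:
            raise ValueError("event_interval and establishment_horizon must be positive")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction_threshold must be positive")

    @property
    def total_time(self) -> float:
        return self.n_events * self.event_interval


@dataclass
class SpeciesRecord:
    """Biography of one attempted colonizer."""

    sid: str
    guild: str
    niche_type: str  # at arrival; immutable
    arrival_time: float
    arrival_event: int
    links_at_arrival: list
    attachment_failed: bool = False
    established: bool | None = None  # None = censored (arrived too late)
    extinction_time: float | None = None

    @property
    def lifetime(self) -> float | None:
        if self.extinction_time is None:
            return None
        return self.extinction_time - self.arrival_time


@dataclass
class EventSnapshot:
    """Network state at one event: right after introductions (``arrival``)
    and after integration plus extinction processing (``post``)."""

    event: int
    arrival: BinaryNetwork
    post: BinaryNetwork


@dataclass
class AssemblyResult:
    config: AssemblyConfig
    records: list  # SpeciesRecord, in arrival order
    snapshots: list  # EventSnapshot per event
    final: Community
    diagnostics: dict = field(default_factory=dict)

    def records_of(self, guild: str) -> list:
        return [r for r in self.records if r.guild == guild]

    def counts(self) -> dict:
        out = {}
        for guild in (PLANT, POLLINATOR):
            recs = self.records_of(guild)
            out[guild] = {
                "introduced": len(recs),
                "established": sum(1 for r in recs if r.established),
                "extinct": sum(1 for r in recs if r.extinction_time is not None),
                "final_richness": len(recs)
                - sum(1 for r in recs if r.extinction_time is not None),
            }
        return out


# -------------------------------------------------------------------- sampling


def sample_colonizer(
    guild: str,
    p_spec: float,
    rng: np.random.Generator,
    distributions: ParamDistributions,
) -> tuple[str, PlantParams | PollinatorParams]:
    """Draw a colonizer's niche type and demographic parameters."""
    niche = SPECIALIST if rng.random() < p_spec else GENERALIST
    if guild == PLANT:
        params = distributions.sample_plant(rng)
    elif guild == POLLINATOR:
        params = distributions.sample_pollinator(rng)
    else:
        raise ValueError(f"unknown guild {guild!r}")
    return niche, params


def attach_colonizer(
    n_opposite: int, niche_type: str, rng: np.random.Generator
) -> list[int]:
    """Choose partner indices in the opposite guild for a colonizer.

    Specialists get exactly one partner, uniformly at random; generalists
    get ``d`` partners with ``d`` uniform on ``{2, ..., n_opposite}``
    (clamped to the feasible maximum in tiny networks).  Returns an empty
    list when the opposite guild is empty — the attachment failed.
    """
    if n_opposite == 0:
        return []
    if niche_type == SPECIALIST:
        d = 1
    else:
        d = int(rng.integers(2, n_opposite + 1)) if n_opposite >= 2 else n_opposite
    return list(rng.choice(n_opposite, size=d, replace=False))


# -------------------------------------------------------------------- assembly


def _snapshot(comm: Community, time: float) -> BinaryNetwork:
    return BinaryNetwork(
        plant_ids=list(comm.plant_ids),
        poll_ids=list(comm.poll_ids),
        adjacency=comm.adjacency.copy(),
        time=time,
        P=comm.P.copy(),
        A=comm.A.copy(),
        alpha=comm.alpha.copy(),
    )


def run_assembly(
    config: AssemblyConfig,
    distributions: ParamDistributions | None = None,
) -> AssemblyResult:
    """Run one full assembly simulation; deterministic given the seed."""
    dists = distributions or default_distributions()
    if not config.adaptive:
        # fixed foragers: the adaptive-foraging rate plays no role, encode G=0
        dists = ParamDistributions(
            plant=dict(dists.plant),
            pollinator={**dists.pollinator, "G": Moments(0.0, 0.0)},
        )
    rng = np.random.default_rng(config.seed)
    comm = Community.empty()
    records: list[SpeciesRecord] = []
    snapshots: list[EventSnapshot] = []
    extinction_times: dict[str, float] = {}
    counters = {PLANT: 0, POLLINATOR: 0}
    diagnostics: dict = {"failed_attachments": 0}
    thr = config.extinction_threshold

    for k in range(config.n_events):
        t_k = k * config.event_interval
        # plants first so this event's pollinators can attach to them
        for guild, p_spec in ((PLANT, config.p_spec_plant), (POLLINATOR, config.p_spec_poll)):
            for _ in range(config.colonizers_per_event):
                niche, params = sample_colonizer(guild, p_spec, rng, dists)
                counters[guild] += 1
                if guild == PLANT:
                    sid = f"P{counters[guild]:04d}"
                    partners = attach_colonizer(comm.n_polls, niche, rng)
                    partner_ids = [comm.poll_ids[j] for j in partners]
                    comm.add_plant(sid, params, thr, partners)
                else:
                    sid = f"A{counters[guild]:04d}"
                    partners = attach_colonizer(comm.n_plants, niche, rng)
                    partner_ids = [comm.plant_ids[i] for i in partners]
                    comm.add_pollinator(sid, params, thr, partners)
                if not partners:
                    diagnostics["failed_attachments"] += 1
                records.append(
                    SpeciesRecord(
                        sid=sid,
                        guild=guild,
                        niche_type=niche,
                        arrival_time=t_k,
                        arrival_event=k,
                        links_at_arrival=partner_ids,
                        attachment_failed=not partners,
                    )
                )
        if not config.adaptive:
            comm.set_uniform_efforts()
        arrival = _snapshot(comm, t_k)
        log = integrate(
            comm,
            config.event_interval,
            adaptive=config.adaptive,
            threshold=thr,
            t0=t_k,
            rtol=config.rtol,
            atol=config.atol,
        )
        for sid, t_ext in log:
            extinction_times[sid] = t_ext
        snapshots.append(
            EventSnapshot(event=k, arrival=arrival, post=_snapshot(comm, t_k + config.event_interval))
        )

    t_end = config.total_time
    for rec in records:
        rec.extinction_time = extinction_times.get(rec.sid)
        if rec.extinction_time is not None:
            rec.established = rec.lifetime > config.establishment_horizon
        elif t_end - rec.arrival_time > config.establishment_horizon:
            rec.established = True
        else:
            rec.established = None  # still alive but arrived too late to assess
    return AssemblyResult(
        config=config,
        records=records,
        snapshots=snapshots,
        final=comm,
        diagnostics=diagnostics,
    )


# ------------------------------------------------------------------------ grid


def grid_seeds(base_seed: int, n: int) -> list[int]:
    """Reproducible per-cell seeds derived from a base seed."""
    children = np.random.SeedSequence(base_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_grid(
    base_config: AssemblyConfig,
    p_values: list[float] | None = None,
    distributions: ParamDistributions | None = None,
    progress: bool = False,
) -> dict[tuple[float, float], AssemblyResult]:
    """One assembly per (p_spec_plant, p_spec_poll) cell of a probability
    grid; the default grid is the 11 x 11 design over {0, 0.1, ..., 1}.
    Per-cell seeds derive from the base config's seed, so results do not
    depend on execution order."""
    if p_values is None:
        p_values = [round(0.1 * i, 1) for i in range(11)]
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise ValueError("specialism probabilities must lie in [0, 1]")
    seeds = grid_seeds(base_config.seed, len(p_values) ** 2)
    out: dict[tuple[float, float], AssemblyResult] = {}
    idx = 0
    for pp in p_values:
        for pa in p_values:
            cfg = replace(base_config, p_spec_plant=pp, p_spec_poll=pa, seed=seeds[idx])
            out[(pp, pa)] = run_assembly(cfg, distributions)
            if progress:
                c = out[(pp, pa)].counts()
                print(
                    f"  grid cell ({pp:.1f}, {pa:.1f}): "
                    f"{c[PLANT]['final_richness']} plants, "
                    f"{c[POLLINATOR]['final_richness']} pollinators"
                )
            idx += 1
    return out
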