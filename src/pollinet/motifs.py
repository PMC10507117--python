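"""Intra-guild indirect-interaction motif groups of colonizing species.

Two species of the same guild interact indirectly when they share at
least one direct mutualistic partner (a path of length two); longer
paths are not considered.  Each focal colonizer falls into exactly one
of four motif groups at any evaluation time, determined by its *current*
degree and the current degrees of its intra-guild indirect partners:

* ``SPEC_SPEC`` — specialist focal (degree 1) with at least one
  specialist indirect partner;
* ``SPEC_GEN``  — specialist focal, only generalist indirect partners;
* ``GEN_SPEC``  — generalist focal (degree >= 2), at least one
  specialist indirect partner;
* ``GEN_GEN``   — generalist focal, only generalist indirect partners.

A focal whose partners host no other same-guild species has no indirect
interactions (``NO_INDIRECT``) and is excluded from motif statistics, as
are the first nine attempted colonizers of each guild (the network is
too small to analyze while they arrive).

Motif-group *transformations* between evaluation times reveal indirect
demographic events: ``SPEC_SPEC -> SPEC_GEN`` or ``GEN_SPEC -> GEN_GEN``
means every indirect specialist disappeared (specialist exclusion),
while ``SPEC_GEN -> SPEC_SPEC`` or ``GEN_GEN -> GEN_SPEC`` means a
subsequent specialist colonizer established on a shared partner.
Transformations caused by the focal species itself changing degree
(opposite-guild turnover) are flagged separately and do not count toward
either headline event.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import AssemblyResult, SpeciesRecord
from .network import BinaryNetwork

__all__ = [
    "MotifGroup",
    "MotifTrajectory",
    "indirect_partners",
    "classify",
    "classify_at_arrival",
    "evaluate_trajectory",
    "analyze_assembly",
    "summarize",
    "modal_motifs",
]

FIRST_EXCLUDED = 9  # first attempted colonizers per guild left out of motif stats


class MotifGroup(enum.Enum):
    SPEC_SPEC = "Spec-Spec"
    SPEC_GEN = "Spec-Gen"
    GEN_SPEC = "Gen-Spec"
    GEN_GEN = "Gen-Gen"
    NO_INDIRECT = "No-Indirect"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CORE_GROUPS = (
    MotifGroup.SPEC_SPEC,
    MotifGroup.SPEC_GEN,
    MotifGroup.GEN_SPEC,
    MotifGroup.GEN_GEN,
)


def _focal_row_or_col(net: BinaryNetwork, focal):
    if focal in net._plant_index:
        return "plant", net._plant_index[focal]
    if focal in net._poll_index:
        return "pollinator", net._poll_index[focal]
    raise KeyError(f"species {focal!r} not present in network")


def indirect_partners(net: BinaryNetwork, focal) -> set:
    """Same-guild species sharing at least one direct partner with ``focal``."""
    guild, idx = _focal_row_or_col(net, focal)
    M = net.adjacency
    if guild == "plant":
        partners = M[idx]  # pollinators visited
        share = (M[:, partners]).any(axis=1)
        ids = net.plant_ids
    else:
        partners = M[:, idx]
        share = (M[partners, :]).any(axis=0)
        ids = net.poll_ids
    out = {ids[k] for k in np.nonzero(share)[0]}
    out.discard(focal)
    return out


def classify(net: BinaryNetwork, focal) -> MotifGroup:
    """Motif group of ``focal`` from current degrees.

    Raises ``ValueError`` for a degree-zero focal (an extinct-in-waiting
    species carries no interactions to classify).
    """
    guild, idx = _focal_row_or_col(net, focal)
    M = net.adjacency
    if guild == "plant":
        deg = int(M[idx].sum())
        partner_deg = M.sum(axis=1)  # plant degrees
        partners = M[idx]
        share = M[:, partners].any(axis=1)
    else:
        deg = int(M[:, idx].sum())
        partner_deg = M.sum(axis=0)
        partners = M[:, idx]
        share = M[partners, :].any(axis=0)
    if deg == 0:
        raise ValueError(f"focal species {focal!r} has degree 0")
    share = share.copy()
    share[idx] = False
    if not share.any():
        return MotifGroup.NO_INDIRECT
    any_spec = bool((partner_deg[share] == 1).any())
    if deg == 1:
        return MotifGroup.SPEC_SPEC if any_spec else MotifGroup.SPEC_GEN
    return MotifGroup.GEN_SPEC if any_spec else MotifGroup.GEN_GEN


@dataclass
class MotifTrajectory:
    """Motif classifications of one focal colonizer at three times:
    arrival, one event interval later (after the extinctions it caused),
    and two intervals later (after the subsequent colonization event)."""

    sid: str
    group_at_arrival: MotifGroup | None
    group_post_extinction: MotifGroup | None
    group_post_subsequent: MotifGroup | None
    specialist_exclusion_detected: bool = False
    subsequent_specialist_establishment_detected: bool = False
    focal_type_changed: bool = False  # opposite-guild-driven, reported separately
    truncated: bool = False  # focal extinct/unlinked at a later timepoint
    incomplete: bool = False  # simulation ended before the third timepoint


def _classify_or_none(net: BinaryNetwork, focal) -> MotifGroup | None:
    if focal not in net:
        return None
    try:
        return classify(net, focal)
    except ValueError:
        return None  # degree 0: effectively gone from the web


def classify_at_arrival(net: BinaryNetwork, record: SpeciesRecord) -> MotifGroup | None:
    """Arrival classification with the focal's links fixed to those it was
    introduced with.

    Colonizers of an event are introduced together (plants first), so in
    the post-introduction snapshot a plant colonizer may already carry
    extra links from same-event pollinators; the focal's own niche at the
    moment of arrival is its introduced link set.
    """
    if record.sid not in net or not record.links_at_arrival:
        return None
    guild, idx = _focal_row_or_col(net, record.sid)
    M = net.adjacency.copy()
    if guild == "plant":
        M[idx, :] = False
        cols = [net._poll_index[p] for p in record.links_at_arrival if p in net._poll_index]
        M[idx, cols] = True
    else:
        M[:, idx] = False
        rows = [net._plant_index[p] for p in record.links_at_arrival if p in net._plant_index]
        M[rows, idx] = True
    patched = BinaryNetwork(
        plant_ids=net.plant_ids, poll_ids=net.poll_ids, adjacency=M, time=net.time
    )
    return _classify_or_none(patched, record.sid)


_FOCAL_SPEC = {MotifGroup.SPEC_SPEC, MotifGroup.SPEC_GEN}


def _same_focal_type(a: MotifGroup, b: MotifGroup) -> bool:
    return (a in _FOCAL_SPEC) == (b in _FOCAL_SPEC)


def _group_with_frozen_prefix(
    net: BinaryNetwork, focal, focal_is_spec: bool
) -> MotifGroup | None:
    """Re-evaluate only the indirect-partner side of a focal's motif.

    Focal-niche changes driven by opposite-guild turnover (a specialist
    gaining partners from later colonizers, a generalist losing them to
    extinctions) are not tracked as motif transformations, so the focal's
    specialist/generalist identity stays frozen at its arrival value;
    only whether any current intra-guild indirect partner is a specialist
    is re-evaluated.
    """
    if focal not in net:
        return None
    guild, idx = _focal_row_or_col(net, focal)
    M = net.adjacency
    if guild == "plant":
        if not M[idx].any():
            return None
        partner_deg = M.sum(axis=1)
        share = M[:, M[idx]].any(axis=1)
    else:
        if not M[:, idx].any():
            return None
        partner_deg = M.sum(axis=0)
        share = M[M[:, idx], :].any(axis=0)
    share = share.copy()
    share[idx] = False
    if not share.any():
        return MotifGroup.NO_INDIRECT
    any_spec = bool((partner_deg[share] == 1).any())
    if focal_is_spec:
        return MotifGroup.SPEC_SPEC if any_spec else MotifGroup.SPEC_GEN
    return MotifGroup.GEN_SPEC if any_spec else MotifGroup.GEN_GEN


def evaluate_trajectory(
    snapshots: list, record: SpeciesRecord
) -> MotifTrajectory:
    """Build the three-timepoint motif trajectory of one colonizer.

    ``snapshots`` is the per-event list from an :class:`AssemblyResult`;
    the arrival classification uses the network right after the focal's
    cohort was introduced (with the focal's links as introduced), and the
    two later ones use the post-extinction networks one and two events
    later with the focal's niche class frozen at arrival.
    """
    k = record.arrival_event
    if k >= len(snapshots):
        raise ValueError("missing snapshot for arrival event")
    g1 = classify_at_arrival(snapshots[k].arrival, record)
    g2 = g3 = None
    incomplete = k + 1 >= len(snapshots)
    focal_changed = False
    if g1 is not None and g1 is not MotifGroup.NO_INDIRECT:
        is_spec = g1 in _FOCAL_SPEC
        g2 = _group_with_frozen_prefix(snapshots[k].post, record.sid, is_spec)
        if not incomplete:
            g3 = _group_with_frozen_prefix(snapshots[k + 1].post, record.sid, is_spec)
        # current-degree class drifting from the arrival class is an
        # opposite-guild-driven change, reported but not a transformation
        cur = _classify_or_none(snapshots[k].post, record.sid)
        if cur is not None and cur in CORE_GROUPS:
            focal_changed = (cur in _FOCAL_SPEC) != is_spec
    traj = MotifTrajectory(
        sid=record.sid,
        group_at_arrival=g1,
        group_post_extinction=g2,
        group_post_subsequent=g3,
        incomplete=incomplete,
        truncated=(g2 is None) or (g3 is None and not incomplete),
        focal_type_changed=focal_changed,
    )
    traj.specialist_exclusion_detected = (g1, g2) in {
        (MotifGroup.SPEC_SPEC, MotifGroup.SPEC_GEN),
        (MotifGroup.GEN_SPEC, MotifGroup.GEN_GEN),
    }
    traj.subsequent_specialist_establishment_detected = (g2, g3) in {
        (MotifGroup.SPEC_GEN, MotifGroup.SPEC_SPEC),
        (MotifGroup.GEN_GEN, MotifGroup.GEN_SPEC),
    }
    return traj


# ---------------------------------------------------------------- aggregation


def analyze_assembly(result: AssemblyResult) -> dict[str, MotifTrajectory]:
    """Motif trajectories for every attempted colonizer of one assembly.

    Established colonizers get the full three-point trajectory;
    non-established ones still carry their arrival classification, which
    feeds the attempted-colonizer counts.
    """
    out: dict[str, MotifTrajectory] = {}
    for rec in result.records:
        traj = evaluate_trajectory(result.snapshots, rec)
        if not rec.established:
            # transformations are only meaningful for established colonizers
            traj.group_post_extinction = None
            traj.group_post_subsequent = None
            traj.specialist_exclusion_detected = False
            traj.subsequent_specialist_establishment_detected = False
            traj.truncated = False
        out[rec.sid] = traj
    return out


def _eligible(records: list[SpeciesRecord]) -> list[SpeciesRecord]:
    """Drop the first nine attempted colonizers of each guild (arrival order)."""
    out = []
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.guild] = seen.get(rec.guild, 0) + 1
        if seen[rec.guild] > FIRST_EXCLUDED:
            out.append(rec)
    return out


def summarize(
    results: list[AssemblyResult] | AssemblyResult,
    trajectories: list[dict] | None = None,
) -> pd.DataFrame:
    """Pooled motif-group statistics across one or more assemblies.

    Returns a tidy frame with one row per (guild, motif group):
    attempted and established counts classified at arrival, the
    establishment rate, counts of established colonizers occupying the
    group after the extinction phase and after the subsequent
    colonization event, and the relative frequency of the latter.
    ``NO_INDIRECT`` colonizers and the first nine attempted per guild of
    each simulation are excluded.
    """
    if isinstance(results, AssemblyResult):
        results = [results]
    if trajectories is None:
        trajectories = [analyze_assembly(r) for r in results]
    rows = []
    for guild in ("plant", "pollinator"):
        tally = {
            g: dict.fromkeys(
                ("attempted", "established", "post_extinction", "post_subsequent"), 0
            )
            for g in CORE_GROUPS
        }
        excluded = 0
        for res, trajs in zip(results, trajectories):
            for rec in _eligible(res.records_of(guild)):
                traj = trajs.get(rec.sid)
                if traj is None:
                    continue
                g1 = traj.group_at_arrival
                if g1 is None or g1 is MotifGroup.NO_INDIRECT:
                    excluded += 1
                    continue
                tally[g1]["attempted"] += 1
                if rec.established:
                    tally[g1]["established"] += 1
                    if traj.group_post_extinction in CORE_GROUPS:
                        tally[traj.group_post_extinction]["post_extinction"] += 1
                    if traj.group_post_subsequent in CORE_GROUPS:
                        tally[traj.group_post_subsequent]["post_subsequent"] += 1
        total_sub = sum(t["post_subsequent"] for t in tally.values())
        for g in CORE_GROUPS:
            t = tally[g]
            rows.append(
                {
                    "guild": guild,
                    "motif_group": g.value,
                    "attempted": t["attempted"],
                    "established": t["established"],
                    "establishment_rate": (
                        t["established"] / t["attempted"] if t["attempted"] else 0.0
                    ),
                    "post_extinction": t["post_extinction"],
                    "post_subsequent": t["post_subsequent"],
                    "freq_after_subsequent": (
                        t["post_subsequent"] / total_sub if total_sub else 0.0
                    ),
                    "excluded_no_indirect": excluded,
                }
            )
    return pd.DataFrame(rows)


def modal_motifs(summary: pd.DataFrame) -> dict[str, str]:
    """Most frequent final motif group (after the subsequent colonization
    event) per guild."""
    out = {}
    for guild, sub in summary.groupby("guild"):
        out[guild] = sub.loc[sub["post_subsequent"].idxmax(), "motif_group"]
    return out
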