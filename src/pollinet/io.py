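"""Configuration files, run-directory serialization and manifests.

A run directory holds everything needed to re-analyze a simulation
without re-running the dynamics:

* ``config.yaml``       — the assembly configuration (and, optionally,
  overridden parameter distributions),
* ``records.csv``       — one row per attempted colonizer,
* ``snapshots/``        — two CSV edge-lists per event (``*_arrival`` just
  after introductions, ``*_post`` after extinction processing), each with
  node rows carrying abundances and edge rows carrying foraging efforts,
* ``manifest.json``     — config hash, seed, package version, output
  listing and wall time.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import AssemblyConfig, AssemblyResult, EventSnapshot, SpeciesRecord
from .network import BinaryNetwork
from .parameters import ParamDistributions, default_distributions

__all__ = [
    "load_config",
    "dump_config",
    "config_hash",
    "write_snapshot",
    "read_snapshot",
    "save_run",
    "load_run",
    "write_manifest",
]

_CONFIG_FIELDS = {f.name for f in fields(AssemblyConfig)}


def load_config(path) -> tuple[AssemblyConfig, ParamDistributions]:
    """Read a YAML config; unknown keys are rejected, missing keys take
    defaults (50 events of 2000 timesteps, threshold 0.01, ...)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    dist_raw = raw.pop("param_distributions", None)
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        cfg = AssemblyConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc
    dists = (
        ParamDistributions.from_dict(dist_raw) if dist_raw else default_distributions()
    )
    return cfg, dists


def dump_config(
    cfg: AssemblyConfig,
    path,
    distributions: ParamDistributions | None = None,
) -> None:
    doc = asdict(cfg)
    if distributions is not None:
        doc["param_distributions"] = distributions.to_dict()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def config_hash(cfg: AssemblyConfig, distributions: ParamDistributions | None = None) -> str:
    """Hash of the canonicalized config; stable under key reordering."""
    doc = asdict(cfg)
    if distributions is not None:
        doc["param_distributions"] = distributions.to_dict()
    blob = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ------------------------------------------------------------------ snapshots


def write_snapshot(net: BinaryNetwork, path) -> None:
    """Serialize one snapshot as a CSV with node and edge rows."""
    rows = []
    for i, sid in enumerate(net.plant_ids):
        ab = float(net.P[i]) if net.P is not None else np.nan
        rows.append(("node", "plant", sid, "", repr(ab), ""))
    for j, sid in enumerate(net.poll_ids):
        ab = float(net.A[j]) if net.A is not None else np.nan
        rows.append(("node", "pollinator", sid, "", repr(ab), ""))
    li, lj = np.nonzero(net.adjacency)
    for i, j in zip(li, lj):
        al = float(net.alpha[i, j]) if net.alpha is not None else np.nan
        rows.append(("edge", "", net.plant_ids[i], net.poll_ids[j], "", repr(al)))
    df = pd.DataFrame(
        rows, columns=["record", "guild", "id", "partner", "abundance", "alpha"]
    )
    df.insert(0, "time", "" if net.time is None else repr(float(net.time)))
    df.to_csv(path, index=False)


def read_snapshot(path) -> BinaryNetwork:
    df = pd.read_csv(
        path,
        dtype={"id": str, "partner": str, "guild": str},
        float_precision="round_trip",
    )
    nodes = df[df["record"] == "node"]
    edges = df[df["record"] == "edge"]
    plants = nodes[nodes["guild"] == "plant"]
    polls = nodes[nodes["guild"] == "pollinator"]
    plant_ids = list(plants["id"])
    poll_ids = list(polls["id"])
    pi = {s: i for i, s in enumerate(plant_ids)}
    ai = {s: j for j, s in enumerate(poll_ids)}
    adj = np.zeros((len(plant_ids), len(poll_ids)), dtype=bool)
    alpha = np.zeros_like(adj, dtype=float)
    for _, row in edges.iterrows():
        i, j = pi[row["id"]], ai[row["partner"]]
        adj[i, j] = True
        alpha[i, j] = float(row["alpha"])
    t = df["time"].iloc[0] if len(df) else np.nan
    return BinaryNetwork(
        plant_ids=plant_ids,
        poll_ids=poll_ids,
        adjacency=adj,
        time=None if pd.isna(t) else float(t),
        P=plants["abundance"].astype(float).to_numpy(),
        A=polls["abundance"].astype(float).to_numpy(),
        alpha=alpha,
    )


# ----------------------------------------------------------------------- runs

_REC_COLS = [
    "sid",
    "guild",
    "niche_type",
    "arrival_time",
    "arrival_event",
    "links_at_arrival",
    "attachment_failed",
    "established",
    "extinction_time",
]


def _records_frame(records: list[SpeciesRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in _REC_COLS}
        d["links_at_arrival"] = ";".join(d["links_at_arrival"])
        rows.append(d)
    return pd.DataFrame(rows, columns=_REC_COLS)


def _records_from_frame(df: pd.DataFrame) -> list[SpeciesRecord]:
    out = []
    for _, row in df.iterrows():
        est = row["established"]
        out.append(
            SpeciesRecord(
                sid=str(row["sid"]),
                guild=str(row["guild"]),
                niche_type=str(row["niche_type"]),
                arrival_time=float(row["arrival_time"]),
                arrival_event=int(row["arrival_event"]),
                links_at_arrival=(
                    str(row["links_at_arrival"]).split(";")
                    if isinstance(row["links_at_arrival"], str) and row["links_at_arrival"]
                    else []
                ),
                attachment_failed=bool(row["attachment_failed"]),
                established=None if pd.isna(est) else bool(est),
                extinction_time=(
                    None if pd.isna(row["extinction_time"]) else float(row["extinction_time"])
                ),
            )
        )
    return out


def save_run(
    result: AssemblyResult,
    run_dir,
    distributions: ParamDistributions | None = None,
    wall_time: float | None = None,
) -> Path:
    """Write a complete run directory (config, records, snapshots, manifest)."""
    run_dir = Path(run_dir)
    snap_dir = run_dir / "snapshots"
    snap_dir.mkdir(parents=True, exist_ok=True)
    dump_config(result.config, run_dir / "config.yaml", distributions)
    _records_frame(result.records).to_csv(run_dir / "records.csv", index=False)
    outputs = ["config.yaml", "records.csv"]
    for snap in result.snapshots:
        for stage in ("arrival", "post"):
            name = f"snapshots/event_{snap.event:03d}_{stage}.csv"
            write_snapshot(getattr(snap, stage), run_dir / name)
            outputs.append(name)
    write_manifest(
        run_dir,
        result.config,
        outputs,
        distributions=distributions,
        wall_time=wall_time,
    )
    return run_dir


def write_manifest(
    run_dir,
    cfg: AssemblyConfig,
    outputs: list[str],
    distributions: ParamDistributions | None = None,
    wall_time: float | None = None,
) -> None:
    run_dir = Path(run_dir)
    manifest = {
        "config_hash": config_hash(cfg, distributions),
        "seed": cfg.seed,
        "version": __version__,
        "outputs": sorted(outputs),
        "wall_time_s": wall_time,
        "created_unix": _time.time(),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    missing = [o for o in outputs if not (run_dir / o).exists()]
    if missing:
        raise FileNotFoundError(f"manifest lists missing outputs: {missing}")


def load_run(run_dir) -> AssemblyResult:
    """Rebuild an :class:`AssemblyResult` (minus the final dynamical
    state) from a saved run directory, for motif/metric re-analysis."""
    run_dir = Path(run_dir)
    cfg, _ = load_config(run_dir / "config.yaml")
    records = _records_from_frame(pd.read_csv(run_dir / "records.csv"))
    snaps = []
    k = 0
    while (run_dir / f"snapshots/event_{k:03d}_arrival.csv").exists():
        snaps.append(
            EventSnapshot(
                event=k,
                arrival=read_snapshot(run_dir / f"snapshots/event_{k:03d}_arrival.csv"),
                post=read_snapshot(run_dir / f"snapshots/event_{k:03d}_post.csv"),
            )
        )
        k += 1
    return AssemblyResult(
        config=cfg, records=records, snapshots=snaps, final=None, diagnostics={}
    )
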