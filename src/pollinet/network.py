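"""Binary bipartite network snapshots shared by the motif and metric code."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BinaryNetwork"]


@dataclass
class BinaryNetwork:
    """Presence/absence interaction network at one point in time.

    Rows are plants, columns are pollinators.  Optional abundance vectors
    travel with the snapshot so saved runs can be re-analyzed.
    """

    plant_ids: list
    poll_ids: list
    adjacency: np.ndarray  # bool (n_plants, n_polls)
    time: float | None = None
    P: np.ndarray | None = None
    A: np.ndarray | None = None
    alpha: np.ndarray | None = None  # foraging efforts on links, if recorded

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.shape != (len(self.plant_ids), len(self.poll_ids)):
            raise ValueError("adjacency shape does not match species lists")

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_polls(self) -> int:
        return len(self.poll_ids)

    def degree_of(self, sid) -> int:
        if sid in self._plant_index:
            return int(self.adjacency[self._plant_index[sid]].sum())
        if sid in self._poll_index:
            return int(self.adjacency[:, self._poll_index[sid]].sum())
        raise KeyError(f"species {sid!r} not in network")

    def __contains__(self, sid) -> bool:
        return sid in self._plant_index or sid in self._poll_index

    @property
    def _plant_index(self) -> dict:
        if not hasattr(self, "_pi"):
            self._pi = {s: i for i, s in enumerate(self.plant_ids)}
        return self._pi

    @property
    def _poll_index(self) -> dict:
        if not hasattr(self, "_ai"):
            self._ai = {s: j for j, s in enumerate(self.poll_ids)}
        return self._ai
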