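"""Mutable community state: species, parameters, abundances and links.

A :class:`Community` bundles everything the dynamical system needs —
plant/pollinator parameter arrays, the bipartite adjacency, abundances of
plants ``P``, pollinators ``A`` and floral rewards ``R``, and the
per-pollinator foraging-effort matrix ``alpha`` (column-stochastic on
links: for every pollinator with at least one partner its efforts sum
to one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import PlantParams, PollinatorParams

__all__ = ["Community"]

_PLANT_FIELDS = ("g", "u", "w", "beta", "phi", "eps", "mu_P", "e")
_POLL_FIELDS = ("tau", "c", "b", "mu_A", "G")

ALPHA_FLOOR = 1e-12
ALPHA_SEED = 0.01  # initial effort share granted to a newly formed link


@dataclass
class Community:
    plant_ids: list
    poll_ids: list
    plant_params: dict  # field name -> (n_p,) array
    poll_params: dict  # field name -> (n_a,) array
    adjacency: np.ndarray  # bool (n_p, n_a)
    P: np.ndarray
    A: np.ndarray
    R: np.ndarray
    alpha: np.ndarray  # (n_p, n_a), nonzero only on links

    # ---------------------------------------------------------------- build
    @classmethod
    def empty(cls) -> "Community":
        z = np.zeros(0)
        return cls(
            plant_ids=[],
            poll_ids=[],
            plant_params={f: np.zeros(0) for f in _PLANT_FIELDS},
            poll_params={f: np.zeros(0) for f in _POLL_FIELDS},
            adjacency=np.zeros((0, 0), dtype=bool),
            P=z.copy(),
            A=z.copy(),
            R=z.copy(),
            alpha=np.zeros((0, 0)),
        )

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_polls(self) -> int:
        return len(self.poll_ids)

    def plant_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def poll_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def copy(self) -> "Community":
        return Community(
            plant_ids=list(self.plant_ids),
            poll_ids=list(self.poll_ids),
            plant_params={k: v.copy() for k, v in self.plant_params.items()},
            poll_params={k: v.copy() for k, v in self.poll_params.items()},
            adjacency=self.adjacency.copy(),
            P=self.P.copy(),
            A=self.A.copy(),
            R=self.R.copy(),
            alpha=self.alpha.copy(),
        )

    # ------------------------------------------------------------ mutation
    def add_plant(
        self,
        sid,
        params: PlantParams,
        abundance: float,
        partners: list[int] | None = None,
    ) -> int:
        """Add a plant; rewards start at the zero-pollinator equilibrium
        ``beta * P0 / phi``.  ``partners`` are pollinator column indices;
        each gains a link whose effort is spliced in at 1/(degree+1) with
        existing efforts rescaled to keep the column sum at one."""
        self.plant_ids.append(sid)
        for f in _PLANT_FIELDS:
            self.plant_params[f] = np.append(self.plant_params[f], getattr(params, f))
        self.P = np.append(self.P, abundance)
        self.R = np.append(self.R, params.beta * abundance / params.phi)
        n_p, n_a = self.adjacency.shape
        adj = np.zeros((n_p + 1, n_a), dtype=bool)
        adj[:n_p] = self.adjacency
        al = np.zeros((n_p + 1, n_a))
        al[:n_p] = self.alpha
        self.adjacency = adj
        self.alpha = al
        i = n_p
        for j in partners or []:
            self._link(i, j)
        return i

    def add_pollinator(
        self,
        sid,
        params: PollinatorParams,
        abundance: float,
        partners: list[int] | None = None,
    ) -> int:
        """Add a pollinator with uniform initial effort over ``partners``
        (plant row indices)."""
        self.poll_ids.append(sid)
        for f in _POLL_FIELDS:
            self.poll_params[f] = np.append(self.poll_params[f], getattr(params, f))
        self.A = np.append(self.A, abundance)
        n_p, n_a = self.adjacency.shape
        adj = np.zeros((n_p, n_a + 1), dtype=bool)
        adj[:, :n_a] = self.adjacency
        al = np.zeros((n_p, n_a + 1))
        al[:, :n_a] = self.alpha
        self.adjacency = adj
        self.alpha = al
        j = n_a
        partners = partners or []
        if partners:
            self.adjacency[partners, j] = True
            self.alpha[partners, j] = 1.0 / len(partners)
        return j

    def _link(self, i: int, j: int) -> None:
        """Create link (plant i, pollinator j).

        The new link starts at a small seed effort (``ALPHA_SEED``, capped
        at the uniform share) and the pollinator's existing efforts are
        rescaled to keep the simplex; under adaptive foraging the link
        must then earn effort through the replicator dynamics."""
        if self.adjacency[i, j]:
            return
        self.adjacency[i, j] = True
        d = int(self.adjacency[:, j].sum())  # degree including the new link
        if d == 1:
            self.alpha[i, j] = 1.0
        else:
            a0 = min(ALPHA_SEED, 1.0 / d)
            self.alpha[:, j] *= 1.0 - a0
            self.alpha[i, j] = a0

    def remove_species(self, plant_rows: list[int], poll_cols: list[int]) -> None:
        """Drop the given plants/pollinators and renormalize the efforts of
        surviving pollinators that lost plant partners (proportional
        rescaling, with a small floor guarding against underflow)."""
        keep_p = np.setdiff1d(np.arange(self.n_plants), plant_rows)
        keep_a = np.setdiff1d(np.arange(self.n_polls), poll_cols)
        self.plant_ids = [self.plant_ids[i] for i in keep_p]
        self.poll_ids = [self.poll_ids[j] for j in keep_a]
        for f in _PLANT_FIELDS:
            self.plant_params[f] = self.plant_params[f][keep_p]
        for f in _POLL_FIELDS:
            self.poll_params[f] = self.poll_params[f][keep_a]
        self.P = self.P[keep_p]
        self.R = self.R[keep_p]
        self.A = self.A[keep_a]
        self.adjacency = self.adjacency[np.ix_(keep_p, keep_a)]
        self.alpha = self.alpha[np.ix_(keep_p, keep_a)]
        self.normalize_efforts()

    def normalize_efforts(self) -> None:
        """Renormalize each linked pollinator's efforts to sum to one."""
        if self.alpha.size == 0:
            return
        self.alpha[~self.adjacency] = 0.0
        np.clip(self.alpha, 0.0, None, out=self.alpha)
        linked = self.adjacency.any(axis=0)
        floored = np.where(self.adjacency, np.maximum(self.alpha, ALPHA_FLOOR), 0.0)
        s = floored.sum(axis=0)
        cols = linked & (s > 0)
        self.alpha[:, cols] = floored[:, cols] / s[cols]

    def set_uniform_efforts(self) -> None:
        """Fixed-forager allocation: equal effort on every diet plant."""
        d = self.poll_degree()
        with np.errstate(divide="ignore", invalid="ignore"):
            self.alpha = np.where(self.adjacency, 1.0 / np.where(d > 0, d, 1), 0.0)

    # ------------------------------------------------------------ checks
    def validate(self, tol: float = 1e-6) -> None:
        n_p, n_a = self.n_plants, self.n_polls
        if self.adjacency.shape != (n_p, n_a) or self.alpha.shape != (n_p, n_a):
            raise ValueError("adjacency/effort shape does not match species lists")
        if self.P.shape != (n_p,) or self.R.shape != (n_p,) or self.A.shape != (n_a,):
            raise ValueError("abundance vector shape mismatch")
        if (self.P < 0).any() or (self.A < 0).any() or (self.R < 0).any():
            raise ValueError("negative abundance")
        if np.isnan(self.P).any() or np.isnan(self.A).any() or np.isnan(self.R).any():
            raise ValueError("NaN abundance")
        linked = self.adjacency.any(axis=0)
        sums = self.alpha.sum(axis=0)
        if linked.any() and np.abs(sums[linked] - 1.0).max() > tol:
            raise ValueError("foraging efforts of a linked pollinator do not sum to 1")
        if (self.alpha[~self.adjacency] != 0).any():
            raise ValueError("effort assigned outside a link")
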